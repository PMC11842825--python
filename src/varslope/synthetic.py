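"""Synthetic underway-transect generator.

Produces every input the patchiness pipeline consumes, with known ground
truth: 1D fields with a prescribed power-law power spectral density,
jittered ship tracks at one record per minute, gappy multivariable underway
streams, and raw 4 Hz hyperspectral absorption/attenuation (AC-s style)
streams with hourly filtered-seawater periods.

Fields are synthesized spectrally: Fourier amplitudes proportional to
k**(-beta/2) with independent uniform phases, inverse-transformed, and
standardized.  The synthesized series is therefore circularly periodic and
its periodogram matches the target spectrum in expectation; a segment cut
from a longer synthesized transect behaves like a window of a continuous
field (no artificial periodicity), which is how ship legs relate to the
ocean they sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG_LAT = 2.0 * np.pi * EARTH_RADIUS_KM / 360.0

#: canonical underway variable order used by the CSV schema
UNDERWAY_VARIABLES = (
    "temp_c",
    "sal_psu",
    "sigma_kg_m3",
    "chl_mg_m3",
    "cp443_1_m",
    "gamma_cp",
    "fcdom_au",
)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTransectConfig:
    """One synthetic 1D field: PSD ~ k**(-beta), optional lognormal marginal,
    additive white-noise floor and injected gaps."""

    beta: float
    n_samples: int
    dx_km: float = 0.21
    marginal: str = "gaussian"
    noise_floor: float = 0.0
    gap_fraction: float = 0.0
    gap_pattern: str = "random_single"
    seed: int = 0
    mean_level: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ConfigurationError("beta must be finite")
        if self.n_samples < 3:
            raise ConfigurationError("n_samples must be >= 3")
        if not 0.0 <= self.gap_fraction <= 0.5:
            raise ConfigurationError("gap_fraction must lie in [0, 0.5]")
        if self.marginal not in ("gaussian", "lognormal"):
            raise ConfigurationError(f"unknown marginal {self.marginal!r}")
        if self.gap_pattern not in ("random_single", "random_blocks"):
            raise ConfigurationError(f"unknown gap_pattern {self.gap_pattern!r}")
        if self.noise_floor < 0:
            raise ConfigurationError("noise_floor must be >= 0")
        if self.marginal == "lognormal" and self.mean_level <= 0:
            raise ConfigurationError("lognormal marginal requires mean_level > 0")


@dataclass
class TrackConfig:
    """Jittered ship track sampled once per minute."""

    n_samples: int
    median_step_km: float = 0.21
    step_variability: float = 0.3
    start_lat: float = 0.0
    start_lon: float = -30.0
    heading_persistence: float = 0.95
    seed: int = 0
    start_time: str = "2020-01-01T00:00:00"

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.median_step_km <= 0:
            raise ConfigurationError("median_step_km must be > 0")
        if not 0.0 <= self.heading_persistence < 1.0 + 1e-12:
            raise ConfigurationError("heading_persistence must lie in [0, 1]")
        if self.step_variability < 0:
            raise ConfigurationError("step_variability must be >= 0")


@dataclass
class AcsStreamConfig:
    """Raw 4 Hz hyperspectral a/c stream with hourly filtered-seawater periods.

    ``chl_profile``, ``gamma_profile`` and ``cdom_profile`` are per-minute
    ground-truth series of chlorophyll (mg m-3), the attenuation spectral
    exponent gamma (dimensionless) and the dissolved absorption level at
    440 nm (m-1).  ``cp443_profile`` (particulate attenuation at 443 nm,
    m-1) defaults to a chlorophyll-linked level 0.05 + 0.3*chl.
    """

    duration_min: int
    chl_profile: np.ndarray
    gamma_profile: np.ndarray
    cdom_profile: np.ndarray
    cp443_profile: np.ndarray | None = None
    sample_rate_hz: int = 4
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 736.1, 4.0)
    )
    filtered_period_min: int = 10
    filtered_cadence_min: int = 60
    spike_rate: float = 0.0
    noise_sd: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or len(wl) < 2 or np.any(np.diff(wl) <= 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        if wl[0] > 410.0 or wl[-1] < 735.0:
            raise ConfigurationError("wavelength grid must span [410, 735] nm")
        self.wavelengths = wl
        for name in ("chl_profile", "gamma_profile", "cdom_profile"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.duration_min,):
                raise ConfigurationError(
                    f"{name} must have length duration_min={self.duration_min}"
                )
            setattr(self, name, arr)
        if self.cp443_profile is None:
            self.cp443_profile = 0.05 + 0.3 * self.chl_profile
        else:
            self.cp443_profile = np.asarray(self.cp443_profile, dtype=float)
            if self.cp443_profile.shape != (self.duration_min,):
                raise ConfigurationError("cp443_profile length mismatch")
        if not 0 < self.filtered_period_min < self.filtered_cadence_min:
            raise ConfigurationError(
                "filtered_period_min must lie in (0, filtered_cadence_min)"
            )
        if not 0.0 <= self.spike_rate < 0.5:
            raise ConfigurationError("spike_rate must lie in [0, 0.5)")


# ---------------------------------------------------------------------------
# power-law field synthesis
# ---------------------------------------------------------------------------

def _powerlaw_amplitudes(beta: float, n: int) -> np.ndarray:
    """rFFT amplitude envelope proportional to k**(-beta/2), DC zeroed."""
    k = np.fft.rfftfreq(n)
    amps = np.zeros_like(k)
    amps[1:] = k[1:] ** (-beta / 2.0)
    return amps


def _unit_phasors(n_freq: int, rng: np.random.Generator) -> np.ndarray:
    """Independent uniform-phase unit phasors, one per rFFT frequency."""
    return np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, n_freq))


def _synthesize(amps: np.ndarray, phasors: np.ndarray, n: int) -> np.ndarray:
    """Inverse-transform an amplitude/phasor spectrum and standardize."""
    spec = amps * phasors
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    if sd == 0.0:  # pathological (all amplitudes zero)
        return x
    return (x - x.mean()) / sd


def _powerlaw_gaussian(beta: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Standardized (zero-mean, unit-variance) series with PSD ~ k**(-beta).

    Spectral synthesis: rFFT amplitudes proportional to k**(-beta/2) with
    independent uniform phases; the DC amplitude is zeroed so the mean is
    decoupled from the spectral shape.
    """
    amps = _powerlaw_amplitudes(beta, n)
    return _synthesize(amps, _unit_phasors(len(amps), rng), n)


def _apply_marginal(z: np.ndarray, config: SyntheticTransectConfig) -> np.ndarray:
    """Map a standardized Gaussian precursor onto the requested marginal.

    Gaussian: affine map to (mean_level, amplitude).  Lognormal: exact
    lognormal with mean ``mean_level`` and standard deviation ``amplitude``
    (guaranteeing positivity), obtained as exp(mu + sigma * z).
    """
    if config.marginal == "gaussian":
        return config.mean_level + config.amplitude * z
    cv2 = (config.amplitude / config.mean_level) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(config.mean_level) - 0.5 * sigma**2
    return np.exp(mu + sigma * z)


def _inject_gaps(
    x: np.ndarray, config: SyntheticTransectConfig, rng: np.random.Generator
) -> np.ndarray:
    """Mark round(gap_fraction * n) samples as NaN, exactly."""
    n = len(x)
    n_gap = int(round(config.gap_fraction * n))
    if n_gap == 0:
        return x
    out = x.copy()
    missing = np.zeros(n, dtype=bool)
    if config.gap_pattern == "random_single":
        idx = rng.choice(n, size=n_gap, replace=False)
        missing[idx] = True
    else:  # random_blocks: geometric block lengths, mean 10 samples
        placed = 0
        attempts = 0
        while placed < n_gap and attempts < 50 * n_gap:
            attempts += 1
            length = min(int(rng.geometric(1.0 / 10.0)), n_gap - placed)
            start = int(rng.integers(0, n - length + 1))
            block = slice(start, start + length)
            if missing[block].any():
                continue
            missing[block] = True
            placed += length
        if placed < n_gap:  # fall back to single-sample fill
            free = np.flatnonzero(~missing)
            idx = rng.choice(free, size=n_gap - placed, replace=False)
            missing[idx] = True
    out[missing] = np.nan
    return out


def gen_powerlaw_series(
    config: SyntheticTransectConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Generate one synthetic transect; NaN marks missing samples."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    z = _powerlaw_gaussian(config.beta, config.n_samples, rng)
    if config.noise_floor > 0:
        z = z + np.sqrt(config.noise_floor) * rng.standard_normal(config.n_samples)
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
    x = _apply_marginal(z, config)
    return _inject_gaps(x, config, rng)


# ---------------------------------------------------------------------------
# ship track
# ---------------------------------------------------------------------------

def gen_track(config: TrackConfig) -> pd.DataFrame:
    """Minute-cadence ship track: columns timestamp, lat, lon.

    Step lengths are lognormal with median ``median_step_km`` and
    coefficient of variation ``step_variability``; the heading random-walks
    with turn size shrinking as heading_persistence approaches 1.  Positions
    advance on a local flat-earth approximation, accurate for sub-km steps.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    if config.step_variability > 0:
        sigma = np.sqrt(np.log1p(config.step_variability**2))
        steps = config.median_step_km * np.exp(
            sigma * rng.standard_normal(n - 1)
        )
    else:
        steps = np.full(n - 1, config.median_step_km)

    turn_sd = 0.5 * (1.0 - config.heading_persistence)
    heading = rng.uniform(0.0, 2.0 * np.pi) + np.concatenate(
        [[0.0], np.cumsum(turn_sd * rng.standard_normal(n - 2))]
    )

    lat = np.empty(n)
    lon = np.empty(n)
    lat[0], lon[0] = config.start_lat, config.start_lon
    dlat = steps * np.cos(heading) / KM_PER_DEG_LAT
    lat[1:] = lat[0] + np.cumsum(dlat)
    # longitude step uses the local latitude's meridian convergence
    coslat = np.cos(np.deg2rad(np.clip(lat[:-1], -89.0, 89.0)))
    dlon = steps * np.sin(heading) / (KM_PER_DEG_LAT * coslat)
    lon[1:] = lon[0] + np.cumsum(dlon)

    timestamps = pd.date_range(config.start_time, periods=n, freq="min")
    return pd.DataFrame({"timestamp": timestamps, "lat": lat, "lon": lon})


# ---------------------------------------------------------------------------
# underway multivariable stream
# ---------------------------------------------------------------------------

def gen_underway_stream(
    track: TrackConfig,
    per_variable_configs: Mapping[str, SyntheticTransectConfig],
    cross_corr: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Assemble a per-minute underway stream on one ship track.

    ``cross_corr`` maps variable pairs to a target Pearson correlation,
    imposed on the Gaussian precursors before marginal transforms
    (Gaussian-copula mixing).  Mixing happens per Fourier frequency on the
    unit phasors, so each variable keeps its own amplitude spectrum exactly
    — correlated absolute values never leak one variable's spectral shape
    (hence its variance slope) into another.  The realized value correlation
    is attenuated below the target when the two spectra differ strongly, and
    further by a lognormal marginal transform.
    """
    n = track.n_samples
    for name, cfg in per_variable_configs.items():
        if cfg.n_samples != n:
            raise ConfigurationError(
                f"variable {name!r} has n_samples={cfg.n_samples}, track has {n}"
            )
    frame = gen_track(track)

    rngs = {
        name: np.random.default_rng(cfg.seed)
        for name, cfg in per_variable_configs.items()
    }
    amps = {
        name: _powerlaw_amplitudes(cfg.beta, n)
        for name, cfg in per_variable_configs.items()
    }
    phasors = {
        name: _unit_phasors(len(amps[name]), rngs[name])
        for name in per_variable_configs
    }
    if cross_corr:
        for (a, b), r in cross_corr.items():
            if a not in phasors or b not in phasors:
                raise ConfigurationError(f"cross_corr names unknown variable ({a}, {b})")
            if not -1.0 < r < 1.0:
                raise ConfigurationError("cross_corr target must lie in (-1, 1)")
            # phasor mixing attenuates the time-domain correlation by the
            # cosine between the two amplitude envelopes; compensate so the
            # realized correlation hits the target (capped at full mixing)
            overlap = (amps[a] * amps[b]).sum() / np.sqrt(
                (amps[a] ** 2).sum() * (amps[b] ** 2).sum()
            )
            r_eff = np.clip(r / max(overlap, 1e-12), -1.0, 1.0)
            phasors[b] = r_eff * phasors[a] + np.sqrt(1.0 - r_eff**2) * phasors[b]

    for name, cfg in per_variable_configs.items():
        rng = rngs[name]
        z = _synthesize(amps[name], phasors[name], n)
        if cfg.noise_floor > 0:
            z = z + np.sqrt(cfg.noise_floor) * rng.standard_normal(n)
            z = (z - z.mean()) / z.std()
        x = _apply_marginal(z, cfg)
        frame[name] = _inject_gaps(x, cfg, rng)
    return frame


def write_underway_csv(stream: pd.DataFrame, path) -> None:
    """Write a stream as CSV; timestamps ISO-8601, missing cells empty."""
    out = stream.copy()
    out = out.rename(columns={"timestamp": "iso8601_time"})
    out["iso8601_time"] = pd.to_datetime(out["iso8601_time"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False, na_rep="")


def read_underway_csv(path) -> pd.DataFrame:
    stream = pd.read_csv(path)
    stream = stream.rename(columns={"iso8601_time": "timestamp"})
    stream["timestamp"] = pd.to_datetime(stream["timestamp"])
    return stream


# ---------------------------------------------------------------------------
# raw 4 Hz AC-s stream
# ---------------------------------------------------------------------------

@dataclass
class AcsStream:
    """Raw 4 Hz spectra with per-minute ground truth.

    ``ap``/``cp`` have shape (n_samples, n_wavelengths); ``minute`` gives
    each sample's minute index and ``is_filtered_minute`` flags filtered-
    seawater minutes.  ``truth`` is the per-minute generator ground truth
    (chl, gamma_cp, cp443, cdom) for parameter-recovery tests.
    """

    wavelengths: np.ndarray
    minute: np.ndarray
    time_min: np.ndarray
    is_filtered_minute: np.ndarray
    ap: np.ndarray
    cp: np.ndarray
    truth: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (time_min, flag, wavelength_nm, ap_1_m, cp_1_m)."""
        n_samp, n_wl = self.ap.shape
        flag = np.where(self.is_filtered_minute[self.minute], "filtered", "total")
        return pd.DataFrame(
            {
                "time_min": np.repeat(self.time_min, n_wl),
                "flag": np.repeat(flag, n_wl),
                "wavelength_nm": np.tile(self.wavelengths, n_samp),
                "ap_1_m": self.ap.ravel(),
                "cp_1_m": self.cp.ravel(),
            }
        )


def _particulate_absorption(
    wavelengths: np.ndarray, chl: np.ndarray
) -> np.ndarray:
    """Chl-scaled particulate absorption: blue band plus the 676 nm peak.

    Chlorophyll-specific shape with Gaussian bands at 440 nm (0.05 m2/mg,
    sigma 60 nm) and 676 nm (0.014 m2/mg, sigma 10 nm).
    """
    blue = 0.05 * np.exp(-0.5 * ((wavelengths - 440.0) / 60.0) ** 2)
    red = 0.014 * np.exp(-0.5 * ((wavelengths - 676.0) / 10.0) ** 2)
    return np.outer(chl, blue + red)


def gen_acs_stream(config: AcsStreamConfig) -> AcsStream:
    """Simulate the raw flow-through optics stream.

    Total-seawater spectra are dissolved baseline plus particulate signal;
    spectra recorded during filtered periods contain only the dissolved
    baseline.  The dissolved baseline is the CDOM exponential
    a_g(lambda) = cdom * exp(-0.017 (lambda - 440)); particulate
    attenuation follows c_p(lambda) = cp443 * (lambda/443)**(-gamma).
    """
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths
    n_min = config.duration_min
    per_min = 60 * config.sample_rate_hz

    minute_idx = np.arange(n_min)
    is_filtered = (minute_idx % config.filtered_cadence_min) < config.filtered_period_min

    ag = np.outer(config.cdom_profile, np.exp(-0.017 * (wl - 440.0)))  # (n_min, n_wl)
    ap_true = _particulate_absorption(wl, config.chl_profile)
    cp_true = config.cp443_profile[:, None] * (wl[None, :] / 443.0) ** (
        -config.gamma_profile[:, None]
    )

    # dissolved matter absorbs but does not scatter, so the filtered-period
    # attenuation baseline equals the CDOM absorption baseline; particulate
    # attenuation cp_true already includes particulate absorption
    ap_minute = ag + np.where(is_filtered[:, None], 0.0, ap_true)
    cp_minute = ag + np.where(is_filtered[:, None], 0.0, cp_true)

    minute = np.repeat(minute_idx, per_min)
    time_min = minute + np.tile(np.arange(per_min) / per_min, n_min)

    shape = (n_min * per_min, len(wl))
    ap = ap_minute[minute] + config.noise_sd * rng.standard_normal(shape)
    cp = cp_minute[minute] + config.noise_sd * rng.standard_normal(shape)

    if config.spike_rate > 0:
        # bubble-like positive spikes, one to ten times a typical signal level
        for arr in (ap, cp):
            mask = rng.random(shape) < config.spike_rate
            arr[mask] += rng.uniform(0.1, 1.0, mask.sum())

    truth = pd.DataFrame(
        {
            "minute": minute_idx,
            "is_filtered": is_filtered,
            "chl_mg_m3": config.chl_profile,
            "gamma_cp": config.gamma_profile,
            "cp443_1_m": config.cp443_profile,
            "cdom_1_m": config.cdom_profile,
        }
    )
    return AcsStream(
        wavelengths=wl,
        minute=minute,
        time_min=time_min,
        is_filtered_minute=is_filtered,
        ap=ap,
        cp=cp,
        truth=truth,
    )


def gen_segmented_legs(
    n_transects: int,
    transect_len: int = 2000,
    leg_size: int = 500,
    beta_range: tuple[float, float] = (1.0, 3.0),
    seed: int = 0,
) -> list[tuple[float, np.ndarray]]:
    """Gapless legs cut from longer power-law transects.

    Each transect draws its spectral exponent uniformly from ``beta_range``
    and is segmented into consecutive ``leg_size``-sample legs, the same way
    the pipeline chops a continuous underway stream.  Because a leg is a
    window of a longer series rather than a full synthesis period, it is not
    circularly periodic — matching how ship legs sample the ocean.  Returns
    (beta, values) pairs.
    """
    rng = np.random.default_rng(seed)
    legs: list[tuple[float, np.ndarray]] = []
    for _ in range(n_transects):
        beta = rng.uniform(*beta_range)
        x = _powerlaw_gaussian(beta, transect_len, rng)
        for j in range(transect_len // leg_size):
            legs.append((beta, x[j * leg_size : (j + 1) * leg_size]))
    return legs


def constant_profiles(
    duration_min: int,
    chl: float = 0.5,
    gamma: float = 1.0,
    cdom: float = 0.05,
) -> dict[str, np.ndarray]:
    """Convenience: flat per-minute profiles for an AC-s stream config."""
    ones = np.ones(duration_min)
    return {
        "chl_profile": chl * ones,
        "gamma_profile": gamma * ones,
        "cdom_profile": cdom * ones,
    }


def smooth_profile(
    duration_min: int,
    base: float,
    amplitude: float,
    period_min: float = 240.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Slowly varying sinusoidal per-minute profile (for baseline drift)."""
    t = np.arange(duration_min)
    return base + amplitude * np.sin(2.0 * np.pi * t / period_min + phase)
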
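"""Underway-stream processing: 4 Hz binning, particulate-spectra derivation,
leg segmentation and quality control.

The processing chain mirrors standard inline-optics practice: raw 4 Hz
samples are percentile-trimmed and averaged per minute; the dissolved
(filtered-seawater) baseline is interpolated across the transect and
subtracted from total-seawater spectra to yield particulate absorption and
attenuation; the per-minute stream is then chopped into consecutive
500-sample legs which must travel 30-150 km, hold at least 80% valid data,
and span no more than 16 hours to enter the patchiness analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ProcessingError
from .synthetic import EARTH_RADIUS_KM, AcsStream


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance (km), Earth radius 6371.0 km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# minute binning with percentile spike rejection
# ---------------------------------------------------------------------------

def minute_bin(samples: np.ndarray) -> tuple[float, float, int]:
    """Trim one minute of raw samples to the [2.5th, 97.5th] percentile
    interval and return (mean, std, n_used) of the retained samples.

    Percentiles use the linear-interpolation convention; samples strictly
    outside the interval are dropped, boundary values retained.  An empty
    minute yields (nan, nan, 0) rather than an error.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        return (np.nan, np.nan, 0)
    lo, hi = np.percentile(samples, [2.5, 97.5])
    kept = samples[(samples >= lo) & (samples <= hi)]
    return (float(kept.mean()), float(kept.std()), int(kept.size))


@dataclass
class BinnedSpectra:
    """Per-minute trimmed-mean spectra with uncertainties."""

    wavelengths: np.ndarray
    minute: np.ndarray            # (n_min,)
    is_filtered: np.ndarray       # (n_min,) bool
    ap: np.ndarray                # (n_min, n_wl) trimmed mean
    cp: np.ndarray
    ap_std: np.ndarray
    cp_std: np.ndarray
    n_used: np.ndarray            # (n_min,) retained samples per minute


def _trim_mean_std(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Percentile-trimmed mean/std along axis 0 of a (n_samples, n_wl) block."""
    lo, hi = np.percentile(block, [2.5, 97.5], axis=0)
    keep = (block >= lo) & (block <= hi)
    masked = np.where(keep, block, np.nan)
    return np.nanmean(masked, axis=0), np.nanstd(masked, axis=0)


def minute_bin_spectra(stream: AcsStream) -> BinnedSpectra:
    """Bin a raw 4 Hz spectra stream to one trimmed-mean spectrum per minute."""
    minutes = np.unique(stream.minute)
    n_wl = len(stream.wavelengths)
    ap = np.full((len(minutes), n_wl), np.nan)
    cp = np.full_like(ap, np.nan)
    ap_std = np.full_like(ap, np.nan)
    cp_std = np.full_like(ap, np.nan)
    n_used = np.zeros(len(minutes), dtype=int)
    for i, m in enumerate(minutes):
        rows = stream.minute == m
        if not rows.any():
            continue
        ap[i], ap_std[i] = _trim_mean_std(stream.ap[rows])
        cp[i], cp_std[i] = _trim_mean_std(stream.cp[rows])
        n_used[i] = int(rows.sum())
    return BinnedSpectra(
        wavelengths=stream.wavelengths,
        minute=minutes,
        is_filtered=stream.is_filtered_minute[minutes],
        ap=ap,
        cp=cp,
        ap_std=ap_std,
        cp_std=cp_std,
        n_used=n_used,
    )


# ---------------------------------------------------------------------------
# dissolved baseline subtraction -> particulate spectra
# ---------------------------------------------------------------------------

@dataclass
class ParticulateSpectra:
    """Per-minute particulate spectra for total-seawater minutes."""

    wavelengths: np.ndarray
    minute: np.ndarray
    ap: np.ndarray
    cp: np.ndarray
    baseline_ap: np.ndarray
    baseline_cp: np.ndarray


def _filtered_periods(binned: BinnedSpectra) -> list[np.ndarray]:
    """Contiguous runs of filtered minutes, as index arrays into binned rows."""
    idx = np.flatnonzero(binned.is_filtered)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(binned.minute[idx]) > 1) + 1
    return np.split(idx, breaks)


def derive_particulate(
    binned: BinnedSpectra,
    method: str = "linear",
    fcdom: np.ndarray | None = None,
) -> ParticulateSpectra:
    """Subtract the interpolated dissolved baseline from total spectra.

    Each filtered period is summarized by its median spectrum at its
    midpoint time.  method="linear" interpolates baselines linearly in time
    between consecutive period medians; method="fcdom_scaled" moves the
    baseline between bracketing medians proportionally to the fCDOM signal
    (falling back to the time fraction when fCDOM is flat between the
    brackets).  Total minutes outside the first/last period take the
    nearest period's baseline.  Exactly: particulate = total - baseline.
    """
    if method not in ("linear", "fcdom_scaled"):
        raise ConfigurationError(f"unknown method {method!r}")
    if method == "fcdom_scaled" and fcdom is None:
        raise ConfigurationError("fcdom_scaled requires an fcdom series")
    periods = _filtered_periods(binned)
    if not periods:
        raise ProcessingError("no filtered-seawater periods in stream")

    t_per = np.array([binned.minute[p].mean() for p in periods])
    ap_per = np.array([np.nanmedian(binned.ap[p], axis=0) for p in periods])
    cp_per = np.array([np.nanmedian(binned.cp[p], axis=0) for p in periods])

    total = ~binned.is_filtered
    t_tot = binned.minute[total].astype(float)

    if method == "linear" or len(periods) == 1:
        base_ap = np.stack([np.interp(t_tot, t_per, ap_per[:, w])
                            for w in range(len(binned.wavelengths))], axis=1)
        base_cp = np.stack([np.interp(t_tot, t_per, cp_per[:, w])
                            for w in range(len(binned.wavelengths))], axis=1)
    else:
        if fcdom is None:
            raise ConfigurationError("fcdom_scaled requires an fcdom series")
        fcdom = np.asarray(fcdom, dtype=float)
        if fcdom.shape != binned.minute.shape:
            raise ConfigurationError("fcdom must align with binned minutes")
        f_per = np.array([np.nanmedian(fcdom[p]) for p in periods])
        # bracketing period for each total minute, clamped at the edges
        hi = np.clip(np.searchsorted(t_per, t_tot), 1, len(t_per) - 1)
        lo = hi - 1
        dt = t_per[hi] - t_per[lo]
        time_frac = np.clip((t_tot - t_per[lo]) / dt, 0.0, 1.0)
        df = f_per[hi] - f_per[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            f_frac = (fcdom[total] - f_per[lo]) / df
        frac = np.where(np.abs(df) > 1e-12, f_frac, time_frac)
        # nearest-neighbour beyond the outermost periods
        frac = np.where(t_tot < t_per[0], 0.0, frac)
        frac = np.where(t_tot > t_per[-1], 1.0, frac)
        base_ap = ap_per[lo] + frac[:, None] * (ap_per[hi] - ap_per[lo])
        base_cp = cp_per[lo] + frac[:, None] * (cp_per[hi] - cp_per[lo])

    return ParticulateSpectra(
        wavelengths=binned.wavelengths,
        minute=binned.minute[total],
        ap=binned.ap[total] - base_ap,
        cp=binned.cp[total] - base_cp,
        baseline_ap=base_ap,
        baseline_cp=base_cp,
    )


# ---------------------------------------------------------------------------
# leg segmentation
# ---------------------------------------------------------------------------

LEG_SIZE = 500


@dataclass
class Leg:
    """One contiguous block of minute slots, the unit of patchiness analysis."""

    leg_id: int
    timestamps: pd.DatetimeIndex
    lat: np.ndarray
    lon: np.ndarray
    values: dict[str, np.ndarray]
    coverage: dict[str, float]
    along_track_km: float
    elapsed_hours: float
    centroid_lat: float
    centroid_lon: float
    province: str | None = None


@dataclass
class QcCriteria:
    """Leg acceptance rules: path distance, data coverage, elapsed time."""

    min_distance_km: float = 30.0
    max_distance_km: float = 150.0
    min_coverage: float = 0.80
    max_elapsed_hours: float = 16.0

    def __post_init__(self) -> None:
        if not self.min_distance_km < self.max_distance_km:
            raise ConfigurationError("min_distance_km must be < max_distance_km")
        if not 0.0 < self.min_coverage <= 1.0:
            raise ConfigurationError("min_coverage must lie in (0, 1]")


def _leg_metadata(lat: np.ndarray, lon: np.ndarray) -> tuple[float, float, float]:
    """(along_track_km, centroid_lat, centroid_lon) over valid positions."""
    ok = np.isfinite(lat) & np.isfinite(lon)
    la, lo = lat[ok], lon[ok]
    if la.size < 2:
        return 0.0, float(np.nanmean(lat)), float(np.nanmean(lon))
    dist = float(haversine_km(la[:-1], lo[:-1], la[1:], lo[1:]).sum())
    return dist, float(la.mean()), float(lo.mean())


def segment_legs(
    stream: pd.DataFrame,
    variables: Sequence[str] | None = None,
    leg_size: int = LEG_SIZE,
) -> list[Leg]:
    """Chop a per-minute stream into consecutive, non-overlapping legs.

    The stream is first reindexed onto a continuous 1-minute grid so that
    absent minutes occupy slots as missing values; the trailing remainder
    shorter than ``leg_size`` is discarded.
    """
    if stream.empty or len(stream) < leg_size:
        return []
    if variables is None:
        variables = [
            c for c in stream.columns if c not in ("timestamp", "lat", "lon")
        ]
    s = stream.set_index("timestamp").sort_index()
    full = pd.date_range(s.index[0], s.index[-1], freq="min")
    s = s.reindex(full)

    legs: list[Leg] = []
    for i in range(len(s) // leg_size):
        chunk = s.iloc[i * leg_size : (i + 1) * leg_size]
        lat = chunk["lat"].to_numpy(float)
        lon = chunk["lon"].to_numpy(float)
        dist, clat, clon = _leg_metadata(lat, lon)
        values = {v: chunk[v].to_numpy(float) for v in variables}
        coverage = {
            v: float(np.isfinite(arr).sum()) / leg_size for v, arr in values.items()
        }
        elapsed = (chunk.index[-1] - chunk.index[0]).total_seconds() / 3600.0
        legs.append(
            Leg(
                leg_id=i,
                timestamps=chunk.index,
                lat=lat,
                lon=lon,
                values=values,
                coverage=coverage,
                along_track_km=dist,
                elapsed_hours=elapsed,
                centroid_lat=clat,
                centroid_lon=clon,
            )
        )
    return legs


def qc_filter(
    legs: Sequence[Leg],
    criteria: QcCriteria | None = None,
    variable: str | None = None,
) -> tuple[list[Leg], dict[int, list[str]]]:
    """Apply the leg acceptance rules for one variable.

    Returns the kept legs and, for every leg, the list of rejection reason
    codes (empty list = kept): distance_short, distance_long, low_coverage,
    elapsed_long.
    """
    criteria = criteria or QcCriteria()
    reasons: dict[int, list[str]] = {}
    kept: list[Leg] = []
    for leg in legs:
        if variable is not None and variable not in leg.coverage:
            raise ConfigurationError(f"unknown variable {variable!r}")
        why: list[str] = []
        if leg.along_track_km < criteria.min_distance_km:
            why.append("distance_short")
        if leg.along_track_km > criteria.max_distance_km:
            why.append("distance_long")
        if variable is not None and leg.coverage[variable] < criteria.min_coverage:
            why.append("low_coverage")
        if leg.elapsed_hours > criteria.max_elapsed_hours:
            why.append("elapsed_long")
        reasons[leg.leg_id] = why
        if not why:
            kept.append(leg)
    return kept, reasons


def leg_table(legs: Sequence[Leg], reasons: Mapping[int, list[str]] | None = None) -> pd.DataFrame:
    """Tabular summary of legs (one row per leg/variable) for CSV export."""
    rows = []
    for leg in legs:
        why = (reasons or {}).get(leg.leg_id, [])
        for var, cov in leg.coverage.items():
            rows.append(
                {
                    "leg_id": leg.leg_id,
                    "variable": var,
                    "coverage": cov,
                    "along_track_km": leg.along_track_km,
                    "elapsed_h": leg.elapsed_hours,
                    "centroid_lat": leg.centroid_lat,
                    "centroid_lon": leg.centroid_lon,
                    "qc_pass": not why,
                    "reason": ";".join(why),
                }
            )
    return pd.DataFrame(rows)
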
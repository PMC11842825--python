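"""Scale-dependent variance and the variance slope (Gamma).

Patchiness of a transect is quantified by how variance partitions across
length scales.  For a 500-sample leg, the within-window variance V is
computed at 11 log-distributed window sizes L from 3 to 500 samples; V
grows with L approximately as a power law

    V = L ** Gamma,

and the least-squares slope of log10 V against log10 L is the variance
slope Gamma.  A white-noise transect has Gamma centered on 0; a red,
large-scale-dominated transect has Gamma near 2.  Lower Gamma means
relatively more variance at small scales — a patchier transect.  Unlike a
Fourier spectral slope the statistic tolerates data gaps (up to ~20% of a
leg), and it is exactly invariant to affine transforms of the data.

A conventional periodogram slope estimator and the empirical linear map
between the two exponents are provided for cross-calibration; on gapless
power-law transects the two are strongly correlated, and the classical
-5/3 inertial-subrange spectral slope corresponds to Gamma near 0.84.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ProcessingError


# ---------------------------------------------------------------------------
# window scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowScheme:
    """Log-distributed integer window sizes (samples)."""

    min_window: int
    max_window: int
    n_windows: int
    sizes: tuple[int, ...]


def make_window_scheme(
    min_window: int = 3, max_window: int = 500, n_windows: int = 11
) -> WindowScheme:
    """Log-uniform window sizes from min to max, rounded to integers,
    deduplicated in order; both endpoints always present."""
    if not 2 <= min_window < max_window:
        raise ConfigurationError("need 2 <= min_window < max_window")
    if n_windows < 2:
        raise ConfigurationError("n_windows must be >= 2")
    if n_windows > max_window - min_window + 1:
        raise ConfigurationError("n_windows exceeds the number of integer sizes")
    raw = np.geomspace(min_window, max_window, n_windows)
    sizes = []
    for s in np.round(raw).astype(int):
        if s not in sizes:
            sizes.append(int(s))
    sizes[0], sizes[-1] = min_window, max_window
    return WindowScheme(min_window, max_window, n_windows, tuple(sizes))


DEFAULT_SCHEME = make_window_scheme()


# ---------------------------------------------------------------------------
# scale-dependent variance
# ---------------------------------------------------------------------------

@dataclass
class ScaleVarianceCurve:
    """V(L) at each window size, with per-scale contributing-block counts."""

    window_samples: np.ndarray
    V: np.ndarray
    n_blocks_used: np.ndarray
    window_km: np.ndarray | None = None


@dataclass
class VarianceSlopeResult:
    """Gamma with fit diagnostics and a validity flag."""

    gamma: float
    intercept: float
    r_squared: float
    n_scales_used: int
    valid: bool
    reason: str = ""


def scale_variance(
    leg_values: np.ndarray,
    scheme: WindowScheme = DEFAULT_SCHEME,
    min_block_coverage: float = 0.80,
    variance_ddof: int = 1,
    step_km: float | None = None,
) -> ScaleVarianceCurve:
    """Gap-tolerant scale-dependent variance of one leg.

    For each window size w the leg is partitioned into consecutive
    non-overlapping blocks of w slots (trailing remainder discarded).  A
    block contributes if its valid fraction is at least
    ``min_block_coverage``; its variance is taken over the valid samples
    (``variance_ddof=1`` for the unbiased sample variance — the default,
    which makes white noise flat in expectation — or 0 for the population
    convention).  V(w) is the mean over contributing blocks, NaN when none
    contribute.
    """
    x = np.asarray(leg_values, dtype=float)
    valid = np.isfinite(x)
    if not valid.any():
        raise ProcessingError("leg contains no valid samples")
    min_valid = variance_ddof + 1
    V = np.full(len(scheme.sizes), np.nan)
    n_used = np.zeros(len(scheme.sizes), dtype=int)
    for i, w in enumerate(scheme.sizes):
        nb = len(x) // w
        if nb == 0:
            continue
        blocks = x[: nb * w].reshape(nb, w)
        bvalid = valid[: nb * w].reshape(nb, w)
        counts = bvalid.sum(axis=1)
        ok = (counts >= min_block_coverage * w) & (counts >= min_valid)
        if not ok.any():
            continue
        with np.errstate(invalid="ignore"):
            bvar = np.nanvar(blocks[ok], axis=1, ddof=variance_ddof)
        bvar = bvar[np.isfinite(bvar)]
        if bvar.size == 0:
            continue
        V[i] = bvar.mean()
        n_used[i] = bvar.size
    window_km = (
        np.asarray(scheme.sizes, float) * step_km if step_km is not None else None
    )
    return ScaleVarianceCurve(
        window_samples=np.asarray(scheme.sizes, dtype=int),
        V=V,
        n_blocks_used=n_used,
        window_km=window_km,
    )


def fit_gamma(curve: ScaleVarianceCurve) -> VarianceSlopeResult:
    """Least-squares fit of log10 V on log10 L over usable scales.

    Scales with missing or non-positive V are excluded; fewer than two
    usable scales yields an invalid result rather than an exception.
    """
    usable = np.isfinite(curve.V) & (curve.V > 0)
    n = int(usable.sum())
    if n < 2:
        return VarianceSlopeResult(
            gamma=np.nan,
            intercept=np.nan,
            r_squared=np.nan,
            n_scales_used=n,
            valid=False,
            reason="fewer than 2 usable scales",
        )
    logL = np.log10(curve.window_samples[usable].astype(float))
    logV = np.log10(curve.V[usable])
    res = stats.linregress(logL, logV)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return VarianceSlopeResult(
        gamma=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_scales_used=n,
        valid=True,
    )


def leg_gamma(
    leg_values: np.ndarray,
    scheme: WindowScheme = DEFAULT_SCHEME,
    min_block_coverage: float = 0.80,
    variance_ddof: int = 1,
    step_km: float | None = None,
) -> VarianceSlopeResult:
    """Variance slope of one leg: scale_variance then fit_gamma."""
    curve = scale_variance(
        leg_values,
        scheme=scheme,
        min_block_coverage=min_block_coverage,
        variance_ddof=variance_ddof,
        step_km=step_km,
    )
    return fit_gamma(curve)


# ---------------------------------------------------------------------------
# Fourier spectral slope and the Gamma <-> slope map
# ---------------------------------------------------------------------------

def fourier_slope(
    leg_values: np.ndarray,
    dx_km: float | None = None,
    scheme: WindowScheme = DEFAULT_SCHEME,
) -> float:
    """Periodogram log-log slope of a gapless leg.

    The mean-removed series' periodogram is fit by OLS of log10 power on
    log10 frequency over the frequency band matched to the window scheme
    (periods between min_window and max_window samples).  The returned
    slope is signed (negative for red spectra) and independent of the
    sample spacing ``dx_km``, which only rescales the frequency axis.
    """
    x = np.asarray(leg_values, dtype=float)
    if not np.isfinite(x).all():
        raise ProcessingError(
            "fourier_slope requires a gapless series; use leg_gamma for gappy legs"
        )
    n = len(x)
    x = x - x.mean()
    f = np.fft.rfftfreq(n)
    power = np.abs(np.fft.rfft(x)) ** 2
    sel = (f >= 1.0 / scheme.max_window) & (f <= 1.0 / scheme.min_window) & (power > 0)
    if sel.sum() < 2:
        raise ProcessingError("too few spectral estimates in the fitted band")
    return float(np.polyfit(np.log10(f[sel]), np.log10(power[sel]), 1)[0])


@dataclass
class GammaSlopeMap:
    """Fitted linear relation Gamma = coef * slope + intercept."""

    coef: float
    intercept: float
    n: int
    r_squared: float

    def predict(self, slope: float) -> float:
        return self.coef * slope + self.intercept


def gamma_slope_map(
    gammas: Sequence[float], slopes: Sequence[float], min_pairs: int = 20
) -> GammaSlopeMap:
    """OLS of per-leg Gamma on per-leg Fourier slope across an ensemble."""
    g = np.asarray(gammas, dtype=float)
    s = np.asarray(slopes, dtype=float)
    ok = np.isfinite(g) & np.isfinite(s)
    g, s = g[ok], s[ok]
    if len(g) < min_pairs:
        raise ConfigurationError(f"need at least {min_pairs} (gamma, slope) pairs")
    if np.std(s) < 1e-12:
        raise ProcessingError("degenerate slope spread; cannot fit the map")
    res = stats.linregress(s, g)
    return GammaSlopeMap(
        coef=float(res.slope),
        intercept=float(res.intercept),
        n=len(g),
        r_squared=float(res.rvalue) ** 2,
    )
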
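"""Comparative statistics over per-leg variance slopes.

Once a Gamma value exists per (leg, variable), the scientific questions are
comparative: do the variance slopes of two variables co-vary across legs;
how do province-level means behave; does patchiness track the absolute
magnitude of a variable; and is Gamma itself spatially organized.  The
central empirical contrast these tools expose is that the absolute values
of physical and biological variables can be strongly correlated while their
variance slopes are not.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ProcessingError
from .gamma import (
    DEFAULT_SCHEME,
    VarianceSlopeResult,
    WindowScheme,
    leg_gamma,
)
from .processing import Leg, haversine_km

logger = logging.getLogger(__name__)

GAMMA_TABLE_COLUMNS = (
    "leg_id",
    "variable",
    "gamma",
    "intercept",
    "r2",
    "n_scales",
    "valid",
    "reason",
    "mean_abs_value",
    "centroid_lat",
    "centroid_lon",
)


def gamma_table_from_legs(
    legs: Sequence[Leg],
    variables: Sequence[str],
    scheme: WindowScheme = DEFAULT_SCHEME,
    min_block_coverage: float = 0.80,
    variance_ddof: int = 1,
) -> pd.DataFrame:
    """Compute the per-(leg, variable) Gamma table feeding all comparisons."""
    rows = []
    for leg in legs:
        for var in variables:
            if var not in leg.values:
                raise ConfigurationError(f"unknown variable {var!r}")
            x = leg.values[var]
            if np.isfinite(x).any():
                res = leg_gamma(
                    x,
                    scheme=scheme,
                    min_block_coverage=min_block_coverage,
                    variance_ddof=variance_ddof,
                )
                mean_abs = float(np.nanmean(np.abs(x)))
            else:
                res = VarianceSlopeResult(
                    np.nan, np.nan, np.nan, 0, False, "all missing"
                )
                mean_abs = np.nan
            rows.append(
                {
                    "leg_id": leg.leg_id,
                    "variable": var,
                    "gamma": res.gamma,
                    "intercept": res.intercept,
                    "r2": res.r_squared,
                    "n_scales": res.n_scales_used,
                    "valid": res.valid,
                    "reason": res.reason,
                    "mean_abs_value": mean_abs,
                    "centroid_lat": leg.centroid_lat,
                    "centroid_lon": leg.centroid_lon,
                }
            )
    return pd.DataFrame(rows, columns=list(GAMMA_TABLE_COLUMNS))


def _valid_rows(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    rows = table[(table["variable"] == variable)]
    if "valid" in table.columns:
        rows = rows[rows["valid"].astype(bool)]
    return rows.dropna(subset=["gamma"])


def correlate_gammas(
    table: pd.DataFrame,
    var_a: str,
    var_b: str,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Cross-variable correlation of per-leg Gamma: (r_squared, p_value, n).

    Pairwise-complete over legs holding a valid Gamma for both variables;
    the two-sided p-value comes from the t reference distribution.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown method {method!r}")
    a = _valid_rows(table, var_a).set_index("leg_id")["gamma"]
    b = _valid_rows(table, var_b).set_index("leg_id")["gamma"]
    joined = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"]).dropna()
    n = len(joined)
    if n < 3:
        raise ProcessingError(f"only {n} complete Gamma pairs; need >= 3")
    if method == "pearson":
        r, p = stats.pearsonr(joined["a"], joined["b"])
    else:
        r, p = stats.spearmanr(joined["a"], joined["b"])
    return float(r) ** 2, float(p), n


def scale_restricted_gamma(
    leg_values: np.ndarray,
    scheme: WindowScheme = DEFAULT_SCHEME,
    max_window_samples: int | None = None,
    **leg_gamma_kwargs,
) -> VarianceSlopeResult:
    """Gamma recomputed with the window set truncated at a top length scale.

    Restricting e.g. to windows of at most 25 samples (~5 km at a 0.21 km
    step) probes patchiness over small scales only.
    """
    if max_window_samples is None:
        return leg_gamma(leg_values, scheme=scheme, **leg_gamma_kwargs)
    sizes = tuple(s for s in scheme.sizes if s <= max_window_samples)
    if len(sizes) < 2:
        raise ConfigurationError("restricted scheme has fewer than 2 window sizes")
    restricted = WindowScheme(sizes[0], sizes[-1], len(sizes), sizes)
    return leg_gamma(leg_values, scheme=restricted, **leg_gamma_kwargs)


def province_aggregate(
    table: pd.DataFrame,
    leg_to_province: pd.DataFrame,
    min_legs: int = 25,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Province-level unweighted means of Gamma and of absolute values.

    ``leg_to_province`` maps leg_id -> province_code; unmapped legs are
    dropped with a warning.  Provinces contribute only where at least
    ``min_legs`` legs hold a valid Gamma for the variable.  ``covariates``
    (e.g. climatological nutrients, oxygen saturation per province) are
    joined by province_code.
    """
    if leg_to_province.empty:
        raise ConfigurationError("empty leg -> province mapping")
    merged = table.merge(leg_to_province, on="leg_id", how="left")
    unmapped = merged["province_code"].isna()
    if unmapped.any():
        logger.warning(
            "dropping %d gamma rows from legs without a province", int(unmapped.sum())
        )
        merged = merged[~unmapped]
    if "valid" in merged.columns:
        merged = merged[merged["valid"].astype(bool)]
    merged = merged.dropna(subset=["gamma"])
    out = (
        merged.groupby(["province_code", "variable"], as_index=False)
        .agg(
            mean_gamma=("gamma", "mean"),
            mean_abs_value=("mean_abs_value", "mean"),
            n_legs=("leg_id", "nunique"),
        )
    )
    out = out[out["n_legs"] >= min_legs].reset_index(drop=True)
    if covariates is not None:
        out = out.merge(covariates, on="province_code", how="left")
    return out


def gamma_vs_magnitude(
    table: pd.DataFrame, variable: str
) -> tuple[float, int, int]:
    """Relationship between a variable's Gamma and its absolute magnitude.

    Pearson correlation across legs between the per-leg mean absolute value
    and Gamma; returns (r_squared, slope_sign, n).  Concentration-like
    variables are expected to show a positive sign (high-biomass regions
    are less patchy); physical variables none.
    """
    rows = _valid_rows(table, variable).dropna(subset=["mean_abs_value"])
    n = len(rows)
    if n < 3:
        raise ProcessingError(f"only {n} valid rows for {variable!r}; need >= 3")
    mags = rows["mean_abs_value"].to_numpy(float)
    if np.std(mags) < 1e-15:
        raise ProcessingError("zero-variance absolute values; correlation undefined")
    r, _ = stats.pearsonr(mags, rows["gamma"].to_numpy(float))
    return float(r) ** 2, int(np.sign(r)), n


def spatial_autocorrelogram(
    table: pd.DataFrame,
    variable: str,
    lag_edges_km: np.ndarray | None = None,
    n_bins: int = 10,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Binned spatial correlogram of Gamma over leg-centroid pairs.

    All leg pairs are binned by haversine centroid distance; each bin
    reports the Pearson correlation of paired Gamma values (both pair
    orders included, making the estimate symmetric).  Bins with fewer than
    ``min_pairs`` pairs are flagged.  Default bins are logarithmic between
    the smallest and largest pair distances.
    """
    rows = _valid_rows(table, variable).dropna(
        subset=["centroid_lat", "centroid_lon"]
    )
    if len(rows) < 10:
        raise ProcessingError("need at least 10 legs with centroids")
    g = rows["gamma"].to_numpy(float)
    lat = rows["centroid_lat"].to_numpy(float)
    lon = rows["centroid_lon"].to_numpy(float)
    i, j = np.triu_indices(len(g), k=1)
    d = haversine_km(lat[i], lon[i], lat[j], lon[j])
    if lag_edges_km is None:
        dmin = max(d[d > 0].min(), 1e-3) if (d > 0).any() else 1e-3
        lag_edges_km = np.geomspace(dmin * 0.999, d.max() * 1.001, n_bins + 1)
    lag_edges_km = np.asarray(lag_edges_km, dtype=float)
    which = np.digitize(d, lag_edges_km) - 1
    records = []
    any_pairs = False
    for b in range(len(lag_edges_km) - 1):
        sel = which == b
        n_pairs = int(sel.sum())
        if n_pairs >= 2:
            x = np.concatenate([g[i[sel]], g[j[sel]]])
            y = np.concatenate([g[j[sel]], g[i[sel]]])
            r = float(np.corrcoef(x, y)[0, 1]) if np.std(x) > 0 else np.nan
        else:
            r = np.nan
        if n_pairs > 0:
            any_pairs = True
        records.append(
            {
                "lag_left_km": lag_edges_km[b],
                "lag_right_km": lag_edges_km[b + 1],
                "r": r,
                "n_pairs": n_pairs,
                "flagged": n_pairs < min_pairs,
            }
        )
    if not any_pairs:
        raise ProcessingError("no leg pairs fall inside the lag bins")
    return pd.DataFrame(records)
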
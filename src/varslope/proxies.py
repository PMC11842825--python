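"""Optical biogeochemical proxies from particulate spectra.

Three per-minute proxies drive the patchiness analysis:

* chlorophyll line height — baseline-subtracted particulate absorption at
  the 676 nm chl-a peak, an optical chlorophyll proxy;
* gamma_cp — the negated log-log slope of particulate attenuation versus
  wavelength (c_p(lambda) ~ lambda**-gamma), a proxy for mean particle size
  (larger gamma, smaller particles);
* c_p(443) — particulate attenuation at 443 nm, a particle-load proxy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .processing import ParticulateSpectra


def _interp_band(wavelengths: np.ndarray, values: np.ndarray, nm: float) -> float:
    """Linear interpolation at one wavelength; NaN if not bracketed or gappy."""
    if nm < wavelengths[0] or nm > wavelengths[-1]:
        return np.nan
    hi = int(np.searchsorted(wavelengths, nm))
    if wavelengths[min(hi, len(wavelengths) - 1)] == nm:
        return float(values[min(hi, len(wavelengths) - 1)])
    lo = hi - 1
    if not (np.isfinite(values[lo]) and np.isfinite(values[hi])):
        return np.nan
    frac = (nm - wavelengths[lo]) / (wavelengths[hi] - wavelengths[lo])
    return float(values[lo] + frac * (values[hi] - values[lo]))


def chl_line_height(
    wavelengths: np.ndarray,
    ap: np.ndarray,
    peak_nm: float = 676.0,
    base_left_nm: float = 650.0,
    base_right_nm: float = 715.0,
) -> float:
    """Absorption line height above the 650-715 nm linear baseline at 676 nm.

    LH = a_p(peak) - [a_p(left) + (a_p(right) - a_p(left)) *
    (peak - left)/(right - left)], each band linearly interpolated on the
    wavelength grid; NaN if any band is unavailable.  Exactly invariant to
    adding any affine function of wavelength to the spectrum.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    ap = np.asarray(ap, dtype=float)
    a_peak = _interp_band(wavelengths, ap, peak_nm)
    a_l = _interp_band(wavelengths, ap, base_left_nm)
    a_r = _interp_band(wavelengths, ap, base_right_nm)
    if not (np.isfinite(a_peak) and np.isfinite(a_l) and np.isfinite(a_r)):
        return np.nan
    frac = (peak_nm - base_left_nm) / (base_right_nm - base_left_nm)
    return a_peak - (a_l + frac * (a_r - a_l))


def particle_size_gamma(
    wavelengths: np.ndarray,
    cp: np.ndarray,
    fit_range_nm: tuple[float, float] = (450.0, 700.0),
    exclude_nm: tuple[float, float] | None = (660.0, 690.0),
    min_points: int = 5,
) -> float:
    """Particle-size proxy gamma: negated slope of ln c_p versus ln lambda.

    Fit over ``fit_range_nm`` with the chl absorption-peak region
    ``exclude_nm`` left out (the power-law model assumes a non-absorbing
    spectral shape); non-positive c_p values are excluded from the log-space
    fit.  NaN when fewer than ``min_points`` usable wavelengths remain.
    Invariant to multiplying c_p by any positive constant.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    cp = np.asarray(cp, dtype=float)
    sel = (
        (wavelengths >= fit_range_nm[0])
        & (wavelengths <= fit_range_nm[1])
        & np.isfinite(cp)
        & (cp > 0)
    )
    if exclude_nm is not None:
        sel &= ~((wavelengths >= exclude_nm[0]) & (wavelengths <= exclude_nm[1]))
    if sel.sum() < min_points:
        return np.nan
    slope = np.polyfit(np.log(wavelengths[sel]), np.log(cp[sel]), 1)[0]
    return -float(slope)


def cp_at(wavelengths: np.ndarray, cp: np.ndarray, target_nm: float = 443.0) -> float:
    """Particulate attenuation linearly interpolated at ``target_nm``."""
    return _interp_band(np.asarray(wavelengths, float), np.asarray(cp, float), target_nm)


def proxy_table(
    spectra: ParticulateSpectra,
    peak_nm: float = 676.0,
    base_left_nm: float = 650.0,
    base_right_nm: float = 715.0,
    gamma_fit_range_nm: tuple[float, float] = (450.0, 700.0),
    cp_target_nm: float = 443.0,
) -> pd.DataFrame:
    """Per-minute proxy table (minute, chl_lh, gamma_cp, cp443)."""
    rows = []
    for i, minute in enumerate(spectra.minute):
        rows.append(
            {
                "minute": int(minute),
                "chl_lh": chl_line_height(
                    spectra.wavelengths, spectra.ap[i], peak_nm, base_left_nm, base_right_nm
                ),
                "gamma_cp": particle_size_gamma(
                    spectra.wavelengths, spectra.cp[i], gamma_fit_range_nm
                ),
                "cp443": cp_at(spectra.wavelengths, spectra.cp[i], cp_target_nm),
            }
        )
    return pd.DataFrame(rows)
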
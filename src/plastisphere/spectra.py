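"""FTIR spectrum processing and polymer oxidation indices.

Spectra are smoothed with a centred moving average, baseline-corrected by
subtracting the straight line through the spectrum minima in the two
flanking regions outside all peak windows, and scaled to unit maximum.
Oxidation indices are ratios of peak heights at the carboxylic C=O
(1711 cm^-1), carboxylic C-O (1240), ester C-O (1090) and aromatic C-H
(725) bands to the invariant reference band at 1410 cm^-1; an increase in
these ratios indicates surface oxidation of the polymer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import OXIDATION_WAVENUMBERS

REFERENCE_WAVENUMBER = 1410.0
RATIO_WAVENUMBERS = (725.0, 1090.0, 1240.0, 1711.0)
DEFAULT_HALF_WINDOW = 10.0  # cm^-1 search window around a nominal peak


@dataclass
class Spectrum:
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValueError("wavenumber and absorbance grids differ in length")
        diffs = np.diff(self.wavenumbers)
        if not ((diffs > 0).all() or (diffs < 0).all()):
            raise ValueError("wavenumber grid must be strictly monotone")


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return y.copy()
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def preprocess(spec: Spectrum, smooth_window: int = 5,
               peaks=OXIDATION_WAVENUMBERS,
               half_window: float = DEFAULT_HALF_WINDOW,
               flank_margin: float = 3.0) -> Spectrum:
    """Smooth, subtract a linear baseline and scale to unit maximum.

    The baseline is the straight line through the smoothed spectrum's
    minimum in the region above the highest peak window and its minimum in
    the region below the lowest peak window (``flank_margin`` half-windows
    away from the outermost peaks).
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    if smooth_window >= spec.wavenumbers.size:
        raise ValueError("smooth_window must be smaller than the grid")
    smoothed = _moving_average(spec.absorbance, smooth_window)
    wn = spec.wavenumbers
    hi_edge = max(peaks) + flank_margin * half_window
    lo_edge = min(peaks) - flank_margin * half_window
    upper = wn > hi_edge
    lower = wn < lo_edge
    if not upper.any() or not lower.any():
        raise ValueError("grid lacks flanking regions outside the peak windows")
    i_hi = np.where(upper)[0][np.argmin(smoothed[upper])]
    i_lo = np.where(lower)[0][np.argmin(smoothed[lower])]
    x1, y1 = wn[i_hi], smoothed[i_hi]
    x2, y2 = wn[i_lo], smoothed[i_lo]
    slope = (y2 - y1) / (x2 - x1)
    baseline = y1 + slope * (wn - x1)
    corrected = smoothed - baseline
    top = corrected.max()
    # scale to unit maximum unless the residual is numerically zero
    if top > 1e-12 * max(1.0, float(np.abs(smoothed).max())):
        corrected = corrected / top
    return replace(spec, absorbance=corrected)


def peak_height(spec: Spectrum, nominal: float,
                half_window: float = DEFAULT_HALF_WINDOW) -> float:
    """Maximum absorbance within ``nominal`` +/- ``half_window`` cm^-1."""
    mask = np.abs(spec.wavenumbers - nominal) <= half_window
    if not mask.any():
        raise ValueError(f"no grid points within {nominal} +/- {half_window}")
    return float(spec.absorbance[mask].max())


def oxidation_indices(spec: Spectrum,
                      half_window: float = DEFAULT_HALF_WINDOW) -> pd.Series:
    """The four peak-height ratios I_725/I_1410 ... I_1711/I_1410."""
    reference = peak_height(spec, REFERENCE_WAVENUMBER, half_window)
    if reference <= 0:
        raise ValueError("reference peak height at 1410 cm^-1 is not positive")
    out = {
        f"I{int(w)}/I{int(REFERENCE_WAVENUMBER)}":
            peak_height(spec, w, half_window) / reference
        for w in RATIO_WAVENUMBERS
    }
    return pd.Series(out, name=spec.sample_id or None)


def compare_groups(indices_a: pd.DataFrame, indices_b: pd.DataFrame,
                   alpha: float = 0.05, welch: bool = False) -> pd.DataFrame:
    """Two-independent-sample t-test per oxidation ratio.

    ``indices_a``/``indices_b`` are spectra x ratio tables (rows = spectra
    of one group).  Pooled-variance Student's t by default; Welch optional.
    """
    if len(indices_a) < 2 or len(indices_b) < 2:
        raise ValueError("need at least two spectra per group")
    rows = []
    for ratio in indices_a.columns:
        a = indices_a[ratio].to_numpy(dtype=float)
        b = indices_b[ratio].to_numpy(dtype=float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            raise ValueError(f"t undefined for {ratio}: zero variance, equal means")
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append({
            "ratio": ratio,
            "mean_a": a.mean(), "sd_a": a.std(ddof=1),
            "mean_b": b.mean(), "sd_b": b.std(ddof=1),
            "t": float(t), "p_value": float(p),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows).set_index("ratio")
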
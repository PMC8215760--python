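"""Principal response curves (PRC).

PRC is a partial redundancy analysis of (log-transformed) abundance on the
treatment x time interaction, with time as the conditioning variable.  Axis
1 yields one canonical coefficient c_dt per non-control treatment d and
time t — the treatment's deviation from the control at that time — and one
weight b_k per taxon; the rank-1 product c_dt * b_k approximates the
conditioned, fitted response.  The control curve is identically zero.

Because the natural "no effect" value of a multiplicative weight display is
1 rather than 0, the reported weight is exp(b_k); the raw canonical loading
is always retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix


@dataclass
class PRCResult:
    curves: pd.DataFrame           # treatments (incl. control) x times, c_dt
    weights: pd.DataFrame          # per taxon: raw_weight, reported_weight
    variance_explained: float      # axis-1 share of the conditioned variance
    control: str
    log_offset: float | None = None


def log_transform(counts, offset: float = 1.0) -> pd.DataFrame:
    """ln(count + offset); zeros map to ln(offset)."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    values = counts.counts if isinstance(counts, CountMatrix) else counts
    if (np.asarray(values) < 0).any():
        raise ValueError("negative counts")
    return np.log(values + offset)


def prc_fit(y: pd.DataFrame, treatments, times, control_label: str,
            log_offset: float | None = None) -> PRCResult:
    """Fit the PRC model.

    Parameters
    ----------
    y
        Transformed response, taxa x samples.
    treatments, times
        Per-sample labels, aligned with the columns of ``y`` (anything
        :class:`pandas.Series`-like; plain sequences are taken in column
        order).
    control_label
        The treatment whose curve is the zero reference.

    Algorithm: centre responses within each time point, regress on
    treatment x time indicators (control excluded) by least squares, and
    take the leading singular triplet of the fitted values.  c_dt is the
    axis-1 score of cell (d, t) and b_k the axis-1 taxon loading (unit
    norm), so c_dt * b_k reproduces the rank-1 approximation of the fitted
    matrix.  The axis sign is fixed so the treatment with the largest mean
    |c_dt| has a positive mean curve.
    """
    treatments = pd.Series(np.asarray(treatments), index=y.columns)
    times = pd.Series(np.asarray(times), index=y.columns)
    if control_label not in set(treatments):
        raise ValueError(f"control treatment {control_label!r} not present")
    time_levels = sorted(set(times))
    treat_levels = [t for t in pd.unique(treatments) if t != control_label]
    for d in treat_levels + [control_label]:
        for t in time_levels:
            if not ((treatments == d) & (times == t)).any():
                raise ValueError(f"missing treatment-time cell: ({d!r}, {t!r})")

    resp = y.T.astype(float)  # samples x taxa
    centred = resp.copy()
    for t in time_levels:
        mask = (times == t).to_numpy()
        centred.iloc[mask] = resp.iloc[mask] - resp.iloc[mask].mean(axis=0)

    cells = [(d, t) for d in treat_levels for t in time_levels]
    x = np.zeros((len(resp), len(cells)))
    for j, (d, t) in enumerate(cells):
        x[:, j] = ((treatments == d) & (times == t)).to_numpy(dtype=float)

    coef, *_ = np.linalg.lstsq(x, centred.to_numpy(), rcond=None)
    fitted = x @ coef
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    if s[0] <= 0:
        b = np.zeros(y.shape[0])
        scores = np.zeros(len(cells))
        var_explained = 0.0
    else:
        b = vt[0]
        scores = coef @ b
        var_explained = float(s[0] ** 2 / (s**2).sum())

    curves = pd.DataFrame(0.0, index=[control_label] + treat_levels,
                          columns=time_levels)
    for (d, t), c in zip(cells, scores):
        curves.loc[d, t] = c

    # sign convention: the treatment with the largest mean |c_dt| is positive
    if len(treat_levels):
        strongest = curves.loc[treat_levels].abs().mean(axis=1).idxmax()
        if curves.loc[strongest].mean() < 0:
            curves.loc[treat_levels] *= -1.0
            b = -b

    weights = pd.DataFrame(
        {"raw_weight": b, "reported_weight": np.exp(b)}, index=y.index
    )
    return PRCResult(curves, weights, var_explained, control_label, log_offset)


def driver_taxa(result: PRCResult, y: pd.DataFrame,
                min_sum_log_abundance: float = 100.0,
                upper: float = 2.0, lower: float = 0.9) -> pd.DataFrame:
    """Label retained taxa as positive/negative drivers or neutral.

    Taxa are retained when their sum of (transformed) abundance over all
    samples exceeds ``min_sum_log_abundance``.  On the reported-weight
    scale, weights above ``upper`` mark positive drivers and weights below
    ``lower`` negative drivers; the rest are neutral.
    """
    if not np.isfinite([min_sum_log_abundance, upper, lower]).all():
        raise ValueError("thresholds must be finite")
    sums = y.sum(axis=1)
    keep = sums[sums > min_sum_log_abundance].index
    table = result.weights.loc[keep].copy()
    table["sum_log_abundance"] = sums.loc[keep]
    rep = table["reported_weight"]
    table["driver"] = np.select(
        [rep > upper, rep < lower], ["positive", "negative"], default="neutral"
    )
    return table
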
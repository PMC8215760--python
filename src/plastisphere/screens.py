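"""Proteomic differential screening and 16S-identity biogeography.

The proteomic screen computes per-protein fold changes and pooled-variance
t-tests between two conditions of an intensity table, plus relative
abundance within each proteome.  The biogeography screen matches a query
organism's 16S gene against community ASVs at identity thresholds, sums the
relative abundance of all matches per sample, and reduces geolocated
samples to the best sample per 5x5-degree latitude/longitude cell.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from ._align import percent_identity

DEFAULT_THRESHOLDS = (90.0, 95.0, 97.0, 99.0)


def relative_abundance(intensities: pd.DataFrame) -> pd.DataFrame:
    """Each protein's share of its sample total, in percent."""
    totals = intensities.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero samples: {bad}")
    return intensities.div(totals, axis=1) * 100.0


def differential(intensities: pd.DataFrame, conditions: pd.Series,
                 condition_a: str, condition_b: str) -> pd.DataFrame:
    """Fold change B/A and Student's t-test per protein.

    Zero condition means are replaced by the smallest nonzero protein mean
    in the matrix (pseudo-floor) and flagged.
    """
    conditions = pd.Series(conditions).reindex(intensities.columns)
    for cond in (condition_a, condition_b):
        if (conditions == cond).sum() < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")
    a_cols = list(conditions.index[conditions == condition_a])
    b_cols = list(conditions.index[conditions == condition_b])
    a = intensities[a_cols]
    b = intensities[b_cols]

    all_means = intensities.mean(axis=1)
    nonzero = all_means[all_means > 0]
    floor = float(nonzero.min()) if len(nonzero) else 1.0

    rel = relative_abundance(intensities)
    rows = []
    for protein in intensities.index:
        mean_a, mean_b = float(a.loc[protein].mean()), float(b.loc[protein].mean())
        floored = mean_a == 0.0 or mean_b == 0.0
        fc = (mean_b if mean_b > 0 else floor) / (mean_a if mean_a > 0 else floor)
        va = a.loc[protein].to_numpy(dtype=float)
        vb = b.loc[protein].to_numpy(dtype=float)
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if mean_a == mean_b else (math.inf, 0.0)
        else:
            t, p = stats.ttest_ind(va, vb, equal_var=True)
        rows.append({
            "protein": protein, "condition_pair": f"{condition_a}->{condition_b}",
            "fold_change": fc, "floored": floored,
            "t": float(t), "p_value": float(p),
            "rel_abundance_a": float(rel.loc[protein, a_cols].mean()),
            "rel_abundance_b": float(rel.loc[protein, b_cols].mean()),
        })
    return pd.DataFrame(rows).set_index("protein")


def pairwise_identity(query: str, subject: str) -> float:
    """Percent identity of two 16S sequences under global alignment."""
    return percent_identity(query, subject)


def match_and_sum(query_seq: str, rel: pd.DataFrame, asv_seqs: dict[str, str],
                  thresholds=DEFAULT_THRESHOLDS,
                  prefilter: float = 90.0) -> pd.DataFrame:
    """Summed relative abundance of ASVs matching the query, per threshold.

    An ASV matches at threshold ``t`` when its percent identity with the
    query is strictly above ``t``.  Only ASVs above ``prefilter`` percent
    identity are considered at all.  Returns samples x thresholds.
    """
    thresholds = sorted(thresholds)
    idents = {}
    for asv in rel.index:
        seq = asv_seqs.get(asv)
        if seq is None:
            continue
        ident = pairwise_identity(query_seq, seq)
        if ident > min(prefilter, thresholds[0]):
            idents[asv] = ident
    out = {}
    for thr in thresholds:
        matched = [a for a, ident in idents.items() if ident > thr]
        out[thr] = rel.loc[matched].sum(axis=0) if matched else pd.Series(
            0.0, index=rel.columns
        )
    return pd.DataFrame(out)


def grid_max(samples: pd.DataFrame, value_col: str = "summed_abundance",
             cell_size: float = 5.0) -> pd.DataFrame:
    """Best sample per latitude/longitude cell.

    ``samples`` needs columns ``latitude``, ``longitude`` and ``value_col``,
    indexed by sample id.  Cells are floor-aligned to multiples of
    ``cell_size``; ties go to the lexicographically smallest sample id.
    """
    lat = samples["latitude"].to_numpy(dtype=float)
    lon = samples["longitude"].to_numpy(dtype=float)
    if ((lat < -90) | (lat > 90)).any() or ((lon < -180) | (lon > 180)).any():
        raise ValueError("coordinates outside [-90, 90] x [-180, 180]")
    cells = samples.assign(
        cell_lat=np.floor(lat / cell_size) * cell_size,
        cell_lon=np.floor(lon / cell_size) * cell_size,
    )
    rows = []
    for (clat, clon), grp in cells.groupby(["cell_lat", "cell_lon"]):
        best_value = grp[value_col].max()
        winners = grp.index[grp[value_col] == best_value]
        best = min(winners)
        row = {"cell_lat": clat, "cell_lon": clon, "sample": best,
               value_col: float(best_value)}
        if "sample_type" in grp.columns:
            row["sample_type"] = grp.loc[best, "sample_type"]
        rows.append(row)
    return pd.DataFrame(rows)
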
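"""Community ecology statistics: depth filtering, diversity, Bray-Curtis
distance and permutation tests (ANOSIM, PERMANOVA).

Permutation p-values use the add-one correction
``p = (1 + #{permuted >= observed}) / (n_permutations + 1)`` so the
smallest attainable p at 999 permutations is 0.001.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .containers import CountMatrix, PermTestResult, validate_relative_abundance

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 999


def filter_low_depth(counts: CountMatrix, min_reads: int = 1000) -> CountMatrix:
    """Drop samples whose total read count is strictly below ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depths = counts.depths()
    keep = depths[depths >= min_reads].index
    removed = [s for s in counts.samples if s not in set(keep)]
    if not len(keep):
        raise ValueError(f"all samples below the {min_reads}-read threshold")
    if removed:
        logger.info("removed %d low-depth samples (<%d reads): %s",
                    len(removed), min_reads, removed)
    return counts.subset_samples([s for s in counts.samples if s in set(keep)])


def diversity_metrics(rel: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Simpson's index of diversity (1 - sum p^2) and richness."""
    validate_relative_abundance(rel)
    simpson = 1.0 - (rel**2).sum(axis=0)
    richness = (rel > 0).sum(axis=0)
    return pd.DataFrame({"simpson": simpson, "richness": richness})


def bray_curtis(rel: pd.DataFrame):
    """Bray-Curtis dissimilarity, d(a,b) = sum|a-b| / sum(a+b).

    Returns a :class:`skbio.DistanceMatrix` labelled by sample id.
    """
    if rel.shape[1] < 2:
        raise ValueError("need at least two samples")
    zero_cols = rel.columns[(rel.sum(axis=0) == 0)]
    if len(zero_cols) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero samples: {list(zero_cols)}"
        )
    from skbio import DistanceMatrix

    condensed = pdist(rel.values.T, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(rel.columns))


def _group_masks(dm, groups) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    groups = pd.Series(groups)
    if hasattr(dm, "ids"):
        data = np.asarray(dm.data)
        if not groups.index.equals(pd.RangeIndex(len(groups))):
            groups = groups.reindex(list(dm.ids))
    else:
        data = np.asarray(dm)
    if groups.isna().any():
        raise ValueError("group label missing for some samples")
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    if (sizes < 2).any():
        raise ValueError(f"groups with a single sample: {list(sizes[sizes < 2].index)}")
    return data, groups.to_numpy(), groups


def _anosim_r(ranks: np.ndarray, codes: np.ndarray, iu) -> float:
    same = codes[iu[0]] == codes[iu[1]]
    n = len(codes)
    m = n * (n - 1) // 2
    return float((ranks[~same].mean() - ranks[same].mean()) / (m / 2.0))


def _permutations(codes: np.ndarray, n_permutations: int, exhaustive: bool,
                  seed: int | None):
    """Yield permuted label vectors plus the p-value denominator offset.

    Random mode draws ``n_permutations`` shuffles and applies the add-one
    correction.  Exhaustive mode enumerates every distinct relabelling
    (identity included, no correction) — only sensible for small n.
    """
    if exhaustive:
        from itertools import permutations as iperm

        if len(codes) > 9:
            raise ValueError("exhaustive enumeration is limited to n <= 9")
        distinct = sorted(set(iperm(codes.tolist())))
        return [np.array(p) for p in distinct], 0
    rng = np.random.default_rng(seed)
    return [rng.permutation(codes) for _ in range(n_permutations)], 1


def anosim(dm, groups, n_permutations: int = DEFAULT_PERMUTATIONS,
           seed: int | None = None, exhaustive: bool = False) -> PermTestResult:
    """ANOSIM: rank-based contrast of between- vs within-group distances.

    R = (mean between-rank - mean within-rank) / (M/2) with
    M = n(n-1)/2; R = 1 means complete separation.  The p-value is the
    add-one-corrected fraction of label permutations with R at least as
    large as observed; with ``exhaustive=True`` every distinct relabelling
    is enumerated instead and p is exact.
    """
    data, codes, _ = _group_masks(dm, groups)
    n = data.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(data[iu])  # average ranks for ties
    observed = _anosim_r(ranks, codes, iu)

    perms, offset = _permutations(codes, n_permutations, exhaustive, seed)
    hits = sum(1 for perm in perms if _anosim_r(ranks, perm, iu) >= observed)
    p = (offset + hits) / (len(perms) + offset)
    return PermTestResult("anosim", observed, p, len(perms), seed)


def _permanova_f(sq: np.ndarray, codes: np.ndarray, iu) -> float:
    n = sq.shape[0]
    labels, counts = np.unique(codes, return_counts=True)
    ss_total = sq[iu].sum() / n
    ss_within = 0.0
    for lab, size in zip(labels, counts):
        mask = codes == lab
        sub = sq[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(size, k=1)].sum() / size
    ss_between = ss_total - ss_within
    a = len(labels)
    if ss_within <= 0:
        raise ValueError("degenerate distances: within-group sum of squares is zero")
    return float((ss_between / (a - 1)) / (ss_within / (n - a)))


def permanova(dm, groups, n_permutations: int = DEFAULT_PERMUTATIONS,
              seed: int | None = None, exhaustive: bool = False) -> PermTestResult:
    """PERMANOVA pseudo-F from the partition of squared distances."""
    data, codes, _ = _group_masks(dm, groups)
    sq = data**2
    n = data.shape[0]
    iu = np.triu_indices(n, k=1)
    observed = _permanova_f(sq, codes, iu)

    perms, offset = _permutations(codes, n_permutations, exhaustive, seed)
    hits = sum(1 for perm in perms if _permanova_f(sq, perm, iu) >= observed)
    p = (offset + hits) / (len(perms) + offset)
    return PermTestResult("permanova", observed, p, len(perms), seed)
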
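"""Core in-memory containers for community data.

The central object is :class:`CountMatrix`, an integer taxa x samples table
with per-sample metadata (treatment, day, replicate).  Relative abundances
are plain :class:`pandas.DataFrame` objects whose columns sum to one (or are
all zero for an empty sample); distance matrices use
:class:`skbio.DistanceMatrix` where scikit-bio is available, otherwise a
plain symmetric DataFrame is accepted by all downstream functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_METADATA = ("treatment", "day", "replicate")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class CountMatrix:
    """Integer ASV x sample count table with aligned sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows = taxa (ASV ids),
        columns = sample ids.
    metadata
        DataFrame indexed by sample id with at least the columns
        ``treatment`` (str), ``day`` (int) and ``replicate`` (int).
        Extra columns (e.g. ``latitude``/``longitude``) are preserved.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate taxon ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        if (np.asarray(self.counts.values) < 0).any():
            raise ValidationError("negative counts are not allowed")
        missing = [c for c in REQUIRED_METADATA if c not in self.metadata.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        if set(self.counts.columns) != set(self.metadata.index):
            raise ValidationError("metadata rows do not match count-matrix samples")
        # keep metadata in sample order
        self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def depths(self) -> pd.Series:
        """Per-sample read depth (column sums)."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Column-normalised relative abundances; all-zero samples stay zero."""
        depths = self.depths()
        safe = depths.replace(0, 1)
        return self.counts.div(safe, axis=1)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(
            self.counts[sample_ids].copy(), self.metadata.loc[sample_ids].copy()
        )


def validate_relative_abundance(rel: pd.DataFrame, tol: float = 1e-9) -> None:
    """Check that every column sums to 1 (or is all zero)."""
    sums = rel.sum(axis=0)
    bad = sums[(sums != 0) & ((sums - 1.0).abs() > tol)]
    if len(bad):
        raise ValidationError(
            f"columns not normalised to 1: {list(bad.index[:5])} (sums {bad.values[:5]})"
        )


@dataclass
class PermTestResult:
    """Result of a permutation test on a distance matrix."""

    method: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value out of (0, 1]: {self.p_value}")


@dataclass
class Ordination:
    """Non-metric MDS solution: sample coordinates plus Kruskal stress-1."""

    coordinates: pd.DataFrame  # samples x k
    stress: float
    n_starts: int
    converged: bool
    stress_history: list = field(default_factory=list)
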
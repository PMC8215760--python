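"""Trait-table augmentation and nearest-sequenced-taxon gene prediction.

A genome x gene-family copy-number table is extended with custom families
found by a profile-HMM search.  Each community ASV is assigned to the
reference genome with the highest global 16S identity; the nearest sequenced
taxon index (NSTI) is proxied by 1 - identity.  Per-sample gene-family
abundances are the relative-abundance-weighted copy numbers of the nearest
genomes, the weighted NSTI is the abundance-weighted mean NSTI over
assigned ASVs, and contributions decompose each predicted abundance by
taxon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import global_identity

logger = logging.getLogger(__name__)


@dataclass
class TraitMatrix:
    """Genome x gene-family non-negative integer copy counts."""

    table: pd.DataFrame
    custom_families: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        values = np.asarray(self.table.values)
        if (values < 0).any():
            raise ValueError("trait copy counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("trait copy counts must be integral")

    @property
    def genomes(self) -> pd.Index:
        return self.table.index

    @property
    def families(self) -> pd.Index:
        return self.table.columns


def augment_traits(traits: TraitMatrix, hit_counts: pd.Series, family_name: str,
                   overwrite: bool = False) -> TraitMatrix:
    """Append a custom family column of per-genome copy counts.

    Genomes present in ``hit_counts`` but absent from the trait table are
    dropped with a warning; trait genomes without a hit count get zero.
    """
    if family_name in traits.families and not overwrite:
        raise ValueError(
            f"family {family_name!r} already present (pass overwrite=True)"
        )
    extra = [g for g in hit_counts.index if g not in set(traits.genomes)]
    if extra:
        logger.warning("dropping %d hit genomes absent from trait table: %s",
                       len(extra), extra[:5])
    column = hit_counts.reindex(traits.genomes).fillna(0).astype(int)
    table = traits.table.copy()
    table[family_name] = column
    return TraitMatrix(table, traits.custom_families | {family_name})


def restrict_to_reference(genome_ids, reference_ids) -> list[str]:
    """Intersection of a genome database with an available reference set."""
    inter = sorted(set(genome_ids) & set(reference_ids))
    if not inter:
        raise ValueError("no genomes shared between database and reference set")
    logger.info("restricted %d database genomes to %d with references",
                len(set(genome_ids)), len(inter))
    return inter


def identity_matrix(asv_seqs: dict[str, str],
                    reference_16s: dict[str, str]) -> pd.DataFrame:
    """Global-alignment identity of every ASV against every reference 16S."""
    if not reference_16s:
        raise ValueError("empty reference set")
    genomes = sorted(reference_16s)
    rows = {
        asv: [global_identity(seq, reference_16s[g]) for g in genomes]
        for asv, seq in asv_seqs.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=genomes)


def assign_nearest(asv_seqs: dict[str, str], reference_16s: dict[str, str],
                   identities: pd.DataFrame | None = None) -> pd.DataFrame:
    """Nearest reference genome per ASV with NSTI = 1 - identity.

    Ties go to the lexicographically smallest genome id.  A precomputed
    ``identities`` table (from :func:`identity_matrix`) is reused if given.
    """
    if identities is None:
        identities = identity_matrix(asv_seqs, reference_16s)
    rows = []
    for asv in identities.index:
        ident = identities.loc[asv]
        best = ident.max()
        genome = min(ident.index[ident == best])  # lexicographic tie-break
        rows.append({"asv": asv, "genome": genome, "identity": float(best),
                     "nsti": float(1.0 - best)})
    return pd.DataFrame(rows).set_index("asv")


@dataclass
class PredictionResult:
    gene_abundance: pd.DataFrame   # families x samples
    weighted_nsti: pd.Series       # per sample
    assignments: pd.DataFrame      # per ASV: genome, identity, nsti


def predict_genes(rel: pd.DataFrame, assignments: pd.DataFrame,
                  traits: TraitMatrix) -> PredictionResult:
    """Per-sample gene-family abundances from nearest-genome copy numbers.

    abundance(sample, family) = sum over assigned ASVs of
    relabund(ASV, sample) * copies(family, nearest genome of ASV);
    weighted NSTI = sum p_i * n_i / sum p_i over assigned ASVs.  ASVs
    without an assignment are excluded from both sums.
    """
    assigned = [a for a in rel.index if a in assignments.index]
    if len(assigned) < len(rel.index):
        logger.info("%d of %d ASVs unassigned; excluded from prediction",
                    len(rel.index) - len(assigned), len(rel.index))
    sub = rel.loc[assigned]
    genomes = assignments.loc[assigned, "genome"]
    copies = traits.table.reindex(genomes).fillna(0).to_numpy(dtype=float)
    abundance = pd.DataFrame(
        copies.T @ sub.to_numpy(), index=traits.families, columns=rel.columns
    )
    nsti = assignments.loc[assigned, "nsti"].to_numpy()
    weights = sub.to_numpy()
    totals = weights.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        wn = (weights * nsti[:, None]).sum(axis=0) / totals
    weighted = pd.Series(wn, index=rel.columns, name="weighted_nsti")
    return PredictionResult(abundance, weighted, assignments.loc[assigned])


def fold_change_vs_control(gene_abundance: pd.DataFrame, metadata: pd.DataFrame,
                           control_label: str,
                           inoculum_label: str | None = None) -> pd.DataFrame:
    """Fold change of replicate-mean predicted abundance vs the control.

    FC(treatment, day, family) = mean over replicates at (treatment, day)
    divided by the control mean on the same day.  The inoculum (a single
    time-course-free treatment) is compared against the mean of *all*
    control samples.  Zero denominators are replaced by the smallest
    nonzero predicted abundance in the table and flagged.
    """
    treatments = metadata["treatment"]
    if control_label not in set(treatments):
        raise ValueError(f"control treatment {control_label!r} missing")
    floor_pool = gene_abundance.to_numpy()
    nonzero = floor_pool[floor_pool > 0]
    floor = float(nonzero.min()) if len(nonzero) else 1.0

    control_samples = metadata.index[treatments == control_label]
    control_by_day = {
        int(day): gene_abundance[list(meta.index)].mean(axis=1)
        for day, meta in metadata.loc[control_samples].groupby("day")
    }
    control_overall = gene_abundance[list(control_samples)].mean(axis=1)

    rows = []
    for (treatment, day), meta in metadata.groupby(["treatment", "day"]):
        mean = gene_abundance[list(meta.index)].mean(axis=1)
        if treatment == inoculum_label:
            denom = control_overall
        else:
            if int(day) not in control_by_day:
                raise ValueError(f"control missing on day {day}")
            denom = control_by_day[int(day)]
        for family in gene_abundance.index:
            d = float(denom[family])
            floored = d == 0.0
            rows.append({
                "treatment": treatment, "day": int(day), "family": family,
                "fold_change": float(mean[family]) / (floor if floored else d),
                "floored": floored,
            })
    return pd.DataFrame(rows)


def taxon_contributions(rel: pd.DataFrame, assignments: pd.DataFrame,
                        traits: TraitMatrix,
                        group_threshold: float = 0.005) -> pd.DataFrame:
    """Decompose predicted family abundance into per-taxon contributions.

    contribution(sample, family, taxon) = relabund * copies(nearest genome).
    Taxa whose share of a family's total contribution (summed over samples)
    is below ``group_threshold`` are merged into ``'Other'``.  Per
    sample-family cell the contributions (including 'Other') sum exactly to
    the predicted abundance.
    """
    assigned = [a for a in rel.index if a in assignments.index]
    genomes = assignments.loc[assigned, "genome"]
    copies = traits.table.reindex(genomes).fillna(0)
    copies.index = assigned
    records = []
    for family in traits.families:
        contrib = rel.loc[assigned].mul(copies[family], axis=0)  # taxa x samples
        totals = contrib.sum(axis=1)
        grand = float(totals.sum())
        if grand > 0:
            minor = totals[totals / grand < group_threshold].index
        else:
            minor = pd.Index([])
        major = [t for t in contrib.index if t not in set(minor)]
        for taxon in major:
            for sample in contrib.columns:
                records.append({"sample": sample, "family": family,
                                "taxon": taxon,
                                "contribution": float(contrib.at[taxon, sample])})
        if len(minor):
            other = contrib.loc[minor].sum(axis=0)
            for sample in contrib.columns:
                records.append({"sample": sample, "family": family,
                                "taxon": "Other",
                                "contribution": float(other[sample])})
    return pd.DataFrame(records)


def closest_trait_bearer(asv: str, identities: pd.DataFrame,
                         traits: TraitMatrix, family: str) -> str:
    """Nearest reference genome that carries >= 1 copy of ``family``."""
    if family not in traits.families:
        raise ValueError(f"unknown family {family!r}")
    carriers = traits.table.index[traits.table[family] >= 1]
    if not len(carriers):
        raise ValueError(f"no genome carries family {family!r}")
    ident = identities.loc[asv, list(carriers)]
    best = ident.max()
    return min(ident.index[ident == best])
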
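"""Coloniser succession: peak-day classification and heatmap matrices.

A taxon is an early, middle or late coloniser of a treatment according to
the sampling day on which its replicate-mean relative abundance peaks:
days 1-7 early, 14-30 middle, 42 late.  Per treatment, only taxa whose
mean relative abundance exceeds an inclusion threshold (default 0.5%) at
one or more time points are classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARLY_DAYS = (1, 7)
MIDDLE_DAYS = (14, 30)
LATE_DAY = 42


@dataclass
class ColoniserReport:
    per_treatment: dict[str, pd.DataFrame]  # taxon -> peak_day, class
    mean_peak_day: pd.Series                # across treatments where included
    heatmaps: dict[str, pd.DataFrame]       # per treatment, normalised & ordered


def classify_coloniser(peak_day: int) -> str:
    """early for days 1-7, middle for 14-30, late for 42."""
    if EARLY_DAYS[0] <= peak_day <= EARLY_DAYS[1]:
        return "early"
    if MIDDLE_DAYS[0] <= peak_day <= MIDDLE_DAYS[1]:
        return "middle"
    if peak_day >= LATE_DAY:
        return "late"
    raise ValueError(f"day {peak_day} outside the coloniser bins")


def peak_day(profile: pd.Series) -> int:
    """Day of maximum abundance; ties broken to the earliest day."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    if (profile <= 0).all():
        raise ValueError("all-zero profile has no peak")
    profile = profile.sort_index()
    return int(profile.index[int(np.argmax(profile.to_numpy()))])


def mean_profiles(rel: pd.DataFrame, metadata: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Replicate means per treatment: {treatment: taxa x day DataFrame}."""
    out: dict[str, pd.DataFrame] = {}
    full_reps = int(metadata.groupby(["treatment", "day"]).size().max())
    for treatment, meta_t in metadata.groupby("treatment"):
        cols = {}
        for day, meta_td in meta_t.groupby("day"):
            samples = list(meta_td.index)
            if not samples:
                raise ValueError(f"no replicates for ({treatment}, day {day})")
            if len(samples) < full_reps:
                logger.info("(%s, day %s): mean of %d replicates", treatment,
                            day, len(samples))
            cols[int(day)] = rel[samples].mean(axis=1)
        out[str(treatment)] = pd.DataFrame(cols).sort_index(axis=1)
    return out


def include_taxa(profile: pd.DataFrame, min_abund: float = 0.005) -> pd.Index:
    """Taxa whose mean abundance is strictly above ``min_abund`` on >= 1 day."""
    if not (0 <= min_abund < 1):
        raise ValueError("min_abund must be in [0, 1)")
    return profile.index[(profile > min_abund).any(axis=1)]


def heatmap_matrix(profile: pd.DataFrame, included: pd.Index,
                   order_by: pd.Series | None = None) -> pd.DataFrame:
    """Max-normalise each included taxon's profile and sort by peak day.

    ``order_by`` (taxon -> mean peak day) overrides the per-treatment peak
    days for ordering, so all treatments can share the global order.
    """
    sub = profile.loc[included].copy()
    maxima = sub.max(axis=1)
    norm = sub.div(maxima.replace(0, 1), axis=0)
    if order_by is None:
        order_by = pd.Series({t: peak_day(norm.loc[t]) for t in norm.index})
    keys = order_by.reindex(norm.index)
    return norm.loc[keys.sort_values(kind="stable").index]


def colonisers(rel: pd.DataFrame, metadata: pd.DataFrame,
               min_abund: float = 0.005) -> ColoniserReport:
    """Full succession analysis over all treatments.

    Returns per-treatment classification tables (taxon, peak_day, class),
    the cross-treatment mean peak day (over treatments where the taxon was
    included) and per-treatment max-normalised heatmap matrices ordered by
    that mean peak day.
    """
    profiles = mean_profiles(rel, metadata)
    per_treatment: dict[str, pd.DataFrame] = {}
    peaks: dict[str, dict[str, int]] = {}
    for treatment, profile in profiles.items():
        included = include_taxa(profile, min_abund)
        rows = []
        for taxon in included:
            day = peak_day(profile.loc[taxon])
            rows.append({"taxon": taxon, "peak_day": day,
                         "class": classify_coloniser(day)})
            peaks.setdefault(taxon, {})[treatment] = day
        per_treatment[treatment] = (
            pd.DataFrame(rows, columns=["taxon", "peak_day", "class"])
            .set_index("taxon")
        )
    mean_peak = pd.Series(
        {t: float(np.mean(list(days.values()))) for t, days in peaks.items()},
        name="mean_peak_day",
    ).sort_values(kind="stable")
    heatmaps = {
        t: heatmap_matrix(profiles[t], per_treatment[t].index, order_by=mean_peak)
        for t in profiles
    }
    return ColoniserReport(per_treatment, mean_peak, heatmaps)
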
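"""Profile hidden Markov models for protein gene-family search.

A profile is built from a seed multiple alignment: columns with at most 50%
gaps become match states, emissions get add-one pseudocounts over a uniform
background, and match/insert/delete transitions are estimated per position
from the alignment paths (again with add-one pseudocounts).  Sequences are
scored by local (free-flanking) Viterbi log-odds in bits — an alignment may
start and end at any match state, and unaligned flanking residues are
emitted by the background at zero cost.

E-values are calibrated per search: database sequences are shuffled to make
decoys, a Gumbel (extreme-value) distribution is fitted to the decoy score
distribution, and E(s) = N_db * P(S >= s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gumbel_r

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NEG = -np.inf


@dataclass
class ProfileHMM:
    """Match-state emission/transition model over the 20 amino acids.

    Transition arrays are indexed by source position ``j`` (0-based match
    states ``M_0 .. M_{m-1}``; ``D_j``/``I_j`` sit between ``M_j`` and
    ``M_{j+1}``), each of length ``m - 1``:

    - ``mm[j] + mi[j] + md[j] = 1`` (out of ``M_j``)
    - ``im[j] + ii[j] = 1`` (out of ``I_j``)
    - ``dm[j] + dd[j] = 1`` (out of ``D_j``)
    """

    match_emissions: np.ndarray      # (m, 20)
    insert_emissions: np.ndarray     # (20,)
    background: np.ndarray           # (20,)
    mm: np.ndarray
    mi: np.ndarray
    md: np.ndarray
    im: np.ndarray
    ii: np.ndarray
    dm: np.ndarray
    dd: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        m = self.n_match
        if m < 1:
            raise ValueError("profile needs at least one match state")
        for name in ("match_emissions",):
            sums = self.match_emissions.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        if m > 1:
            for a, b, label in (
                (self.mm + self.mi + self.md, 1.0, "match"),
                (self.im + self.ii, 1.0, "insert"),
                (self.dm + self.dd, 1.0, "delete"),
            ):
                if not np.allclose(a, b, atol=1e-9):
                    raise ValueError(f"{label}-state transitions must sum to 1")

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))


def _encode(seq: str) -> np.ndarray:
    bad = sorted({c for c in seq if c not in _AA_INDEX})
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {bad}")
    return np.fromiter((_AA_INDEX[c] for c in seq), dtype=int, count=len(seq))


def build_profile(alignment: dict[str, str], pseudocount: float = 1.0,
                  max_gap_fraction: float = 0.5, source: str = "") -> ProfileHMM:
    """Build a profile from an aligned FASTA-style mapping {id: row}.

    Columns whose gap fraction is <= ``max_gap_fraction`` become match
    states; the rest are treated as insertions.
    """
    rows = list(alignment.values())
    if len(rows) < 2:
        raise ValueError("seed alignment needs at least two sequences")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: unequal row lengths")
    width = lengths.pop()
    arr = np.array([list(r.upper()) for r in rows])
    gap_frac = np.mean((arr == "-") | (arr == "."), axis=0)
    match_cols = np.where(gap_frac <= max_gap_fraction)[0]
    m = len(match_cols)
    if m == 0:
        raise ValueError("no match columns under the gap-fraction rule")

    background = np.full(20, 1.0 / 20)
    emissions = np.full((m, 20), pseudocount)
    for k, col in enumerate(match_cols):
        for c in arr[:, col]:
            if c in _AA_INDEX:
                emissions[k, _AA_INDEX[c]] += 1.0
    emissions /= emissions.sum(axis=1, keepdims=True)

    # per-position transition counts from each sequence's path through the
    # match columns (insert events between consecutive match columns)
    is_match_col = np.zeros(width, dtype=bool)
    is_match_col[match_cols] = True
    col_to_state = {c: k for k, c in enumerate(match_cols)}
    tcounts = {key: np.full(max(m - 1, 1), pseudocount)
               for key in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    for row in arr:
        events: list[tuple[str, int]] = []
        for c in range(width):
            residue = row[c] in _AA_INDEX
            if is_match_col[c]:
                events.append(("M" if residue else "D", col_to_state[c]))
            elif residue:
                k = sum(1 for cc in match_cols if cc < c) - 1
                if 0 <= k < m - 1:
                    events.append(("I", k))
        for (s1, j1), (s2, j2) in zip(events, events[1:]):
            if s1 == "M" and j1 < m - 1:
                if s2 == "M" and j2 == j1 + 1:
                    tcounts["mm"][j1] += 1
                elif s2 == "I" and j2 == j1:
                    tcounts["mi"][j1] += 1
                elif s2 == "D" and j2 == j1 + 1:
                    tcounts["md"][j1] += 1
            elif s1 == "I":
                if s2 == "M" and j2 == j1 + 1:
                    tcounts["im"][j1] += 1
                elif s2 == "I" and j2 == j1:
                    tcounts["ii"][j1] += 1
            elif s1 == "D" and j1 < m - 1:
                if s2 == "M" and j2 == j1 + 1:
                    tcounts["dm"][j1] += 1
                elif s2 == "D" and j2 == j1 + 1:
                    tcounts["dd"][j1] += 1

    n = max(m - 1, 1)
    msum = tcounts["mm"] + tcounts["mi"] + tcounts["md"]
    isum = tcounts["im"] + tcounts["ii"]
    dsum = tcounts["dm"] + tcounts["dd"]
    return ProfileHMM(
        match_emissions=emissions,
        insert_emissions=background.copy(),
        background=background,
        mm=(tcounts["mm"] / msum)[:n], mi=(tcounts["mi"] / msum)[:n],
        md=(tcounts["md"] / msum)[:n],
        im=(tcounts["im"] / isum)[:n], ii=(tcounts["ii"] / isum)[:n],
        dm=(tcounts["dm"] / dsum)[:n], dd=(tcounts["dd"] / dsum)[:n],
        source=source,
    )


def _log_odds_tables(hmm: ProfileHMM):
    lo_match = np.log2(hmm.match_emissions / hmm.background)
    lo_insert = float(np.log2(hmm.insert_emissions / hmm.background).mean())
    with np.errstate(divide="ignore"):
        trans = {k: np.log2(getattr(hmm, k)) for k in
                 ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    return lo_match, lo_insert, trans


def score_sequence(hmm: ProfileHMM, sequence: str) -> float:
    """Local Viterbi log-odds score in bits (max over alignments)."""
    if not sequence:
        raise ValueError("empty sequence")
    obs = _encode(sequence)
    m = hmm.n_match
    lo_match, _, tr = _log_odds_tables(hmm)
    # insert emissions equal the background by default and then score zero;
    # a non-background insert model contributes per inserted residue
    ins_cost = float(np.log2(hmm.insert_emissions / hmm.background).max()) \
        if not np.allclose(hmm.insert_emissions, hmm.background) else 0.0

    prev_m = np.full(m, _NEG)
    prev_i = np.full(m, _NEG)
    prev_d = np.full(m, _NEG)
    best = _NEG
    if m > 1:
        s_dd = np.concatenate(([0.0], np.cumsum(tr["dd"])))  # S[j] = sum_{k<j} dd
    for a in obs:
        new_m = np.full(m, _NEG)
        # entry (free) or extension from the previous column
        stay = np.full(m, 0.0)
        if m > 1:
            from_m = np.concatenate(([_NEG], prev_m[:-1] + tr["mm"]))
            from_i = np.concatenate(([_NEG], prev_i[:-1] + tr["im"]))
            from_d = np.concatenate(([_NEG], prev_d[:-1] + tr["dm"]))
            stay = np.maximum.reduce([stay, from_m, from_i, from_d])
        new_m = lo_match[:, a] + stay
        new_i = np.full(m, _NEG)
        if m > 1:
            cand = np.maximum(prev_m[:-1] + tr["mi"], prev_i[:-1] + tr["ii"])
            new_i[:-1] = cand + ins_cost
        new_d = np.full(m, _NEG)
        if m > 1:
            base = new_m[:-1] + tr["md"] - s_dd[1:]
            run = np.maximum.accumulate(base)
            new_d[1:] = s_dd[1:] + run
        best = max(best, float(new_m.max()))
        prev_m, prev_i, prev_d = new_m, new_i, new_d
    return best


def forward_score(hmm: ProfileHMM, sequence: str) -> float:
    """Local forward (log-sum-exp over alignments) score in bits.

    Plain O(L * m^2) implementation intended for small profiles; useful as
    an upper bound on the Viterbi score.
    """
    if not sequence:
        raise ValueError("empty sequence")
    obs = _encode(sequence)
    m = hmm.n_match
    lo_match, _, tr = _log_odds_tables(hmm)

    def lse(vals):
        vals = [v for v in vals if v > _NEG]
        if not vals:
            return _NEG
        top = max(vals)
        return top + np.log2(sum(2.0 ** (np.array(vals) - top)))

    prev = None
    total = []
    for a in obs:
        cur_m = [_NEG] * m
        cur_i = [_NEG] * m
        cur_d = [_NEG] * m
        for j in range(m):
            inputs = [0.0]
            if prev is not None and j > 0:
                pm, pi, pdel = prev
                inputs += [pm[j - 1] + tr["mm"][j - 1],
                           pi[j - 1] + tr["im"][j - 1],
                           pdel[j - 1] + tr["dm"][j - 1]]
            cur_m[j] = lo_match[j, a] + lse(inputs)
        for j in range(m - 1):
            if prev is not None:
                pm, pi, _ = prev
                cur_i[j] = lse([pm[j] + tr["mi"][j], pi[j] + tr["ii"][j]])
        for j in range(1, m):
            cur_d[j] = lse([cur_m[j - 1] + tr["md"][j - 1],
                            cur_d[j - 1] + tr["dd"][j - 1]])
        total.extend(cur_m)
        prev = (cur_m, cur_i, cur_d)
    return float(lse(total))


def _shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def calibrate_and_search(
    hmm: ProfileHMM,
    proteomes: dict[str, dict[str, str]],
    e_cutoff: float = 0.01,
    seed: int | None = None,
    n_shuffles: int = 1,
    min_decoys: int = 100,
) -> tuple[pd.DataFrame, pd.Series]:
    """Score every protein, calibrate E-values on shuffled decoys, report hits.

    Returns ``(hits, per_genome_counts)``: a DataFrame with columns
    ``genome``, ``protein``, ``bit_score``, ``e_value``, ``threshold`` (one
    row per protein with E <= ``e_cutoff``) and a Series of hit counts per
    genome (zeros included).
    """
    rng = np.random.default_rng(seed)
    entries = [(g, pid, seq) for g, prots in sorted(proteomes.items())
               for pid, seq in sorted(prots.items()) if seq]
    n_db = len(entries)
    decoy_scores = []
    for _ in range(n_shuffles):
        for _, _, seq in entries:
            decoy_scores.append(score_sequence(hmm, _shuffle(seq, rng)))
    if len(decoy_scores) < min_decoys:
        raise ValueError(
            f"only {len(decoy_scores)} decoy scores; need >= {min_decoys} "
            "for a stable Gumbel fit (increase n_shuffles)"
        )
    loc, scale = gumbel_r.fit(decoy_scores)

    rows = []
    counts = {g: 0 for g in proteomes}
    for g, pid, seq in entries:
        score = score_sequence(hmm, seq)
        evalue = float(n_db * gumbel_r.sf(score, loc, scale))
        evalue = max(evalue, np.nextafter(0, 1))  # E-values are > 0
        if evalue <= e_cutoff:
            rows.append({"genome": g, "protein": pid, "bit_score": score,
                         "e_value": evalue, "threshold": e_cutoff})
            counts[g] += 1
    hits = pd.DataFrame(rows, columns=["genome", "protein", "bit_score",
                                       "e_value", "threshold"])
    return hits, pd.Series(counts, name="hit_count").sort_index()
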
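"""Global pairwise alignment and percent identity for 16S sequences.

Identity is defined over a global (Needleman-Wunsch) alignment with match
+1, mismatch -1, gap -2: identity = matches / aligned columns, where gap
columns count against identity and ``N`` matches nothing.  This definition
is deliberately explicit rather than inherited from a local-alignment
search tool, so partial overlaps are penalised.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

VALID_BASES = set("ACGTN")


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def _check(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"empty {label} sequence")
    seq = seq.upper()
    bad = sorted(set(seq) - VALID_BASES)
    if bad:
        raise ValueError(f"{label} sequence has non-ACGTN characters: {bad}")
    return seq


def global_identity(query: str, subject: str) -> float:
    """Fraction identity in [0, 1] over aligned columns (gaps mismatch)."""
    query = _check(query, "query")
    subject = _check(subject, "subject")
    alignment = _aligner().align(query, subject)[0]
    a, b = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x not in "-N")
    return matches / len(a)


def percent_identity(query: str, subject: str) -> float:
    """Percent identity in [0, 100]."""
    return 100.0 * global_identity(query, subject)
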
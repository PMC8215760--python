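"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts and traits travel as TSV, sequences as FASTA (via Biopython),
spectra as two-column CSV.  Floats are written with a fixed format so that
repeated runs produce byte-identical files.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix

FLOAT_FORMAT = "%.10g"


def read_counts(counts_path, metadata_path) -> CountMatrix:
    """Load a taxa x samples count TSV plus its sample metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.metadata.to_csv(metadata_path, sep="\t")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {id: sequence} preserving file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def read_spectrum_csv(path) -> pd.DataFrame:
    """Two-column CSV (wavenumber, absorbance) -> DataFrame."""
    df = pd.read_csv(path)
    expected = {"wavenumber", "absorbance"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: spectra CSV needs columns {sorted(expected)}")
    return df


def write_spectrum_csv(wavenumbers, absorbance, path) -> None:
    df = pd.DataFrame({"wavenumber": wavenumbers, "absorbance": absorbance})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
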
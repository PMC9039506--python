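"""Light wrappers around Biopython / pandas for the package's file formats.

All on-disk formats are plain text: FASTA references, FASTQ reads, and
tab-separated tables.  Sample columns in expression / intensity tables are
named with :attr:`graftmobile.design.GraftSample.key`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, reads: list[tuple[str, str]]) -> None:
    """Write (read id, sequence) pairs; a constant Q40 quality string is used."""
    records = []
    for name, seq in reads:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_tsv(path: str | Path, frame: pd.DataFrame, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
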
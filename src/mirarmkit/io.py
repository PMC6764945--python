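"""File I/O: FASTA/FASTQ via Biopython, tab-delimited tables via pandas,
and the JSON run manifest."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(records: Mapping[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Sequence[Tuple[str, str]], path) -> None:
    """Phred+33 FASTQ with a constant quality of 'I' (Q40)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_reads(path) -> List[Tuple[str, str]]:
    """Read a FASTQ or FASTA file of small-RNA reads."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fq", ".fastq")) else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(p, fmt)]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_manifest(path, params: Mapping, outputs: Iterable[str]) -> None:
    Path(path).write_text(
        json.dumps({"parameters": dict(params), "outputs": sorted(outputs)}, indent=2, default=str)
        + "\n"
    )
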
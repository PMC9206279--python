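"""FASTA and TSV plumbing shared by the CLI and the library surface."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scanner import G4Motif

__all__ = ["read_fasta", "write_fasta", "motifs_to_frame", "write_motifs_tsv"]

PathLike = Union[str, Path]

MOTIF_COLUMNS = [
    "query_id",
    "start",
    "end",
    "strand",
    "motif_seq",
    "q",
    "n_loops",
    "loop_min",
    "loop_max",
]


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a multi-record FASTA, wrapped or not."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def motifs_to_frame(motifs: Iterable[G4Motif]) -> pd.DataFrame:
    rows = []
    for m in motifs:
        topo = m.topology
        rows.append(
            {
                "query_id": m.query_id,
                "start": m.start,
                "end": m.end,
                "strand": m.strand,
                "motif_seq": m.motif_seq,
                "q": topo.q if topo else pd.NA,
                "n_loops": topo.n_loops if topo else pd.NA,
                "loop_min": topo.loop_min if topo else pd.NA,
                "loop_max": topo.loop_max if topo else pd.NA,
            }
        )
    return pd.DataFrame(rows, columns=MOTIF_COLUMNS)


def write_motifs_tsv(motifs: Iterable[G4Motif], path: PathLike) -> None:
    motifs_to_frame(motifs).to_csv(path, sep="\t", index=False)
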
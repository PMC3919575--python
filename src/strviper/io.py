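"""Thin IO helpers for FASTA, truth tables and edit tables."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import TruthRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_truth_table",
    "write_truth_table",
    "read_edit_table",
    "write_edit_table",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_truth_table(truth: Sequence[TruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(t.locus_id, t.true_delta_units, t.true_delta_bp) for t in truth],
        columns=["locus_id", "delta_units", "delta_bp"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthRecord(str(r.locus_id), int(r.delta_units), int(r.delta_bp))
        for r in df.itertuples()
    ]


def write_edit_table(edits: pd.DataFrame, path: str | Path) -> None:
    edits.to_csv(path, sep="\t", index=False)


def read_edit_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "ref_start": int, "ref_allele": str,
               "alt_allele": str, "kind": str, "donor_start": int},
    )
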
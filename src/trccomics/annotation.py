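"""Gene annotation (TSS table) and genome sequence I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ANNOTATION_COLUMNS = ("gene_id", "chrom", "tss", "strand")


@dataclass
class GeneAnnotationSet:
    """Table of genes with chromosome, 0-based TSS position and strand."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(ANNOTATION_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.table["gene_id"].duplicated().any():
            dup = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id: {dup}")
        bad = ~self.table["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand value: {self.table.loc[bad, 'strand'].iloc[0]!r}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    @property
    def chroms(self) -> set[str]:
        return set(self.table["chrom"].unique())

    def promoter_window(self, gene_id: str, flank: int = 1000) -> tuple[str, int, int]:
        """Half-open window of +/- ``flank`` bp around a gene's TSS."""
        row = self.table.set_index("gene_id").loc[gene_id]
        return row["chrom"], max(0, int(row["tss"]) - flank), int(row["tss"]) + flank

    def write_tsv(self, path: str | Path) -> None:
        self.table[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneAnnotationSet":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
        df["tss"] = df["tss"].astype(int)
        return cls(df)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a ``{name: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
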
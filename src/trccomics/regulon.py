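"""Core-regulon definition from multi-sample peak sets.

The "core program" of a fusion transcription factor is defined here as the
set of genes whose nearby binding sites satisfy, jointly:

1. *commonly bound* — the site is occupied in at least ``min_samples`` of the
   profiled cell lines (default: all of them);
2. *motif-positive* — the site sequence contains an M/E-box (CACGTG core by
   default), the cognate element of MiT/TFE bHLH-LZ factors;
3. *near a TSS* — the site midpoint lies within a strand-aware distance
   window of the gene's transcription start site;
4. *active chromatin* — for the extended program, the site also overlaps an
   H3K27ac peak in at least ``min_k27_samples`` samples.

Two gene programs are emitted: the *promoter program* (motif-positive common
sites within +/-500 bp of the TSS) and the *extended program* (motif-positive
common K27ac-marked sites within +/-30 kb of the TSS).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import GeneAnnotationSet
from .intervals import PeakCompendium, _overlaps_any, filter_commonly_bound, write_bed
from .motif import MEBOX, scan_motif


@dataclass
class RegulonConfig:
    """Thresholds of the core-program definition.

    Distances are in bp from the TSS to the site midpoint; ``flank`` widens
    the scanned sequence window beyond the site on both sides.
    """

    min_samples: int | None = None  # None -> all samples
    motif: str = MEBOX
    flank: int = 0
    min_k27_samples: int = 1
    proximal_bp: int = 500
    promoter_bp: int = 1000
    distal_bp: int = 30_000

    def distance_class(self, d: int) -> str:
        a = abs(d)
        if a <= self.proximal_bp:
            return "proximal_500"
        if a < self.promoter_bp:
            return "promoter_1k"
        if a > self.distal_bp:
            return "distal_30k"
        return "intermediate"


@dataclass
class CoreRegulon:
    """Qualifying sites plus the two derived gene programs."""

    sites: pd.DataFrame = field(repr=False)
    promoter_genes: set[str]
    extended_genes: set[str]
    criteria: dict

    @property
    def genes(self) -> set[str]:
        """The extended core program (the headline gene set)."""
        return self.extended_genes

    def summary(self) -> str:
        c = self.criteria
        lines = [
            "Core regulon",
            f"  commonly bound M/E-box sites : {len(self.sites)}",
            f"  promoter program genes       : {len(self.promoter_genes)}",
            f"  extended program genes       : {len(self.extended_genes)}",
            f"  criteria: min_samples={c['min_samples']}, motif={c['motif']}, "
            f"k27>={c['min_k27_samples']} sample(s), "
            f"windows {c['proximal_bp']}/{c['promoter_bp']}/{c['distal_bp']} bp",
        ]
        return "\n".join(lines)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write sites BED, regulon gene table and a criteria sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "sites_bed": directory / "core_sites.bed",
            "regulon_tsv": directory / "regulon.tsv",
            "criteria_json": directory / "criteria.json",
        }
        bed = self.sites.copy()
        bed["name"] = bed["nearest_gene"].fillna("none") + ":" + bed["distance_class"]
        write_bed(bed, paths["sites_bed"])
        rows = [
            {"gene_id": g, "program": prog}
            for prog, genes in (
                ("promoter", sorted(self.promoter_genes)),
                ("extended", sorted(self.extended_genes)),
            )
            for g in genes
        ]
        pd.DataFrame(rows, columns=["gene_id", "program"]).to_csv(
            paths["regulon_tsv"], sep="\t", index=False
        )
        with open(paths["criteria_json"], "w") as fh:
            json.dump(self.criteria, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def classify_tss_distance(
    sites: pd.DataFrame, annotation: GeneAnnotationSet, config: RegulonConfig | None = None
) -> pd.DataFrame:
    """Assign each site its nearest gene, signed TSS distance and class.

    Distance is measured from the TSS to the site midpoint and is
    strand-aware: negative means the site lies upstream of the TSS.  The
    nearest gene minimises |distance|; exact ties go to the
    lexicographically smallest gene_id.  Sites on chromosomes absent from
    the annotation get ``nearest_gene = None`` and are flagged.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    config = config or RegulonConfig()
    ann = annotation.table
    by_chrom: dict[str, tuple[np.ndarray, list[tuple[str, str]]]] = {}
    for chrom, sub in ann.groupby("chrom"):
        # genes sharing a TSS: keep the lexicographically smallest id per position
        sub = sub.sort_values(["tss", "gene_id"], kind="mergesort")
        dedup = sub.drop_duplicates("tss", keep="first")
        by_chrom[chrom] = (
            dedup["tss"].to_numpy(),
            list(zip(dedup["gene_id"], dedup["strand"])),
        )

    genes: list[str | None] = []
    dists: list[int] = []
    classes: list[str] = []
    flagged: list[bool] = []
    mids = ((sites["start"] + sites["end"]) // 2).to_numpy()
    for chrom, mid in zip(sites["chrom"], mids):
        if chrom not in by_chrom:
            genes.append(None)
            dists.append(0)
            classes.append("unassigned")
            flagged.append(True)
            continue
        positions, meta = by_chrom[chrom]
        idx = np.searchsorted(positions, mid)
        candidates = [i for i in (idx - 1, idx) if 0 <= i < len(positions)]
        best = min(
            candidates, key=lambda i: (abs(int(positions[i]) - int(mid)), meta[i][0])
        )
        gene_id, strand = meta[best]
        tss = int(positions[best])
        d = int(mid) - tss if strand == "+" else tss - int(mid)
        genes.append(gene_id)
        dists.append(d)
        classes.append(config.distance_class(d))
        flagged.append(False)
    out = sites.copy()
    out["nearest_gene"] = genes
    out["signed_tss_distance"] = dists
    out["distance_class"] = classes
    out["no_annotation"] = flagged
    return out


def _check_chrom_consistency(
    site_chroms: set[str], sequences: Mapping[str, str], annotation: GeneAnnotationSet
) -> None:
    seq_chroms = set(sequences)
    offenders = sorted(site_chroms - seq_chroms) + sorted(annotation.chroms - seq_chroms)
    if offenders:
        raise ValueError(
            "chromosome naming inconsistent across inputs; absent from the "
            f"genome sequence: {offenders}"
        )


def call_core_regulon(
    compendium: PeakCompendium,
    annotation: GeneAnnotationSet,
    sequences: Mapping[str, str],
    k27_sets: Mapping[str, pd.DataFrame],
    config: RegulonConfig | None = None,
) -> CoreRegulon:
    """Run the full core-program pipeline on a peak compendium.

    Steps: commonly-bound filter -> motif scan per site (+/- ``flank``) ->
    TSS-distance classification -> H3K27ac co-marking -> gene programs.
    """
    config = config or RegulonConfig()
    _check_chrom_consistency(set(compendium.union_sites["chrom"].unique()), sequences, annotation)

    common = filter_commonly_bound(compendium, config.min_samples)

    n_hits = []
    has_box = []
    for chrom, start, end in zip(common["chrom"], common["start"], common["end"]):
        seq = sequences[chrom]
        lo = max(0, int(start) - config.flank)
        hi = min(len(seq), int(end) + config.flank)
        hits = scan_motif(seq[lo:hi], config.motif)
        n_hits.append(len(hits))
        has_box.append(bool(hits))
    common["n_motif_hits"] = n_hits
    common["has_mebox"] = has_box

    common = classify_tss_distance(common, annotation, config)

    if k27_sets:
        k27_flags = np.column_stack(
            [_overlaps_any(common, peaks) for peaks in k27_sets.values()]
        )
        common["k27ac_samples"] = k27_flags.sum(axis=1)
    else:
        common["k27ac_samples"] = 0
    common["k27ac_marked"] = common["k27ac_samples"] >= config.min_k27_samples

    qualifying = common["has_mebox"] & common["nearest_gene"].notna()
    promoter = common[qualifying & (common["distance_class"] == "proximal_500")]
    extended = common[
        qualifying
        & common["k27ac_marked"]
        & (common["signed_tss_distance"].abs() <= config.distal_bp)
    ]
    criteria = asdict(config)
    criteria["min_samples"] = (
        len(compendium.sample_ids) if config.min_samples is None else config.min_samples
    )
    return CoreRegulon(
        sites=common.reset_index(drop=True),
        promoter_genes=set(promoter["nearest_gene"]),
        extended_genes=set(extended["nearest_gene"]),
        criteria=criteria,
    )
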
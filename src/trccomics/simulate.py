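"""Synthetic multi-omics cohort generator with planted ground truth.

Every downstream stage of the pipeline is testable against data this module
fabricates: a random chromosome with genes spaced far apart, CACGTG M/E-box
elements planted next to a chosen set of "regulon" genes (and chance
hexamers scrubbed from every other promoter so zero-noise recovery is
exact), per-sample TFE3 and H3K27ac peak sets covering the planted elements,
negative-binomial count matrices whose signature genes follow planted
cell-state fractions and cluster labels, and survival times whose hazard is
log-linear in a chosen per-sample score.

The planted truth travels in a :class:`SyntheticTruth` record and
round-trips through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneAnnotationSet, write_fasta
from .deconv import SignatureMatrix
from .expression import ExpressionMatrix, GeneSet, write_gmt
from .intervals import write_bed
from .motif import MEBOX, scan_motif
from .survival import SurvivalTable

CHROM = "chrS"
BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic cohort."""

    seed: int
    regulon_genes: list[str] = field(default_factory=list)
    motif_positions: dict[str, int] = field(default_factory=dict)
    signature_genes: dict[str, list[str]] = field(default_factory=dict)
    states: list[str] = field(default_factory=list)
    mix_fractions: pd.DataFrame | None = None  # samples x states
    cluster_labels: pd.Series | None = None  # values in 1..K
    true_log_hazard_coef: float | None = None

    def validate(self, annotation: GeneAnnotationSet | None = None) -> None:
        if self.mix_fractions is not None:
            sums = self.mix_fractions.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("mix fractions must sum to 1 per sample")
            if (self.mix_fractions.to_numpy() < 0).any():
                raise ValueError("mix fractions must be nonnegative")
        if self.cluster_labels is not None:
            labs = set(self.cluster_labels.unique())
            if not labs <= set(range(1, len(labs) + 1)):
                raise ValueError("cluster labels must be 1..K")
        if annotation is not None:
            extra = set(self.regulon_genes) - set(annotation.gene_ids)
            if extra:
                raise ValueError(f"regulon genes absent from annotation: {sorted(extra)[:5]}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "regulon_genes": sorted(self.regulon_genes),
            "motif_positions": dict(sorted(self.motif_positions.items())),
            "signature_genes": {k: list(v) for k, v in sorted(self.signature_genes.items())},
            "states": self.states,
            "mix_fractions": None
            if self.mix_fractions is None
            else {
                "samples": self.mix_fractions.index.tolist(),
                "states": self.mix_fractions.columns.tolist(),
                "values": self.mix_fractions.to_numpy().tolist(),
            },
            "cluster_labels": None
            if self.cluster_labels is None
            else {str(k): int(v) for k, v in self.cluster_labels.items()},
            "true_log_hazard_coef": self.true_log_hazard_coef,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        mix = d["mix_fractions"]
        mix_df = (
            None
            if mix is None
            else pd.DataFrame(mix["values"], index=mix["samples"], columns=mix["states"])
        )
        labels = d["cluster_labels"]
        lab_s = (
            None
            if labels is None
            else pd.Series({k: int(v) for k, v in labels.items()}, name="cluster")
        )
        return cls(
            seed=d["seed"],
            regulon_genes=list(d["regulon_genes"]),
            motif_positions={k: int(v) for k, v in d["motif_positions"].items()},
            signature_genes={k: list(v) for k, v in d["signature_genes"].items()},
            states=list(d["states"]),
            mix_fractions=mix_df,
            cluster_labels=lab_s,
            true_log_hazard_coef=d["true_log_hazard_coef"],
        )


def _scrub_hexamers(seq: np.ndarray, lo: int, hi: int, rng: np.random.Generator) -> None:
    """Destroy every CACGTG occurrence in ``seq[lo:hi]`` in place.

    One base of each occurrence is resampled until no hexamer overlapping
    the window survives (re-scanning with margin so edits cannot silently
    create a new occurrence just outside the window).
    """
    margin = len(MEBOX) - 1
    lo = max(0, lo - margin)
    hi = min(len(seq), hi + margin)
    for _ in range(50):  # converges in a couple of passes
        window = seq[lo:hi].tobytes().decode()
        hits = scan_motif(window, MEBOX)
        if not hits:
            return
        for hit in hits:
            pos = lo + hit.offset + 2  # mutate the middle of the hexamer
            current = seq[pos]
            choices = BASES[BASES != current]
            seq[pos] = rng.choice(choices)
    raise RuntimeError("hexamer scrubbing failed to converge")


def simulate_genome(
    n_genes: int = 200,
    n_regulon: int = 40,
    chrom_len: int | None = None,
    spacing: int = 100_000,
    motif_offset: int = 100,
    seed: int = 0,
) -> tuple[GeneAnnotationSet, dict[str, str], SyntheticTruth]:
    """Random chromosome + TSS table with planted M/E-boxes.

    Genes sit ``spacing`` bp apart (small jitter) on a single synthetic
    chromosome; strands are uniform.  Each of ``n_regulon`` randomly chosen
    regulon genes gets a CACGTG element planted ``motif_offset`` bp
    downstream of its TSS (strand-aware); chance CACGTG occurrences within
    +/-1 kb of every TSS are scrubbed first, so under zero peak noise the
    regulon is exactly recoverable.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0 <= n_regulon <= n_genes):
        raise ValueError("n_regulon must be in [0, n_genes]")
    required = spacing * (n_genes + 1)
    if chrom_len is None:
        chrom_len = required
    if chrom_len < required:
        raise ValueError(
            f"chrom_len={chrom_len} too short for {n_genes} TSSs at {spacing} bp spacing "
            f"(need >= {required})"
        )
    rng = np.random.default_rng(seed)
    seq = rng.choice(BASES, size=chrom_len)

    jitter = rng.integers(-spacing // 10, spacing // 10 + 1, size=n_genes)
    tss = spacing * (np.arange(1, n_genes + 1)) + jitter
    strands = rng.choice(["+", "-"], size=n_genes)
    width = len(str(n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    annotation = GeneAnnotationSet(
        pd.DataFrame(
            {"gene_id": gene_ids, "chrom": CHROM, "tss": tss.astype(int), "strand": strands}
        )
    )

    for pos in tss:
        _scrub_hexamers(seq, int(pos) - 1000, int(pos) + 1000, rng)

    regulon = sorted(rng.choice(gene_ids, size=n_regulon, replace=False).tolist())
    motif_positions: dict[str, int] = {}
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in regulon:
        i = idx[g]
        pos = int(tss[i]) + motif_offset if strands[i] == "+" else int(tss[i]) - motif_offset - len(MEBOX)
        seq[pos : pos + len(MEBOX)] = np.frombuffer(MEBOX.encode(), dtype="S1")
        motif_positions[g] = pos

    truth = SyntheticTruth(seed=seed, regulon_genes=regulon, motif_positions=motif_positions)
    sequences = {CHROM: seq.tobytes().decode()}
    return annotation, sequences, truth


def simulate_peaks(
    annotation: GeneAnnotationSet,
    truth: SyntheticTruth,
    n_samples: int = 4,
    noise_fp: float = 0.0,
    noise_fn: float = 0.0,
    peak_halfwidth: int = 150,
    k27_halfwidth: int = 500,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Per-sample TFE3 and H3K27ac peak sets covering the planted elements.

    Every regulon gene receives, in each sample, a TFE3 peak centred on its
    planted M/E-box (dropped out with probability ``noise_fn``) and an
    H3K27ac peak spanning its promoter.  False-positive TFE3 peaks are added
    per sample at rate ``noise_fp`` (expected ``noise_fp * n_genes`` peaks),
    placed >40 kb from any TSS so they can never enter a gene program.
    Peak edges get a small per-sample jitter so the union merge is exercised.
    """
    for rate, name in ((noise_fp, "noise_fp"), (noise_fn, "noise_fn")):
        if not (0 <= rate < 1):
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ann = annotation.table.set_index("gene_id")
    tss_sorted = np.sort(annotation.table["tss"].to_numpy())
    chrom_len = int(tss_sorted[-1] + 100_000)
    motif_len = len(MEBOX)

    tfe3: dict[str, pd.DataFrame] = {}
    k27: dict[str, pd.DataFrame] = {}
    for s in range(n_samples):
        sid = f"line{s + 1}"
        rows = []
        k_rows = []
        for g in truth.regulon_genes:
            pos = truth.motif_positions[g]
            t = int(ann.loc[g, "tss"])
            if rng.random() >= noise_fn:
                j = int(rng.integers(-20, 21))
                rows.append((CHROM, pos - peak_halfwidth + j, pos + motif_len + peak_halfwidth + j, g))
            j = int(rng.integers(-20, 21))
            k_rows.append((CHROM, max(0, t - k27_halfwidth + j), t + k27_halfwidth + j, g))
        n_fp = rng.binomial(len(annotation), noise_fp)
        placed = 0
        attempts = 0
        while placed < n_fp and attempts < 100 * max(1, n_fp):
            attempts += 1
            start = int(rng.integers(0, chrom_len - 2 * peak_halfwidth))
            mid = start + peak_halfwidth
            i = np.searchsorted(tss_sorted, mid)
            near = min(
                abs(mid - tss_sorted[k]) for k in (i - 1, i) if 0 <= k < len(tss_sorted)
            )
            if near <= 40_000:
                continue
            rows.append((CHROM, start, start + 2 * peak_halfwidth, f"fp{placed}"))
            placed += 1
        tfe3[sid] = (
            pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
            .sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True)
        )
        k27[sid] = (
            pd.DataFrame(k_rows, columns=["chrom", "start", "end", "name"])
            .sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True)
        )
    return tfe3, k27


def _draw_nb(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion * mu^2."""
    if dispersion < 1e-8:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(
    annotation: GeneAnnotationSet,
    truth: SyntheticTruth,
    n_samples: int = 60,
    n_clusters: int = 3,
    depth_range: tuple[float, float] = (0.7, 1.4),
    nb_dispersion: float = 0.1,
    n_signature: int = 22,
    n_caf_markers: int = 15,
    n_oxphos: int = 30,
    n_cluster_markers: int = 25,
    signature_boost: float = 8.0,
    oxphos_boost: float = 4.0,
    marker_boost: float = 6.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SignatureMatrix, dict[str, GeneSet]]:
    """Bulk RNA-seq counts with planted signatures, fractions and clusters.

    Reference states are epithelial / mesenchymal tumour cells and a
    myCAF-like fibroblast state.  Each sample's expected expression is a
    fraction-weighted mixture of the state profiles, times a sample depth
    factor, times cluster-marker boosts; counts are negative binomial with
    variance ``mu + dispersion * mu^2``.  Updates ``truth`` in place with
    mix fractions, cluster labels and signature gene lists; returns the
    counts, the reference signature matrix and GMT-ready gene sets.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if nb_dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    rng = np.random.default_rng(seed)
    genes = annotation.gene_ids
    states = ["epi", "mes", "caf"]

    # disjoint signature gene draws; OxPhos genes come from the planted regulon
    non_regulon = [g for g in genes if g not in set(truth.regulon_genes)]
    pool = list(non_regulon)
    rng.shuffle(pool)
    need = 2 * n_signature + n_caf_markers + n_clusters * n_cluster_markers
    if len(pool) < need:
        raise ValueError(f"need >= {need} non-regulon genes, have {len(pool)}")
    epi = sorted(pool[:n_signature])
    mes = sorted(pool[n_signature : 2 * n_signature])
    caf = sorted(pool[2 * n_signature : 2 * n_signature + n_caf_markers])
    off = 2 * n_signature + n_caf_markers
    cluster_markers = {
        c + 1: sorted(pool[off + c * n_cluster_markers : off + (c + 1) * n_cluster_markers])
        for c in range(n_clusters)
    }
    n_ox = min(n_oxphos, len(truth.regulon_genes))
    oxphos = sorted(rng.choice(truth.regulon_genes, size=n_ox, replace=False).tolist()) if n_ox else []

    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=len(genes))
    profiles = pd.DataFrame(
        np.tile(base[:, None], (1, len(states))), index=genes, columns=states
    )
    profiles.loc[epi, "epi"] *= signature_boost
    profiles.loc[mes, "mes"] *= signature_boost
    profiles.loc[caf, "caf"] *= signature_boost
    if oxphos:  # tumour-intrinsic, fusion-driven: high in both tumour states
        profiles.loc[oxphos, ["epi", "mes"]] *= oxphos_boost

    sample_ids = [f"T{j + 1:03d}" for j in range(n_samples)]
    labels = pd.Series(
        (np.arange(n_samples) % n_clusters) + 1, index=sample_ids, name="cluster"
    )
    alpha_by_cluster = {1: np.array([8.0, 1.0, 1.0]), 2: np.array([1.0, 8.0, 1.0])}
    for c in range(3, n_clusters + 1):
        alpha_by_cluster[c] = np.array([3.0, 3.0, 6.0])
    fractions = np.vstack(
        [rng.dirichlet(alpha_by_cluster[int(labels[sid])]) for sid in sample_ids]
    )
    mix = pd.DataFrame(fractions, index=sample_ids, columns=states)

    depth = rng.uniform(depth_range[0], depth_range[1], size=n_samples)
    mu = (profiles.to_numpy() @ fractions.T) * depth[None, :]
    for c, markers in cluster_markers.items():
        gi = [genes.index(g) for g in markers]
        sj = labels.to_numpy() == c
        mu[np.ix_(gi, sj)] *= marker_boost
    counts = _draw_nb(rng, mu, nb_dispersion)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=genes, columns=sample_ids),
        state="raw_counts",
    )

    truth.states = states
    truth.mix_fractions = mix
    truth.cluster_labels = labels
    truth.signature_genes = {
        "epithelial": epi,
        "mesenchymal": mes,
        "myCAF": caf,
        "oxphos": oxphos,
        **{f"cluster{c}_markers": m for c, m in cluster_markers.items()},
    }
    gene_sets = {
        name: GeneSet(name, genes_)
        for name, genes_ in truth.signature_genes.items()
        if genes_
    }
    # the reference signature matrix carries only state-discriminating
    # markers, the way a deconvolution signature matrix is built
    marker_genes = sorted(set(epi) | set(mes) | set(caf))
    return matrix, SignatureMatrix(profiles.loc[marker_genes]), gene_sets


def simulate_survival(
    scores: pd.Series,
    beta: float = 1.0,
    censor_rate: float = 0.3,
    baseline_hazard: float = 0.02,
    seed: int = 0,
) -> SurvivalTable:
    """Exponential survival times with hazard ``h0 * exp(beta * score)``.

    Censoring is independent exponential with a per-subject rate chosen so
    each subject is censored with probability exactly ``censor_rate``.
    """
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    x = scores.to_numpy(dtype=float)
    hazard = baseline_hazard * np.exp(beta * x)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_rate = hazard * censor_rate / (1 - censor_rate)
        t_censor = rng.exponential(1.0 / c_rate)
    else:
        t_censor = np.full_like(t_event, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return SurvivalTable(
        pd.DataFrame(
            {"sample_id": scores.index.astype(str), "time": time, "event": event}
        )
    )


def write_cohort(
    directory: str | Path,
    annotation: GeneAnnotationSet,
    sequences: Mapping[str, str],
    truth: SyntheticTruth,
    tfe3: Mapping[str, pd.DataFrame],
    k27: Mapping[str, pd.DataFrame],
    counts: ExpressionMatrix,
    reference: SignatureMatrix,
    gene_sets: Mapping[str, GeneSet],
    survival: SurvivalTable,
) -> dict[str, Path]:
    """Write every synthetic input as plain-text files; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome_fa"] = directory / "genome.fa"
    write_fasta(sequences, paths["genome_fa"])
    paths["tss_tsv"] = directory / "tss.tsv"
    annotation.write_tsv(paths["tss_tsv"])
    paths["truth_json"] = directory / "truth.json"
    truth.to_json(paths["truth_json"])
    for sid, df in tfe3.items():
        p = directory / f"tfe3_{sid}.bed"
        write_bed(df, p)
        paths[f"tfe3_{sid}"] = p
    for sid, df in k27.items():
        p = directory / f"k27ac_{sid}.bed"
        write_bed(df, p)
        paths[f"k27ac_{sid}"] = p
    paths["counts_tsv"] = directory / "counts.tsv"
    counts.write_tsv(paths["counts_tsv"])
    paths["reference_tsv"] = directory / "reference_profiles.tsv"
    reference.write_tsv(paths["reference_tsv"])
    paths["signatures_gmt"] = directory / "signatures.gmt"
    write_gmt(gene_sets.values(), paths["signatures_gmt"])
    paths["survival_tsv"] = directory / "survival.tsv"
    survival.write_tsv(paths["survival_tsv"])
    return paths
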
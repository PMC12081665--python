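"""End-to-end orchestration: simulate -> regulon -> score -> cluster ->
deconvolve -> survive, with a self-describing run directory and manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import GeneAnnotationSet, read_fasta
from .config import PipelineConfig
from .consensus import consensus_cluster
from .deconv import SignatureMatrix, nnls_deconvolve, stratify_by_ratio
from .expression import (
    ExpressionMatrix,
    geometric_mean_score,
    normalize,
    read_gmt,
    select_features,
    signature_ratio,
)
from .intervals import merge_union, read_bed
from .regulon import RegulonConfig, call_core_regulon
from .simulate import (
    SyntheticTruth,
    simulate_counts,
    simulate_genome,
    simulate_peaks,
    simulate_survival,
    write_cohort,
)
from .survival import SurvivalTable, km_estimate, optimal_cutpoint

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [f"validation: {len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        lines += [f"  ERROR: {e}" for e in self.errors]
        lines += [f"  warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def validate_inputs(sim_dir: str | Path) -> ValidationReport:
    """Cross-check a cohort directory: chromosome names, id joins, GMT coverage."""
    sim_dir = Path(sim_dir)
    report = ValidationReport()
    required = ["genome.fa", "tss.tsv", "counts.tsv", "survival.tsv"]
    for name in required:
        if not (sim_dir / name).exists():
            report.errors.append(f"missing input file: {name}")
    if report.errors:
        return report
    sequences = read_fasta(sim_dir / "genome.fa")
    annotation = GeneAnnotationSet.read_tsv(sim_dir / "tss.tsv")
    seq_chroms = set(sequences)
    bad_ann = sorted(annotation.chroms - seq_chroms)
    if bad_ann:
        report.errors.append(
            f"annotation chromosomes absent from FASTA: {bad_ann}; "
            "rename chromosomes consistently (e.g. '1' vs 'chr1')"
        )
    for bed in sorted(sim_dir.glob("*.bed")):
        chroms = set(read_bed(bed)["chrom"].unique())
        bad = sorted(chroms - seq_chroms)
        if bad:
            report.errors.append(
                f"{bed.name}: chromosomes absent from FASTA: {bad}; rename consistently"
            )
    counts = ExpressionMatrix.read_tsv(sim_dir / "counts.tsv")
    gmt = sim_dir / "signatures.gmt"
    if gmt.exists():
        for name, gs in read_gmt(gmt).items():
            missing = sorted(set(gs.genes) - set(counts.gene_ids))
            if missing:
                report.warnings.append(
                    f"gene set {name}: {len(missing)} gene(s) absent from matrix "
                    f"(e.g. {missing[0]})"
                )
    surv = SurvivalTable.read_tsv(sim_dir / "survival.tsv")
    unmatched = sorted(set(surv.table["sample_id"]) - set(counts.sample_ids))
    if unmatched:
        report.warnings.append(
            f"{len(unmatched)} survival sample(s) absent from counts (e.g. {unmatched[0]})"
        )
    return report


def run_all(config: PipelineConfig, run_dir: str | Path) -> dict:
    """Execute every stage on a synthetic cohort and write a manifest.

    Returns the manifest dict.  Any stage failure raises :class:`StageError`
    naming the stage; partial outputs are preserved in the run directory.
    """
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    stages_done: list[str] = []
    rng_seed = config.seed

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            stages_done.append(name)
            return out

        return wrap

    # --- simulate -----------------------------------------------------------
    def _simulate():
        annotation, sequences, truth = simulate_genome(
            n_genes=config.n_genes,
            n_regulon=config.n_regulon,
            spacing=config.spacing,
            seed=rng_seed,
        )
        tfe3, k27 = simulate_peaks(
            annotation,
            truth,
            n_samples=config.n_peak_samples,
            noise_fp=config.noise_fp,
            noise_fn=config.noise_fn,
            seed=rng_seed + 1,
        )
        counts, reference, gene_sets = simulate_counts(
            annotation,
            truth,
            n_samples=config.n_tumor_samples,
            n_clusters=config.n_clusters,
            depth_range=(config.depth_low, config.depth_high),
            nb_dispersion=config.nb_dispersion,
            seed=rng_seed + 2,
        )
        truth.true_log_hazard_coef = config.survival_beta
        # survival driven by the OxPhos-style score of the planted signature
        normalized = normalize(counts)
        sig = truth.signature_genes.get(config.survival_signature) or truth.signature_genes["oxphos"]
        score = geometric_mean_score(normalized, sig, config.pseudocount)
        z = (np.log(score + 1) - np.log(score + 1).mean()) / np.log(score + 1).std()
        survival = simulate_survival(
            pd.Series(z, index=score.index),
            beta=config.survival_beta,
            censor_rate=config.censor_rate,
            baseline_hazard=config.baseline_hazard,
            seed=rng_seed + 3,
        )
        truth.validate(annotation)
        write_cohort(
            run_dir / "simulate",
            annotation,
            sequences,
            truth,
            tfe3,
            k27,
            counts,
            reference,
            gene_sets,
            survival,
        )
        return annotation, sequences, truth, tfe3, k27, counts, reference, gene_sets, survival

    (annotation, sequences, truth, tfe3, k27, counts, reference, gene_sets, survival) = stage(
        "simulate"
    )(_simulate)

    # --- regulon ------------------------------------------------------------
    def _regulon():
        compendium = merge_union(tfe3)
        reg_cfg = RegulonConfig(
            min_samples=config.min_samples,
            motif=config.motif,
            flank=config.flank,
            min_k27_samples=config.min_k27_samples,
            proximal_bp=config.proximal_bp,
            promoter_bp=config.promoter_bp,
            distal_bp=config.distal_bp,
        )
        regulon = call_core_regulon(compendium, annotation, sequences, k27, reg_cfg)
        regulon.write(run_dir / "regulon")
        return compendium, regulon

    compendium, regulon = stage("regulon")(_regulon)

    # --- score --------------------------------------------------------------
    def _score():
        normalized = normalize(counts)
        scores = pd.DataFrame(index=normalized.sample_ids)
        for name in ("epithelial", "mesenchymal", "myCAF", "oxphos"):
            if name in gene_sets:
                scores[name] = geometric_mean_score(
                    normalized, gene_sets[name], config.pseudocount
                )
        scores["SignatureRatio"] = signature_ratio(
            normalized,
            gene_sets["mesenchymal"],
            gene_sets["epithelial"],
            config.pseudocount,
        )
        out = run_dir / "score"
        out.mkdir(exist_ok=True)
        scores.to_csv(out / "scores.tsv", sep="\t", index_label="sample_id")
        return normalized, scores

    normalized, scores = stage("score")(_score)

    # --- cluster ------------------------------------------------------------
    def _cluster():
        values = normalized.values
        if config.log2_before_clustering:
            values = np.log2(values + 1)
        k = config.select_k or min(5000, len(values))
        feats = select_features(values, k=min(k, len(values)))
        result = consensus_cluster(
            feats,
            k_range=range(config.k_min, config.k_max + 1),
            n_resamples=config.n_resamples,
            subsample=config.subsample,
            seed=rng_seed + 4,
            delta_threshold=config.delta_threshold,
        )
        out = run_dir / "cluster"
        out.mkdir(exist_ok=True)
        result.consensus_frame().to_csv(out / "consensus_matrix.tsv", sep="\t")
        result.labels_series().to_frame().to_csv(
            out / "labels.tsv", sep="\t", index_label="sample_id"
        )
        with open(out / "model_selection.json", "w") as fh:
            json.dump(
                {
                    "recommended_k": result.recommended_k,
                    "cdf_area": {str(k): v for k, v in result.cdf_area.items()},
                    "delta_area": {str(k): v for k, v in result.delta_area.items()},
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        return result

    cluster_result = stage("cluster")(_cluster)

    # --- deconv -------------------------------------------------------------
    def _deconv():
        est = nnls_deconvolve(normalized, reference, normalize=True)
        n_strat = min(config.n_per_stratum, len(est.sample_ids) // 3)
        groups = stratify_by_ratio(est, "epi", "mes", n_per_stratum=n_strat)
        out = run_dir / "deconv"
        out.mkdir(exist_ok=True)
        est.frame().to_csv(out / "fractions.tsv", sep="\t", index_label="sample_id")
        rows = [(sid, grp) for grp, sids in groups.items() for sid in sids]
        pd.DataFrame(rows, columns=["sample_id", "stratum"]).sort_values("sample_id").to_csv(
            out / "strata.tsv", sep="\t", index=False
        )
        return est, groups

    fractions, strata = stage("deconv")(_deconv)

    # --- survive ------------------------------------------------------------
    def _survive():
        sig = config.survival_signature if config.survival_signature in scores else "oxphos"
        joined = survival.join_scores(scores[sig], name=sig)
        cut = optimal_cutpoint(joined, sig, minprop=config.minprop)
        curves = km_estimate(joined, cut.groups.to_numpy())
        out = run_dir / "survive"
        out.mkdir(exist_ok=True)
        km_rows = []
        for grp, df in curves.items():
            df = df.assign(group=grp)
            km_rows.append(df)
        pd.concat(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False)
        payload = {
            "signature": sig,
            "threshold": cut.threshold,
            "max_standardized_logrank": cut.statistic,
            "logrank_chi2": cut.logrank_chi2,
            "logrank_p": cut.logrank_p,
            "p_is_optimistic": cut.p_is_optimistic,
            "hazard_ratio": cut.cox.hazard_ratio if cut.cox else None,
            "hr_ci95": list(cut.cox.confint()) if cut.cox else None,
            "wald_p": cut.cox.wald_p if cut.cox else None,
            "minprop": cut.minprop,
        }
        with open(out / "survival_summary.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        cut.groups.to_frame().to_csv(out / "groups.tsv", sep="\t", index_label="sample_id")
        return cut

    cutpoint = stage("survive")(_survive)

    # --- manifest -----------------------------------------------------------
    files = {
        str(p.relative_to(run_dir)): _sha256(p)
        for p in sorted(run_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package": "trccomics",
        "version": __version__,
        "seed": config.seed,
        "stages": stages_done,
        "files": files,
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
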
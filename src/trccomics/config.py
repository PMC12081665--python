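"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, with documented defaults.

    Defaults are sized for the synthetic demonstration cohort: 200 genes /
    40 regulon genes / 4 peak samples mirror a desk-scale version of a
    4-cell-line binding study, and 60 tumour samples in 3 clusters mirror a
    small expression cohort.
    """

    seed: int = 0

    # --- synthetic cohort ---
    n_genes: int = 200
    n_regulon: int = 40
    spacing: int = 100_000
    n_peak_samples: int = 4
    noise_fp: float = 0.02
    noise_fn: float = 0.0
    n_tumor_samples: int = 60
    n_clusters: int = 3
    nb_dispersion: float = 0.1
    depth_low: float = 0.7
    depth_high: float = 1.4

    # --- core regulon ---
    min_samples: int | None = None  # None -> all peak samples
    motif: str = "CACGTG"
    flank: int = 0
    min_k27_samples: int = 1
    proximal_bp: int = 500
    promoter_bp: int = 1000
    distal_bp: int = 30_000

    # --- scoring / clustering ---
    pseudocount: float = 1.0
    select_k: int | None = None  # None -> min(5000, n_genes)
    log2_before_clustering: bool = True
    k_min: int = 2
    k_max: int = 6
    n_resamples: int = 200
    subsample: float = 0.8
    delta_threshold: float = 0.1

    # --- deconvolution ---
    n_per_stratum: int = 20

    # --- survival ---
    survival_signature: str = "oxphos"
    survival_beta: float = 1.0
    censor_rate: float = 0.3
    baseline_hazard: float = 0.02
    minprop: float = 0.1

    def validate(self) -> None:
        if self.n_regulon > self.n_genes:
            raise ValueError("n_regulon cannot exceed n_genes")
        for rate, name in ((self.noise_fp, "noise_fp"), (self.noise_fn, "noise_fn")):
            if not (0 <= rate < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0 < self.minprop < 0.5):
            raise ValueError("minprop must be in (0, 0.5)")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.pseudocount < 0 or self.nb_dispersion < 0:
            raise ValueError("pseudocount and dispersion must be nonnegative")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
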
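"""Pipeline configuration with the study's processing constants as defaults."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config", "stage_seed"]


@dataclass
class PipelineConfig:
    # QC
    sample_min_reads: float = 5_000_000
    gene_min_reads: int = 10
    gene_max_low_frac: float = 0.10
    gene_cv_max: float = 3.0
    high_confidence_thresh: int = 30
    # DEG
    deg_alpha: float = 0.05
    deg_min_base_mean: float = 10.0
    # MRGF
    correlation_cutoff: float = 0.90
    n_lambda: int = 100
    folds: int = 10
    mrmr_bins: int = 10
    mrmr_n_boot: int = 0
    # classifier; 5000 random draws is the full-scale search, 200 the desk default
    svm_n_draws: int = 200
    threshold: float = 0.5
    ca125_cutoff: float = 35.0
    # evaluation
    fixed_specificity: float = 0.90
    permutation_B: int = 999
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        checks = [
            ("sample_min_reads", self.sample_min_reads >= 0),
            ("gene_min_reads", self.gene_min_reads >= 0),
            ("gene_max_low_frac", 0.0 <= self.gene_max_low_frac <= 1.0),
            ("gene_cv_max", self.gene_cv_max > 0),
            ("deg_alpha", 0.0 < self.deg_alpha < 1.0),
            ("correlation_cutoff", 0.0 < self.correlation_cutoff <= 1.0),
            ("n_lambda", self.n_lambda >= 2),
            ("folds", self.folds >= 2),
            ("svm_n_draws", self.svm_n_draws >= 1),
            ("threshold", 0.0 < self.threshold < 1.0),
            ("fixed_specificity", 0.0 < self.fixed_specificity < 1.0),
            ("permutation_B", self.permutation_B >= 1),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"config values out of range: {bad}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def stage_seed(seed: int, stage: str) -> int:
    """Fan a global seed out to a stable per-stage child seed (< 2^31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
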
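"""Pipeline configuration.

Defaults follow the published analysis protocol wherever it states a
value: missingness cutoff 0.70, follow-up filter > 30 days, univariate
alpha 0.05, consensus k range 2-20 with 100 iterations at 80%
subsampling and a 0.90 cluster-consensus rule, entropy-null SD 0.04,
tenfold cross-validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0

    # preprocess
    max_missing_frac: float = 0.70
    min_followup_days: float = 30.0
    knn_k: int = 10
    train_frac: float = 0.5
    split_attempts: int = 200

    # Cox screen
    alpha_univariate: float = 0.05
    q_cutoff: float = 0.05

    # consensus clustering
    k_min: int = 2
    k_max: int = 20
    n_consensus_iter: int = 100
    subsample_frac: float = 0.8
    min_cluster_consensus: float = 0.90
    delta_tol: float = 0.05

    # specific-CpG calling
    entropy_sd: float = 0.04
    null_quantile: float = 0.001
    n_null: int = 10000

    # classifier
    n_folds: int = 10
    var_floor: float = 1e-6

    def validate(self) -> None:
        for name in ("max_missing_frac", "train_frac", "subsample_frac",
                     "min_cluster_consensus", "null_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
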
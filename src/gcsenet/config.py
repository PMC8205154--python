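"""Run configuration: every tunable of the pipeline in one flat record.

Defaults follow the method's standard settings for the
miRNA-disease task: decay Δ=0.5, channel-mix α=0.57, SE compression r=4,
dropout 0.5, L2 0.002, Adam lr 1e-2, batch 64, 150 classifier epochs, a
3-layer GCN.  `task="phenotype"` atomically flips the paired phenotype
settings (α=0.5, batch 128, 20 epochs).  CNN shape parameters
(filters/kernel/pool/hidden) have no standard reference values and carry
this package's own defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    pass


# (alpha, batch_size, epochs) pairs flipped by task mode
_TASK_DEFAULTS = {
    "disease": {"alpha": 0.57, "batch_size": 64, "epochs": 150},
    "phenotype": {"alpha": 0.5, "batch_size": 128, "epochs": 20},
}


@dataclass
class RunConfig:
    task: str = "disease"
    # similarity
    delta: float = 0.5          # semantic contribution decay per ancestor step
    knn_k: int = 15             # similarity -> edge sparsification
    # encoder
    gcn_layers: int = 3
    embed_dim: int = 64
    encoder_epochs: int = 100
    encoder_batch_edges: int = 128
    encoder_dropout: float = 0.25
    encoder_per_fold: bool = False
    # feature stage
    alpha: float = 0.57         # weight of the disease-gene channel in x_dm
    # classifier
    conv_filters: int = 16
    kernel_width: int = 4
    pool_width: int = 2
    fc_hidden: int = 64
    se_ratio: int = 4
    dropout: float = 0.5
    lr: float = 1e-2
    l2: float = 0.002
    batch_size: int = 64
    epochs: int = 150
    # evaluation
    neg_ratio: float = 1.0
    folds: int = 10
    grouping: str = "by-disease"   # or "by-pair"
    threshold: float = 0.5
    seed: int = 0
    # single-component ablation switches
    no_gcn: bool = False
    no_weighting: bool = False
    no_component: bool = False
    no_senet: bool = False

    def __post_init__(self):
        if self.task not in _TASK_DEFAULTS:
            raise ConfigError(f"task must be disease|phenotype, got {self.task!r}")
        if not (0.0 < self.delta < 1.0):
            raise ConfigError(f"delta must be in (0,1), got {self.delta}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.grouping not in ("by-disease", "by-pair"):
            raise ConfigError(f"grouping must be by-disease|by-pair, got {self.grouping!r}")
        if self.se_ratio < 1:
            raise ConfigError("se_ratio must be >= 1")
        if self.conv_filters % self.se_ratio != 0:
            raise ConfigError(
                f"conv_filters ({self.conv_filters}) must be divisible by "
                f"se_ratio ({self.se_ratio})"
            )
        if self.gcn_layers < 1:
            raise ConfigError("gcn_layers must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must be in [0,1)")

    @staticmethod
    def for_task(task: str, **overrides) -> "RunConfig":
        """Config with the task's paired defaults, then explicit overrides."""
        base = dict(_TASK_DEFAULTS[task]) if task in _TASK_DEFAULTS else {}
        base.update(overrides)
        return RunConfig(task=task, **base)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        task = d.get("task", "disease")
        return RunConfig.for_task(task, **{k: v for k, v in d.items() if k != "task"})

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} must be a flat mapping")
        return RunConfig.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
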
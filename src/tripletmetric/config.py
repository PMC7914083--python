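"""Training configuration shared by the metric optimizer and the pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["LossConfig", "TrainConfig"]


@dataclass
class LossConfig:
    """Margin alpha and pairwise balance mu of the improved triplet loss."""

    margin: float = 1.0
    balance_mu: float = 0.1

    def __post_init__(self):
        if not (self.margin >= 0 and self.balance_mu >= 0):
            raise ValueError("margin and balance_mu must be nonnegative and finite")


@dataclass
class TrainConfig:
    """Everything the end-to-end trainer needs, with desk-scale defaults.

    ``outer_iters`` counts alternating rounds; each round runs
    ``inner_batches`` SGD mini-batches on the network weights (metric fixed),
    then ``metric_steps`` projected-gradient steps on the metric (weights
    fixed).  ``batch_K``/``batch_L`` give the K-classes-x-L-images batch
    shape used for batch-hard mining.
    """

    seed: int = 0
    outer_iters: int = 20
    inner_batches: int = 16
    metric_steps: int = 5
    lr_w: float = 0.02
    lr_M: float = 0.01
    momentum: float = 0.5
    weight_decay: float = 0.0
    batch_K: int = 2
    batch_L: int = 8
    #: ratio-loss margin; small relative to unit-sphere squared distances so
    #: the ratio keeps useful curvature when embeddings start clustered
    margin: float = 0.2
    #: pairwise (intraclass) penalty weight; sized to keep class clusters
    #: tight enough for the nearest-centroid readout
    balance_mu: float = 0.5
    rounds: int = 2  # attention rounds r
    preset: str = "desk"
    input_size: int = 64
    enhance: bool = False
    classifier_head: str = "centroid"  # or "attention"
    use_attention: bool = False
    #: Polyak-Ruppert averaging of the stage-2 metric iterates over the
    #: second half of training; reduces the variance of the final M.
    average_metric_tail: bool = False

    def __post_init__(self):
        if self.outer_iters < 0 or self.inner_batches < 1 or self.metric_steps < 0:
            raise ValueError("iteration counts out of range")
        if self.batch_K < 1 or self.batch_L < 1:
            raise ValueError("batch shape must be positive")
        if self.margin < 0 or self.balance_mu < 0:
            raise ValueError("margin and balance_mu must be nonnegative")

    @property
    def loss(self) -> LossConfig:
        return LossConfig(margin=self.margin, balance_mu=self.balance_mu)

    @classmethod
    def from_mapping(cls, mapping) -> "TrainConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
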
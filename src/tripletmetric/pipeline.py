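"""End-to-end train / classify / evaluate workflow.

The public surface follows the model/results convention of statistical
modelling packages: :class:`TripletMetricClassifier` is built from labelled
images plus a :class:`~tripletmetric.config.TrainConfig`; ``fit()`` runs
preprocessing, backbone construction, batch-hard mining and the two-stage
alternating optimization, and returns a :class:`TripletMetricResults`
carrying the fitted network, the learned Mahalanobis metric, per-class
centroids, the training history and a ``summary()`` table.  Module-level
``train`` / ``classify_nearest_centroid`` / ``evaluate`` wrappers expose the
same steps functionally, and ``stratified_split`` provides the single
class-stratified train/test split utility.

Classification is by nearest class centroid under the learned metric
(ties break to the lowest class id); the attention memory encoder with the
discriminative decoder is available as an alternative head via
``classifier_head='attention'``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import attention as attn
from .backbone import ArchitectureDescriptor, Backbone, PRESETS, build_backbone
from .config import TrainConfig
from .metric import MetricMatrix, optimize_alternating, psd_project
from .preprocess import equalize_histogram, resize_normalize
from .synthetic_data import LabeledImageSet

logger = logging.getLogger("tripletmetric")

__all__ = [
    "EvalReport",
    "TripletMetricClassifier",
    "TripletMetricResults",
    "train",
    "classify_nearest_centroid",
    "evaluate",
    "stratified_split",
    "preprocess_images",
    "nearest_centroid_labels",
]


@dataclass
class EvalReport:
    """Accuracy, per-class accuracy and confusion counts of one evaluation."""

    accuracy: float
    per_class_accuracy: dict
    confusion_counts: np.ndarray  # rows = true class, cols = predicted
    n_eval: int

    def __str__(self):
        lines = [f"accuracy: {self.accuracy:.4f}  (n={self.n_eval})"]
        for c, a in sorted(self.per_class_accuracy.items()):
            lines.append(f"  class {c}: {a:.4f}")
        return "\n".join(lines)


def preprocess_images(images, cfg: TrainConfig) -> np.ndarray:
    """Optional histogram enhancement, then resize to the configured input
    size with intensities rescaled to [0, 1]."""
    out = []
    for img in images:
        if cfg.enhance:
            img = equalize_histogram(img).pixels
        out.append(resize_normalize(img, cfg.input_size).pixels)
    return np.stack(out) if out else np.empty((0, cfg.input_size, cfg.input_size))


def stratified_split(
    labels, test_fraction: float = 0.5, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded class-stratified split; returns (train_idx, test_idx)."""
    labels = np.asarray(labels, dtype=int)
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        pool = np.flatnonzero(labels == c)
        pool = rng.permutation(pool)
        n_test = int(round(test_fraction * len(pool)))
        test_idx.extend(pool[:n_test])
        train_idx.extend(pool[n_test:])
    return np.sort(np.array(train_idx, int)), np.sort(np.array(test_idx, int))


def nearest_centroid_labels(queries, centroids, M, classes):
    """Predict the class whose centroid is nearest under the metric M; ties
    break to the lowest class id.  Returns (labels, distance matrix)."""
    Q = np.asarray(queries, float)
    C = np.asarray(centroids, float)
    Mmat = np.asarray(getattr(M, "M", M), float)
    Ms = 0.5 * (Mmat + Mmat.T)
    diffs = Q[:, None, :] - C[None, :, :]
    dists = np.einsum("qcd,de,qce->qc", diffs, Ms, diffs)
    classes = np.asarray(classes)
    return classes[np.argmin(dists, axis=1)], dists


def _resolve_descriptor(cfg: TrainConfig) -> ArchitectureDescriptor:
    if cfg.preset not in PRESETS:
        raise ValueError(f"unknown backbone preset {cfg.preset!r}")
    desc = PRESETS[cfg.preset]
    if desc.input_size != cfg.input_size:
        desc = ArchitectureDescriptor(**{**json.loads(desc.to_json()), "input_size": cfg.input_size})
    return desc


class TripletMetricClassifier:
    """Metric-learning image classifier model.

    Parameters
    ----------
    images, labels, ids:
        The training sample: grayscale images (any per-image size; they are
        preprocessed to the configured input size), integer class labels,
        optional unique string ids.
    config:
        A :class:`TrainConfig`; defaults are desk scale.
    """

    def __init__(self, images, labels, ids=None, config: Optional[TrainConfig] = None):
        self.config = config or TrainConfig()
        labels = np.asarray(labels, dtype=int)
        if ids is None:
            ids = [f"img{i:05d}" for i in range(len(labels))]
        self.data = LabeledImageSet(images=list(images), labels=labels, ids=list(ids))

    @classmethod
    def from_image_set(cls, data: LabeledImageSet, config: Optional[TrainConfig] = None):
        return cls(data.images, data.labels, ids=data.ids, config=config)

    def fit(self) -> "TripletMetricResults":
        cfg = self.config
        labels = self.data.labels
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) < 2 or counts.min() < 2:
            raise ValueError("training needs >= 2 classes with >= 2 images each")

        X = preprocess_images(self.data.images, cfg)
        net = build_backbone(_resolve_descriptor(cfg), seed=cfg.seed)
        net, M, history = optimize_alternating(X, labels, net, cfg)

        emb = net.embed_batchwise(X, labels=labels)
        centroids = np.stack(
            [emb.vectors[labels == c].mean(axis=0) for c in classes]
        )

        attention_params = None
        category_memory = None
        if cfg.use_attention or cfg.classifier_head == "attention":
            C = net.last_conv_map.shape[1]
            attention_params = attn.AttentionParams.init(
                d=C, k=max(C // 2, 2), vocab_size=len(classes), seed=cfg.seed
            )
            category_memory = np.random.default_rng(cfg.seed).uniform(
                -0.1, 0.1, size=(len(classes), C)
            )

        return TripletMetricResults(
            backbone=net,
            metric=M,
            centroids=centroids,
            classes=classes,
            config=cfg,
            history=history,
            train_ids=list(self.data.ids),
            attention_params=attention_params,
            category_memory=category_memory,
        )


@dataclass
class TripletMetricResults:
    """Fitted classifier: network weights, learned metric, class centroids,
    training history and diagnostics."""

    backbone: Backbone
    metric: MetricMatrix
    centroids: np.ndarray
    classes: np.ndarray
    config: TrainConfig
    history: pd.DataFrame
    train_ids: list = field(default_factory=list)
    attention_params: Optional[attn.AttentionParams] = None
    category_memory: Optional[np.ndarray] = None

    # -- prediction ---------------------------------------------------------
    def _embed_queries(self, images) -> np.ndarray:
        X = preprocess_images(images, self.config)
        return self.backbone.embed_batchwise(X).vectors

    def predict(self, images) -> Tuple[np.ndarray, np.ndarray]:
        """Nearest-centroid labels and the full query-by-class Mahalanobis
        distance matrix (or attention posteriors, per the configured head)."""
        if self.config.classifier_head == "attention":
            return self._predict_attention(images)
        if self.centroids is None or len(self.centroids) == 0:
            raise RuntimeError("model carries no class centroids")
        Q = self._embed_queries(images)
        return nearest_centroid_labels(Q, self.centroids, self.metric, self.classes)

    def _predict_attention(self, images) -> Tuple[np.ndarray, np.ndarray]:
        """Alternative head: encode the conv map regions with the attention
        memory encoder and rank class candidates with the discriminative
        decoder."""
        if self.attention_params is None:
            raise RuntimeError("model was fitted without the attention head")
        X = preprocess_images(images, self.config)
        preds, posteriors = [], []
        candidates = [[int(c)] for c in self.classes]
        for x in X:
            self.backbone.embed(x[None])
            fm = np.asarray(self.backbone.last_conv_map[0], float)
            banks = attn.MemoryBanks.from_conv_map(fm, self.category_memory)
            v = attn.encode_input(list(banks.visual_memory), self.attention_params)
            state = attn.multi_round_encode(
                v, banks, self.attention_params, rounds=self.config.rounds
            )
            out = attn.discriminative_decode(
                state.encoded, candidates, self.attention_params
            )
            preds.append(self.classes[int(np.argmax(out.posterior))])
            posteriors.append(out.posterior)
        return np.asarray(preds), np.asarray(posteriors)

    def evaluate(self, data: LabeledImageSet) -> EvalReport:
        if len(data) == 0:
            raise ValueError("evaluation data is empty")
        overlap = set(data.ids) & set(self.train_ids)
        if overlap:
            logger.warning(
                "evaluation set shares %d ids with the training set", len(overlap)
            )
        pred, _ = self.predict(data.images)
        true = data.labels
        k = int(max(self.classes.max(), true.max())) + 1
        confusion = np.zeros((k, k), dtype=int)
        np.add.at(confusion, (true, pred), 1)
        acc = float(np.mean(pred == true))
        per_class = {}
        for c in np.unique(true):
            mask = true == c
            per_class[int(c)] = float(np.mean(pred[mask] == c))
        return EvalReport(
            accuracy=acc,
            per_class_accuracy=per_class,
            confusion_counts=confusion,
            n_eval=len(true),
        )

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        eig = np.linalg.eigvalsh(0.5 * (self.metric.M + self.metric.M.T))[::-1]
        h = self.history
        lines = [
            "Triplet Mahalanobis Metric Classifier Results",
            "=" * 45,
            f"classes:            {len(self.classes)}",
            f"training images:    {len(self.train_ids)}",
            f"embedding dim:      {self.backbone.descriptor.embed_dim}",
            f"backbone preset:    {self.config.preset}",
            f"outer iterations:   {len(h)}",
            f"margin alpha:       {self.config.margin}",
            f"pairwise weight mu: {self.config.balance_mu}",
        ]
        if len(h):
            lines += [
                f"initial loss:       {h['loss'].iloc[0]:.6f}",
                f"final loss:         {h['loss'].iloc[-1]:.6f}",
                f"active triplets:    {int(h['active_triplets'].iloc[-1])} (last batch)",
            ]
        lines += [
            f"metric eigenvalues: top {min(5, len(eig))} = "
            + ", ".join(f"{v:.4f}" for v in eig[: min(5, len(eig))]),
            f"metric min eig:     {eig[-1]:.2e}",
        ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive serialization (weights, metric, centroids, config,
        history)."""
        arrays = {f"backbone.{k}": v for k, v in self.backbone.state_arrays().items()}
        cfg_json = json.dumps(self.config.__dict__)
        np.savez(
            path,
            __descriptor__=np.frombuffer(
                self.backbone.descriptor.to_json().encode(), dtype=np.uint8
            ),
            __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
            __seed__=np.array([self.backbone.seed]),
            metric=self.metric.M,
            centroids=self.centroids,
            classes=self.classes,
            history=self.history.to_numpy(dtype=float)
            if len(self.history)
            else np.empty((0, 3)),
            train_ids=np.array(self.train_ids, dtype="U64"),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TripletMetricResults":
        with np.load(path) as data:
            desc = ArchitectureDescriptor.from_json(bytes(data["__descriptor__"]).decode())
            cfg = TrainConfig.from_mapping(json.loads(bytes(data["__config__"]).decode()))
            net = Backbone(desc, seed=int(data["__seed__"][0]))
            for i, layer in enumerate(net._layers_with_params()):
                layer.W = data[f"backbone.layer{i}.W"]
                layer.b = data[f"backbone.layer{i}.b"]
            hist = pd.DataFrame(
                data["history"], columns=["iteration", "loss", "active_triplets"]
            )
            return cls(
                backbone=net,
                metric=psd_project(data["metric"]),
                centroids=data["centroids"],
                classes=data["classes"],
                config=cfg,
                history=hist,
                train_ids=[str(s) for s in data["train_ids"]],
            )


# ---------------------------------------------------------------------------
# functional wrappers


def train(data: LabeledImageSet, cfg: Optional[TrainConfig] = None) -> TripletMetricResults:
    """Fit the classifier on a labelled image set; fully seeded."""
    return TripletMetricClassifier.from_image_set(data, config=cfg).fit()


def classify_nearest_centroid(model: TripletMetricResults, images):
    """Embed queries and predict the class whose stored centroid is nearest
    under the learned metric; ties break to the lowest class id."""
    return model.predict(images)


def evaluate(model: TripletMetricResults, data: LabeledImageSet) -> EvalReport:
    """Accuracy, per-class accuracy and confusion counts on labelled data
    (expected disjoint from training; overlap is logged)."""
    return model.evaluate(data)
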
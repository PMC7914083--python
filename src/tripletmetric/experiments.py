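"""Self-contained validation experiments run by the test suite and the
acceptance script.

``metric_recovery`` is the planted-direction study: two classes of feature
vectors whose means differ only along a random unit direction v (isotropic
within-class noise), so the only discriminative axis is v.  The alternating
optimizer (identity feature extractor, so only the metric learns) should
concentrate the learned Mahalanobis matrix on that axis; the experiment
reports the angle between M's dominant eigenvector and v.

``desk_end_to_end`` trains the full desk-scale pipeline on synthetic blob
images and reports test accuracy plus the training-loss endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from .config import TrainConfig
from .metric import IdentityExtractor, optimize_alternating
from .pipeline import TripletMetricClassifier, stratified_split
from .synthetic_data import generate_blob_images

__all__ = ["RecoveryResult", "metric_recovery", "desk_end_to_end"]


@dataclass
class RecoveryResult:
    angle_deg: float
    planted: np.ndarray
    top_eigenvector: np.ndarray
    loss_initial: float
    loss_final: float


def planted_direction_features(
    seed: int, d: int = 6, n_per_class: int = 200, separation: float = 1.5, sigma: float = 0.6
):
    """Two classes at means -separation*v and +separation*v with isotropic
    within-class noise of scale sigma; v is a seeded random unit vector."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=d)
    v /= np.linalg.norm(v)
    X = np.vstack(
        [
            rng.normal(scale=sigma, size=(n_per_class, d)) - separation * v,
            rng.normal(scale=sigma, size=(n_per_class, d)) + separation * v,
        ]
    )
    y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    return X, y, v


def metric_recovery(seed: int) -> RecoveryResult:
    """Learn M on a planted-direction fixture and measure the angle between
    its dominant eigenvector and the planted axis.

    The optimizer runs stage 2 only (identity extractor): 200 alternating
    iterations of 5 projected-gradient steps, step size 0.1, 2x16 batches,
    with Polyak tail-averaging of the metric iterates.
    """
    X, y, v = planted_direction_features(seed)
    cfg = TrainConfig(
        seed=seed,
        outer_iters=200,
        inner_batches=1,
        metric_steps=5,
        lr_M=0.1,
        batch_K=2,
        batch_L=16,
        margin=1.0,
        balance_mu=0.1,
        average_metric_tail=True,
    )
    _, M, history = optimize_alternating(X, y, IdentityExtractor(), cfg)
    vals, vecs = np.linalg.eigh(M.M)
    top = vecs[:, -1]
    angle = float(np.degrees(np.arccos(min(1.0, abs(float(top @ v))))))
    return RecoveryResult(
        angle_deg=angle,
        planted=v,
        top_eigenvector=top,
        loss_initial=float(history["loss"].iloc[0]),
        loss_final=float(history["loss"].iloc[-1]),
    )


def desk_end_to_end(seed: int, n_per_class: int = 100, outer_iters: int = 20):
    """Full pipeline on 2-class synthetic blob images: generate
    ``n_per_class`` images per class, split 50/50 stratified, train the desk
    preset, and evaluate on the held-out half.

    Returns (accuracy, history DataFrame).
    """
    data = generate_blob_images(
        n_classes=2, n_per_class=n_per_class, size=64, contrast=1.0, seed=seed
    )
    train_idx, test_idx = stratified_split(data.labels, test_fraction=0.5, seed=seed)
    cfg = TrainConfig(seed=seed, outer_iters=outer_iters)
    model = TripletMetricClassifier.from_image_set(data.subset(train_idx), config=cfg)
    results = model.fit()
    report = results.evaluate(data.subset(test_idx))
    return report.accuracy, results.history
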
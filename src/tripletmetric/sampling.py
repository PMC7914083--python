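"""Triplet enumeration, K-class x L-image batch construction, and batch-hard
mining.

With N classes of M images each, the number of admissible (anchor, positive,
negative) triples is N(N-1)M^2(M-1) -- far too many to materialize, so
training draws batches of K classes x L images and, for every image in the
batch, keeps only the hardest positive (farthest same-class member) and the
hardest negative (nearest different-class member) under the current learned
metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple

import numpy as np

__all__ = [
    "Triplet",
    "BatchPlan",
    "count_possible_triplets",
    "sample_pk_batch",
    "mine_hard_triplets",
    "mine_hard_from_labels",
]


class Triplet(NamedTuple):
    """Index triple: anchor and positive share a label, negative differs."""

    anchor: int
    positive: int
    negative: int


@dataclass
class BatchPlan:
    """K distinct classes with L sampled member indices each."""

    class_ids: np.ndarray
    member_ids: np.ndarray  # shape (K, L), indices into the dataset
    K: int
    L: int

    def flat_indices(self) -> np.ndarray:
        """Batch indices with duplicates (from with-replacement sampling)
        removed, order of first occurrence preserved."""
        flat = self.member_ids.ravel()
        _, first = np.unique(flat, return_index=True)
        return flat[np.sort(first)]


def count_possible_triplets(n_classes: int, per_class: int) -> int:
    """Closed form N(N-1)M^2(M-1) for the number of admissible triplets in a
    balanced set of N classes with M images each."""
    if n_classes < 2 or per_class < 2:
        raise ValueError("need at least 2 classes and 2 images per class")
    n, m = int(n_classes), int(per_class)
    return n * (n - 1) * m * m * (m - 1)


def sample_pk_batch(labels, K: int, L: int, seed: int = 0) -> BatchPlan:
    """Randomly draw K distinct classes, then L member indices per class.

    Classes with fewer than L members are sampled with replacement so the
    batch keeps its K*L shape; duplicates are dropped at mining time.
    """
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if K < 1 or L < 1:
        raise ValueError("K and L must be positive")
    if len(classes) < K:
        raise ValueError(f"only {len(classes)} classes available, need K={K}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(classes, size=K, replace=False)
    members = np.empty((K, L), dtype=int)
    for row, c in enumerate(chosen):
        pool = np.flatnonzero(labels == c)
        members[row] = rng.choice(pool, size=L, replace=len(pool) < L)
    return BatchPlan(class_ids=chosen, member_ids=members, K=K, L=L)


def _pairwise_mahalanobis(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """All-pairs quadratic-form distances d(i,j) = (x_i-x_j)^T M (x_i-x_j).

    Only the symmetric part of M contributes to a quadratic form, so the Gram
    trick with (M + M^T)/2 is exact.
    """
    Ms = 0.5 * (M + M.T)
    G = X @ Ms @ X.T
    diag = np.diag(G)
    return diag[:, None] + diag[None, :] - 2.0 * G


def mine_hard_from_labels(vectors: np.ndarray, labels, M) -> List[Triplet]:
    """Batch-hard mining over an embedded batch.

    Every row anchors one triplet: positive = same-class row at maximal
    Mahalanobis distance, negative = different-class row at minimal distance;
    ties break to the lowest index.  Anchors whose class has no second member
    in the batch are skipped.
    """
    X = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels, dtype=int)
    Mmat = getattr(M, "M", M)
    D = _pairwise_mahalanobis(X, np.asarray(Mmat, dtype=float))
    triplets: List[Triplet] = []
    for a in range(len(X)):
        same = (labels == labels[a]) & (np.arange(len(X)) != a)
        diff = labels != labels[a]
        if not same.any() or not diff.any():
            continue
        pos_pool = np.flatnonzero(same)
        neg_pool = np.flatnonzero(diff)
        positive = pos_pool[np.argmax(D[a, pos_pool])]
        negative = neg_pool[np.argmin(D[a, neg_pool])]
        triplets.append(Triplet(a, int(positive), int(negative)))
    return triplets


def mine_hard_triplets(embeddings, M, plan: BatchPlan) -> List[Triplet]:
    """Batch-hard mining restricted to the images of a sampled batch plan.

    ``embeddings`` holds vectors (and labels) for the full indexed set; the
    returned triplets carry indices into that set.  An empty list signals
    that no anchor had a valid positive.
    """
    vectors = getattr(embeddings, "vectors", embeddings)
    labels = getattr(embeddings, "labels", None)
    if labels is None:
        raise ValueError("embeddings must carry labels for mining")
    idx = plan.flat_indices()
    if idx.max(initial=-1) >= len(vectors):
        raise ValueError("batch plan indexes beyond the embedding set")
    local = mine_hard_from_labels(
        np.asarray(vectors, float)[idx], np.asarray(labels, int)[idx], M
    )
    return [Triplet(int(idx[t.anchor]), int(idx[t.positive]), int(idx[t.negative])) for t in local]
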
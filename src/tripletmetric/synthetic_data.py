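"""Seeded synthetic image and tabular data with the statistical structure the
classifier assumes.

Two generators are provided.  ``generate_blob_images`` emulates a nodule
screening task: class 0 images are textured background only, higher classes
add one or more bright Gaussian blobs whose count and amplitude depend on the
class, so classes are separable by blob/texture statistics.  It is a synthetic
stand-in for chest-radiograph nodule data and makes no claim to radiographic
realism.  ``generate_tabular`` emulates a cytology table: nine ordinal
features on a 1-10 scale, benign records drawn low on the scale and malignant
records high, with ``inject_missing``/``drop_missing`` reproducing the
missing-value bookkeeping of such datasets.

All generators take an explicit seed and are bitwise reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "LabeledImageSet",
    "TabularSet",
    "FEATURE_NAMES",
    "generate_blob_images",
    "generate_tabular",
    "inject_missing",
    "drop_missing",
    "save_image_set",
    "load_image_set",
]

#: Cytological feature names, in the column order of the public
#: breast-cancer-wisconsin file dialect (id, 9 features, class).
FEATURE_NAMES = [
    "clump_thickness",
    "uniformity_cell_size",
    "uniformity_cell_shape",
    "marginal_adhesion",
    "single_epithelial_cell_size",
    "bare_nuclei",
    "bland_chromatin",
    "normal_nucleoli",
    "mitoses",
]


@dataclass
class LabeledImageSet:
    """Grayscale images with integer class labels and unique string ids.

    Intensities are 8-bit, in ``[0, 255]``; all images in a set share one
    shape.
    """

    images: list = field(default_factory=list)
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    ids: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.images) == len(self.labels) == len(self.ids)):
            raise ValueError("images, labels and ids must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("image ids must be unique")
        if len(self.labels) and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative integers")

    def __len__(self):
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def subset(self, indices) -> "LabeledImageSet":
        indices = np.asarray(indices, dtype=int)
        return LabeledImageSet(
            images=[self.images[i] for i in indices],
            labels=self.labels[indices],
            ids=[self.ids[i] for i in indices],
        )


@dataclass
class TabularSet:
    """Rows of 9 ordinal features in {1..10} with binary labels.

    Missing values are held as NaN in memory and serialized as ``"?"``,
    matching the public WBCD file convention.  Labels are 0 (benign analogue)
    and 1 (malignant analogue).
    """

    features: np.ndarray
    labels: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.size == 0:
            self.features = self.features.reshape(0, 9)
        if self.features.ndim != 2 or self.features.shape[1] != 9:
            raise ValueError("features must be an (n, 9) array")
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        if not self.ids:
            self.ids = [f"S{i:05d}" for i in range(len(self.labels))]
        vals = self.features[~np.isnan(self.features)]
        if vals.size and (
            (vals < 1).any() or (vals > 10).any() or (vals != np.round(vals)).any()
        ):
            raise ValueError("non-missing feature values must be integers in [1, 10]")
        if len(self.labels) and not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary")

    def __len__(self):
        return len(self.labels)

    @property
    def missing_row_mask(self) -> np.ndarray:
        return np.isnan(self.features).any(axis=1)

    def to_csv(self, path) -> None:
        """Write in the WBCD dialect: id, 9 features, class (2=benign,
        4=malignant), missing values as '?'."""
        df = pd.DataFrame(self.features, columns=FEATURE_NAMES)
        df.insert(0, "id", self.ids)
        df["class"] = np.where(self.labels == 0, 2, 4)
        for c in FEATURE_NAMES:
            df[c] = df[c].map(lambda v: "?" if np.isnan(v) else str(int(v)))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TabularSet":
        df = pd.read_csv(path, na_values=["?"])
        feats = df[FEATURE_NAMES].to_numpy(dtype=float)
        labels = (df["class"].to_numpy(dtype=int) == 4).astype(int)
        return cls(features=feats, labels=labels, ids=[str(i) for i in df["id"]])


def _textured_background(rng: np.random.Generator, size: int) -> np.ndarray:
    """Low-frequency random field plus fine grain, mean ~90, sd ~20."""
    field_ = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 8.0, mode="reflect")
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    return 90.0 + 18.0 * field_ + 6.0 * rng.standard_normal((size, size))


def generate_blob_images(
    n_classes: int,
    n_per_class: int,
    size: int = 64,
    contrast: float = 1.0,
    seed: int = 0,
) -> LabeledImageSet:
    """Generate a seeded set of textured grayscale images in ``n_classes``
    classes distinguished by bright-blob statistics.

    Class 0 images carry no blob; class ``c >= 1`` carries ``1 + (c-1) % 3``
    Gaussian blobs with class-dependent amplitude scaled by ``contrast``.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    if size < 32:
        raise ValueError("size must be >= 32")
    if not (0.0 < contrast <= 1.0):
        raise ValueError("contrast must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    images, labels, ids = [], [], []
    for c in range(n_classes):
        n_blobs = 0 if c == 0 else 1 + (c - 1) % 3
        for i in range(n_per_class):
            img = _textured_background(rng, size)
            for _ in range(n_blobs):
                cx, cy = rng.uniform(0.2 * size, 0.8 * size, size=2)
                sigma = rng.uniform(size / 14.0, size / 8.0)
                amp = contrast * (80.0 + 15.0 * c) * rng.uniform(0.8, 1.2)
                img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2))
            images.append(np.clip(img, 0.0, 255.0).astype(np.uint8))
            labels.append(c)
            ids.append(f"c{c}_{i:04d}")
    return LabeledImageSet(images=images, labels=np.array(labels), ids=ids)


def generate_tabular(n_benign: int, n_malignant: int, seed: int = 0) -> TabularSet:
    """Generate a WBCD-style table: benign rows low on the 1-10 ordinal
    scale, malignant rows high."""
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    benign = np.clip(np.round(rng.normal(2.5, 1.2, size=(n_benign, 9))), 1, 10)
    malignant = np.clip(np.round(rng.normal(7.0, 1.8, size=(n_malignant, 9))), 1, 10)
    feats = np.vstack([benign, malignant]) if (n_benign + n_malignant) else np.empty((0, 9))
    labels = np.concatenate([np.zeros(n_benign, int), np.ones(n_malignant, int)])
    return TabularSet(features=feats, labels=labels)


def inject_missing(table: TabularSet, n_rows: int, seed: int = 0) -> TabularSet:
    """Return a copy in which exactly ``n_rows`` additional rows carry at
    least one missing marker; all other rows are untouched."""
    if n_rows < 0:
        raise ValueError("n_rows must be nonnegative")
    if n_rows > len(table):
        raise ValueError("n_rows exceeds the number of rows")
    complete = np.flatnonzero(~table.missing_row_mask)
    if n_rows > len(complete):
        raise ValueError("not enough complete rows to mark as missing")
    rng = np.random.default_rng(seed)
    rows = rng.choice(complete, size=n_rows, replace=False)
    feats = table.features.copy()
    for r in rows:
        k = int(rng.integers(1, 3))  # 1 or 2 features blanked per row
        cols = rng.choice(9, size=k, replace=False)
        feats[r, cols] = np.nan
    return TabularSet(features=feats, labels=table.labels.copy(), ids=list(table.ids))


def drop_missing(table: TabularSet) -> TabularSet:
    """Drop every row containing a missing marker; row order is preserved.

    This is the invalid-data exclusion rule: records lacking an attribute
    value take no part in any experiment.
    """
    keep = np.flatnonzero(~table.missing_row_mask)
    return TabularSet(
        features=table.features[keep],
        labels=table.labels[keep],
        ids=[table.ids[i] for i in keep],
    )


def save_image_set(data: LabeledImageSet, directory) -> None:
    """Write images as 8-bit grayscale PNGs plus a labels.csv manifest."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    for img, label, id_ in zip(data.images, data.labels, data.ids):
        fname = f"{id_}.png"
        Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(
            os.path.join(directory, fname)
        )
        rows.append({"id": id_, "file": fname, "label": int(label)})
    pd.DataFrame(rows).to_csv(os.path.join(directory, "labels.csv"), index=False)


def load_image_set(directory) -> LabeledImageSet:
    manifest = pd.read_csv(os.path.join(directory, "labels.csv"))
    images, labels, ids = [], [], []
    for _, row in manifest.iterrows():
        with Image.open(os.path.join(directory, row["file"])) as im:
            images.append(np.asarray(im.convert("L"), dtype=np.uint8))
        labels.append(int(row["label"]))
        ids.append(str(row["id"]))
    return LabeledImageSet(images=images, labels=np.array(labels), ids=ids)
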
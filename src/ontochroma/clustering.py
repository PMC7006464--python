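"""Shared-palette color quantization by k-means.

RGB values hand-sampled from unstandardized photographs carry illumination
noise that is not biologically meaningful.  Quantizing all measurements to a
common palette of cluster colors (k-means in raw RGB space, followed by a
merge of redundant low-reflectance centers — blacks and near-blacks from
different photographs) makes between-species distances comparable.  The
default of k = 20 clusters with a darkness merge emulates the 20 -> 17
reduction used for the Australian butterfly dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .datamodel import ColorPatch, ColorPattern, ValidationError

__all__ = [
    "ClusterModel",
    "fit_color_clusters",
    "reduce_low_reflectance",
    "assign_clusters",
    "DEFAULT_K",
    "DEFAULT_DARKNESS_THRESHOLD",
]

DEFAULT_K = 20
#: Sum-over-channels threshold below which centers count as low reflectance.
DEFAULT_DARKNESS_THRESHOLD = 90.0
DEFAULT_N_INIT = 20


@dataclass
class ClusterModel:
    """A fitted RGB palette: cluster centers plus fit provenance."""

    centers: np.ndarray
    seed: int | None = None
    darkness_threshold: float | None = None
    counts: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValidationError("centers must be an array of RGB triples")
        if len(self.centers) < 1:
            raise ValidationError("model needs at least one center")
        if self.centers.min() < 0 or self.centers.max() > 255:
            raise ValidationError("centers outside channel bounds [0, 255]")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, float)

    @property
    def k(self) -> int:
        return len(self.centers)

    def nearest(self, rgb: np.ndarray) -> np.ndarray:
        """Index of the nearest center for each row of rgb (ties -> lowest index)."""
        rgb = np.atleast_2d(np.asarray(rgb, float))
        d2 = ((rgb[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centers": self.centers.tolist(),
            "k": self.k,
            "seed": self.seed,
            "darkness_threshold": self.darkness_threshold,
            "counts": None if self.counts is None else self.counts.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        counts = payload.get("counts")
        return cls(
            centers=np.asarray(payload["centers"], float),
            seed=payload.get("seed"),
            darkness_threshold=payload.get("darkness_threshold"),
            counts=None if counts is None else np.asarray(counts, float),
        )


def fit_color_clusters(
    rgb: np.ndarray | list,
    k: int = DEFAULT_K,
    seed: int = 1,
    n_init: int = DEFAULT_N_INIT,
) -> ClusterModel:
    """k-means on raw RGB triples; best of ``n_init`` restarts, seeded.

    Raises if there are fewer distinct points than requested centers.
    """
    rgb = np.asarray(rgb, float)
    if rgb.ndim != 2 or rgb.shape[1] != 3:
        raise ValidationError("expected an array of RGB triples")
    n_distinct = len(np.unique(rgb, axis=0))
    if n_distinct < k:
        raise ValidationError(
            f"{n_distinct} distinct colors but k={k} clusters requested"
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(rgb)
    counts = np.bincount(labels, minlength=k).astype(float)
    centers = np.clip(km.cluster_centers_, 0.0, 255.0)
    return ClusterModel(centers=centers, seed=seed, counts=counts)


def reduce_low_reflectance(
    model: ClusterModel, darkness_threshold: float = DEFAULT_DARKNESS_THRESHOLD
) -> ClusterModel:
    """Merge all centers with R+G+B below the threshold into one dark center.

    The merged center is the count-weighted mean of the dark centers
    (unweighted when the model has no fit counts).  Idempotent: the merged
    center is itself dark, and a second pass with the same threshold finds a
    single dark center and leaves the model unchanged.
    """
    sums = model.centers.sum(axis=1)
    dark = sums < darkness_threshold
    if dark.sum() < 2:
        return ClusterModel(
            centers=model.centers.copy(),
            seed=model.seed,
            darkness_threshold=darkness_threshold,
            counts=None if model.counts is None else model.counts.copy(),
        )
    w = model.counts[dark] if model.counts is not None else np.ones(dark.sum())
    merged = np.average(model.centers[dark], axis=0, weights=w)
    centers = np.vstack([model.centers[~dark], merged])
    counts = None
    if model.counts is not None:
        counts = np.concatenate([model.counts[~dark], [w.sum()]])
    return ClusterModel(
        centers=centers,
        seed=model.seed,
        darkness_threshold=darkness_threshold,
        counts=counts,
    )


def assign_clusters(
    patterns: list[ColorPattern], model: ClusterModel
) -> list[ColorPattern]:
    """Snap every patch's RGB to its nearest palette center.

    Area categories are untouched; the returned patterns carry the
    "RGB-cluster" values all downstream distances operate on.  Idempotent.
    """
    if model.k < 1:
        raise ValidationError("empty cluster model")
    out = []
    for p in patterns:
        rgb = np.array([patch.rgb for patch in p.patches], float)
        idx = model.nearest(rgb)
        new_patches = tuple(
            ColorPatch(
                r=int(round(model.centers[i][0])),
                g=int(round(model.centers[i][1])),
                b=int(round(model.centers[i][2])),
                area_category=patch.area_category,
            )
            for patch, i in zip(p.patches, idx)
        )
        out.append(p.with_patches(new_patches))
    return out
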
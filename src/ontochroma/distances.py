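"""Between-species color distances and conspicuousness scores.

Three pairwise metrics on species color patterns, all in raw RGB space:

* **A — Euclidean 6-D**: distance between the brightest-first primary-color
  vectors.  Uses only the two primary colors.
* **B — area-weighted Euclidean**: expected RGB distance between a random
  patch of one species and a random patch of the other, patches drawn with
  their normalized area weights (independent coupling over all colors).
* **C — earth mover's distance**: minimum-cost transport of one species'
  area-weighted color mass onto the other's, ground cost Euclidean RGB
  distance.  Always <= metric B, since the optimal transport plan can never
  cost more than the independent coupling.

Plus two within-species scores used by the antipredator-strategy analysis:
internal contrast (how different a pattern's own colors are from each other)
and background distance (how far a pattern sits from natural green and brown
backgrounds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist, pdist, squareform

from .clustering import ClusterModel, assign_clusters
from .datamodel import (
    ColorPattern,
    StageDataset,
    ValidationError,
    normalized_weights,
    pattern_vector,
)

__all__ = [
    "WeightedPattern",
    "distance_euclidean6",
    "distance_area_weighted",
    "distance_emd",
    "pairwise_matrix",
    "internal_contrast",
    "background_distance",
    "DistanceMatrix",
]

METRICS = ("A", "B", "C")


@dataclass
class DistanceMatrix:
    """Symmetric species x species dissimilarities with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal is not zero")
        if self.values.min() < -1e-9:
            raise ValidationError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels), values=self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        return squareform(self.values, checks=False)


@dataclass
class WeightedPattern:
    """A pattern as a discrete color distribution: colors + area weights."""

    colors: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.colors = np.atleast_2d(np.asarray(self.colors, float))
        self.weights = np.asarray(self.weights, float).ravel()
        if len(self.colors) != len(self.weights):
            raise ValidationError("colors and weights differ in length")
        if (self.weights < 0).any():
            raise ValidationError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"weights sum to {self.weights.sum():.12f}, not 1"
            )

    @classmethod
    def from_pattern(cls, pattern: ColorPattern) -> "WeightedPattern":
        colors = np.array([p.rgb for p in pattern.patches], float)
        return cls(colors=colors, weights=normalized_weights(pattern))


def distance_euclidean6(a: ColorPattern, b: ColorPattern) -> float:
    """Metric A: Euclidean distance between 6-D primary-color vectors."""
    return float(np.linalg.norm(pattern_vector(a) - pattern_vector(b)))


def _as_weighted(x) -> WeightedPattern:
    return x if isinstance(x, WeightedPattern) else WeightedPattern.from_pattern(x)


def distance_area_weighted(a, b) -> float:
    """Metric B: expected cross-species patch distance under area weights.

    sum_i sum_j w_i^a w_j^b ||c_i^a - c_j^b||.  Zero-weight colors are
    impossible by construction (weights strictly positive).
    """
    a, b = _as_weighted(a), _as_weighted(b)
    ground = cdist(a.colors, b.colors)
    return float(a.weights @ ground @ b.weights)


def distance_emd(a, b, tol: float = 1e-8) -> float:
    """Metric C: earth mover's distance, solved as a transportation LP.

    Both sides carry total mass 1, so the transport polytope is nonempty and
    bounded; the optimum is found by ``scipy.optimize.linprog`` (HiGHS) to
    the requested tolerance.
    """
    a, b = _as_weighted(a), _as_weighted(b)
    m, n = len(a.weights), len(b.weights)
    ground = cdist(a.colors, b.colors)
    # Variables f_ij >= 0, row sums = a.weights, col sums = b.weights.
    A_eq = np.zeros((m + n, m * n))
    for i in range(m):
        A_eq[i, i * n : (i + 1) * n] = 1.0
    for j in range(n):
        A_eq[m + j, j::n] = 1.0
    b_eq = np.concatenate([a.weights, b.weights])
    res = linprog(
        ground.ravel(),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=(0, None),
        method="highs",
        options={"primal_feasibility_tolerance": tol, "dual_feasibility_tolerance": tol},
    )
    if not res.success:
        raise RuntimeError(
            f"transportation LP failed ({m}x{n} instance): {res.message}"
        )
    return float(res.fun)


_METRIC_FUNCS = {
    "A": distance_euclidean6,
    "B": distance_area_weighted,
    "C": distance_emd,
}


def pairwise_matrix(
    dataset: StageDataset,
    metric: str = "A",
    model: ClusterModel | None = None,
) -> DistanceMatrix:
    """All pairwise distances between the dataset's species, in label order.

    With a cluster model, patterns are palette-assigned first ("RGB-cluster"
    values); metric A is vectorized through ``pdist``, B and C loop pairs.
    """
    if metric not in _METRIC_FUNCS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    species = dataset.species
    if len(species) < 2:
        raise ValidationError("need at least 2 species for a distance matrix")
    patterns = [dataset[s] for s in species]
    if model is not None:
        patterns = assign_clusters(patterns, model)

    n = len(species)
    if metric == "A":
        X = np.vstack([pattern_vector(p) for p in patterns])
        values = squareform(pdist(X))
    else:
        func = _METRIC_FUNCS[metric]
        weighted = [WeightedPattern.from_pattern(p) for p in patterns]
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = func(weighted[i], weighted[j])
    return DistanceMatrix(labels=species, values=values)


def internal_contrast(
    pattern: ColorPattern, aggregation: str = "max"
) -> float:
    """Within-individual color contrast over all patches (any area category).

    Default is the maximum pairwise RGB distance — a black + bright-yellow
    pattern scores the full black-to-yellow distance no matter how small the
    yellow patch is, matching how high-contrast warning patterns are judged.
    ``aggregation="weighted_mean"`` averages pairwise distances with products
    of area weights instead.  Single-patch patterns score 0.
    """
    if len(pattern.patches) == 1:
        return 0.0
    colors = np.array([p.rgb for p in pattern.patches], float)
    d = cdist(colors, colors)
    if aggregation == "max":
        return float(d.max())
    if aggregation == "weighted_mean":
        w = normalized_weights(pattern)
        ww = np.outer(w, w)
        np.fill_diagonal(ww, 0.0)
        if ww.sum() == 0:
            return 0.0
        return float((ww * d).sum() / ww.sum())
    raise ValidationError(f"unknown aggregation {aggregation!r}")


def background_distance(
    pattern: ColorPattern,
    greens: np.ndarray,
    browns: np.ndarray,
    mode: str = "mean_pooled",
) -> float:
    """Area-weighted RGB distance of a pattern from natural backgrounds.

    Per background sample s, score = sum_i w_i ||c_i - s||.  ``mean_pooled``
    (default) averages the score over all green and brown samples pooled;
    ``min_per_background`` takes the smaller of the two per-set means —
    crypsis against either background suffices to look cryptic.
    """
    greens = np.atleast_2d(np.asarray(greens, float))
    browns = np.atleast_2d(np.asarray(browns, float))
    if greens.size == 0 or browns.size == 0:
        raise ValidationError("background sets must be nonempty")
    colors = np.array([p.rgb for p in pattern.patches], float)
    w = normalized_weights(pattern)
    score_green = w @ cdist(colors, greens)  # one score per green sample
    score_brown = w @ cdist(colors, browns)
    if mode == "mean_pooled":
        return float(np.concatenate([score_green, score_brown]).mean())
    if mode == "min_per_background":
        return float(min(score_green.mean(), score_brown.mean()))
    raise ValidationError(f"unknown mode {mode!r}")
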
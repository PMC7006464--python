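"""Stage-coupling and color-diversity statistics.

Three questions about larval vs. adult color, each answered by a
permutation procedure:

* **Mantel test** — do species that resemble each other as caterpillars also
  resemble each other as adults?  Pearson correlation between the two
  stages' between-species distance matrices, significance by jointly
  permuting one matrix's rows and columns.
* **Color diversity D** — the mean of all between-species color distances
  within a stage; the stage occupying more color space has the larger D.
* **D_dif test** — D_caterpillar - D_adult, with a null built by permuting
  stage identity.  Significantly negative D_dif means adults have diverged
  in color relative to caterpillars (ontogenetic divergence); positive means
  adult convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .clustering import ClusterModel, assign_clusters
from .datamodel import StageDataset, ValidationError, pattern_vector
from .distances import DistanceMatrix, WeightedPattern, _METRIC_FUNCS, pairwise_matrix

__all__ = [
    "MantelResult",
    "DdifResult",
    "mantel",
    "diversity_D",
    "ddif_test",
    "pca_colorspace",
]

logger = logging.getLogger(__name__)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    tail: str
    n_species: int


def _centered_offdiag(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Center a symmetric zero-diagonal matrix on its triangle mean.

    Returns the full centered matrix (diagonal zeroed) and the Frobenius
    norm of its upper triangle; both are invariant to joint row/column
    permutation, which is what makes the permutation loop cheap.
    """
    tri = squareform(values, checks=False)
    centered = values - tri.mean()
    np.fill_diagonal(centered, 0.0)
    norm = np.sqrt((tri - tri.mean()) @ (tri - tri.mean()))
    return centered, float(norm)


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_perm: int = 10_000,
    tail: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Matrix correlation with a joint row/column permutation null.

    ``dy`` is reordered to ``dx``'s labels; the statistic is the Pearson
    correlation of the N(N-1)/2 upper-triangle entries.  ``tail="greater"``
    (the default) asks whether the matrices are positively coupled;
    ``"two_sided"`` uses |r|.  P carries the +1 correction so it is never 0.
    """
    if tail not in ("greater", "two_sided"):
        raise ValidationError(f"unknown tail {tail!r}")
    if set(dx.labels) != set(dy.labels):
        raise ValidationError("distance matrices have different label sets")
    n = dx.n
    if n < 3:
        raise ValidationError("need at least 3 species for a Mantel test")
    dy = dy.reorder(dx.labels)

    Xc, xnorm = _centered_offdiag(dx.values)
    Yc, ynorm = _centered_offdiag(dy.values)
    if xnorm == 0 or ynorm == 0:
        raise ValidationError("zero variance in a distance matrix triangle")
    scale = xnorm * ynorm
    r_obs = float((Xc * Yc).sum() / 2.0 / scale)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        p = rng.permutation(n)
        null[b] = (Xc * Yc[np.ix_(p, p)]).sum() / 2.0 / scale
    if tail == "greater":
        extreme = np.sum(null >= r_obs)
    else:
        extreme = np.sum(np.abs(null) >= abs(r_obs))
    p_value = (1.0 + extreme) / (n_perm + 1.0)
    return MantelResult(
        r=r_obs, p_value=float(p_value), n_perm=n_perm, tail=tail, n_species=n
    )


def diversity_D(
    dataset: StageDataset,
    metric: str = "A",
    model: ClusterModel | None = None,
    group_by: dict[str, str] | None = None,
):
    """Mean between-species color distance (color diversity, D).

    Ungrouped, returns a float.  With ``group_by`` mapping species to family,
    returns a dict with one D per family (groups with < 2 species skipped
    with a warning) plus the pooled value under key ``"overall"``.
    """
    dm = pairwise_matrix(dataset, metric=metric, model=model)
    overall = float(dm.condensed().mean())
    if group_by is None:
        return overall
    out: dict[str, float] = {"overall": overall}
    families: dict[str, list[str]] = {}
    for sp in dataset.species:
        families.setdefault(group_by.get(sp, "unassigned"), []).append(sp)
    for fam, members in sorted(families.items()):
        if len(members) < 2:
            logger.warning("group %r has %d species; skipped", fam, len(members))
            continue
        sub = dm.reorder(members)
        out[fam] = float(sub.condensed().mean())
    return out


@dataclass
class DdifResult:
    d_caterpillar: float
    d_adult: float
    d_dif: float
    p_lower: float
    p_upper: float
    n_perm: int
    metric: str
    scheme: str
    perm_values: np.ndarray | None = field(default=None, repr=False)


def _combined_distance_matrix(patterns: list, metric: str) -> np.ndarray:
    if metric == "A":
        X = np.vstack([pattern_vector(p) for p in patterns])
        return squareform(pdist(X))
    func = _METRIC_FUNCS[metric]
    weighted = [WeightedPattern.from_pattern(p) for p in patterns]
    n = len(weighted)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = func(weighted[i], weighted[j])
    return values


def _subset_mean(values: np.ndarray, idx: np.ndarray) -> float:
    sub = values[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub.sum() / (n * (n - 1)))


def ddif_test(
    cats: StageDataset,
    adults: StageDataset,
    metric: str = "A",
    n_perm: int = 1000,
    scheme: str = "within_species_swap",
    seed: int | None = None,
    model: ClusterModel | None = None,
    keep_null: bool = False,
) -> DdifResult:
    """Permutation test for D_dif = D_caterpillar - D_adult.

    The default null swaps each species' caterpillar and adult patterns with
    probability 1/2 (preserving the species pairing and per-species color
    content while breaking stage identity); ``free_relabel`` instead
    partitions the pooled 2N patterns into two arbitrary stage groups of N.
    ``p_lower`` is the +1-corrected proportion of permuted D_dif <= observed
    (small p_lower: adults significantly more diverse), ``p_upper`` the
    proportion >= observed.  Ties count as extreme on both sides, so the two
    probabilities can sum to more than 1.
    """
    if metric not in _METRIC_FUNCS:
        raise ValidationError(f"unknown metric {metric!r}")
    if scheme not in ("within_species_swap", "free_relabel"):
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    if set(cats.patterns) != set(adults.patterns):
        raise ValidationError(
            "caterpillar and adult datasets must cover the same species"
        )
    species = cats.species
    n = len(species)
    if n < 2:
        raise ValidationError("need at least 2 species")
    patterns = [cats[s] for s in species] + [adults[s] for s in species]
    if model is not None:
        patterns = assign_clusters(patterns, model)
    values = _combined_distance_matrix(patterns, metric)

    cat_idx = np.arange(n)
    adult_idx = np.arange(n, 2 * n)
    d_cat = _subset_mean(values, cat_idx)
    d_adult = _subset_mean(values, adult_idx)
    observed = d_cat - d_adult

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        if scheme == "within_species_swap":
            swap = rng.integers(0, 2, size=n).astype(bool)
            ci = np.where(swap, adult_idx, cat_idx)
            ai = np.where(swap, cat_idx, adult_idx)
        else:
            p = rng.permutation(2 * n)
            ci, ai = p[:n], p[n:]
        null[b] = _subset_mean(values, ci) - _subset_mean(values, ai)
    p_lower = (1.0 + np.sum(null <= observed)) / (n_perm + 1.0)
    p_upper = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return DdifResult(
        d_caterpillar=d_cat,
        d_adult=d_adult,
        d_dif=observed,
        p_lower=float(p_lower),
        p_upper=float(p_upper),
        n_perm=n_perm,
        metric=metric,
        scheme=scheme,
        perm_values=null if keep_null else None,
    )


def pca_colorspace(datasets: list[StageDataset]) -> pd.DataFrame:
    """PCA of the stacked 6-D color vectors, for visualization only.

    Returns one row per pattern with its scores on the first two principal
    components; ``attrs["explained_variance_ratio"]`` carries the variance
    shares.  No downstream statistic consumes these coordinates.
    """
    rows = []
    vectors = []
    for d in datasets:
        for sp in d.species:
            rows.append({"dataset": d.label, "species": sp})
            vectors.append(pattern_vector(d[sp]))
    if len(vectors) < 3:
        raise ValidationError("need at least 3 patterns for a PCA")
    X = np.vstack(vectors)
    if np.allclose(X.var(axis=0), 0.0):
        raise ValidationError("zero-variance color data; PCA undefined")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(X)
    df = pd.DataFrame(rows)
    df["pc1"] = scores[:, 0]
    df["pc2"] = scores[:, 1]
    df.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return df
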
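"""Multivariate phylogenetic signal (Blomberg's K extended to p traits).

K compares the trait variance observed among species with the variance
expected if the traits had evolved by Brownian motion along the given tree.
With C the Brownian covariance, a-hat the GLS estimate of the root state

    a-hat = (1' C^-1 1)^-1 1' C^-1 X,   E = X - 1 a-hat',

the statistic is

    K = [ tr(E'E) / tr(E' C^-1 E) ]  /  [ (tr(C) - N / (1' C^-1 1)) / (N-1) ].

K = 1 in expectation under Brownian motion; K < 1 means close relatives
resemble each other less than Brownian motion predicts (signal erased, e.g.
by stage-specific selection), K > 1 more.  Significance is assessed by
permuting species' trait rows across the tips of the tree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .datamodel import StageDataset, ValidationError
from .phylo import PhyloCovariance, covariance_for_species, match_and_prune, normalize_species_id

__all__ = [
    "KmultResult",
    "SignalComparison",
    "kmult",
    "kmult_test",
    "kmult_test_matrix",
    "signal_over_posterior",
]

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """All trait rows identical; K is undefined (0/0)."""


def _inverse_with_ridge(C: np.ndarray) -> np.ndarray:
    """Invert a Brownian covariance via Cholesky, ridging if necessary.

    Posterior trees can carry zero-length terminal branches, which make two
    tips exactly exchangeable and C singular; a tiny ridge restores
    invertibility without materially changing the statistic.
    """
    n = C.shape[0]
    ridge_scale = np.mean(np.diag(C))
    for eps in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            factor = cho_factor(C + eps * ridge_scale * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            continue
        if eps:
            warnings.warn(
                f"phylogenetic covariance singular; ridged with "
                f"{eps:g} * mean(diag)",
                stacklevel=3,
            )
        return cho_solve(factor, np.eye(n))
    raise np.linalg.LinAlgError("covariance not invertible even after ridging")


@dataclass
class _KmultWorkspace:
    """Pieces of the K statistic that depend on the tree only."""

    Cinv: np.ndarray
    w: np.ndarray  # GLS mean weights: C^-1 1 / (1' C^-1 1)
    denominator: float  # (tr(C) - N / (1' C^-1 1)) / (N - 1)

    @classmethod
    def build(cls, C: np.ndarray) -> "_KmultWorkspace":
        C = np.asarray(C, float)
        n = C.shape[0]
        if n < 3:
            raise ValidationError(f"need >= 3 species, got {n}")
        Cinv = _inverse_with_ridge(C)
        Cinv1 = Cinv.sum(axis=1)
        s = Cinv1.sum()
        denominator = (np.trace(C) - n / s) / (n - 1)
        return cls(Cinv=Cinv, w=Cinv1 / s, denominator=denominator)

    def k(self, X: np.ndarray) -> float:
        if np.allclose(X, X[0]):
            raise DegenerateDataError("all trait rows identical; K undefined")
        a_hat = self.w @ X
        E = X - a_hat
        num = (E * E).sum()
        den = (E * (self.Cinv @ E)).sum()
        return float((num / den) / self.denominator)

    def k_batch(self, Xs: np.ndarray) -> np.ndarray:
        """K for a stack of trait matrices (B, N, p) sharing this tree."""
        a_hat = np.einsum("j,bjp->bp", self.w, Xs)
        E = Xs - a_hat[:, None, :]
        num = (E * E).sum(axis=(1, 2))
        CE = np.einsum("ij,bjp->bip", self.Cinv, E)
        den = (E * CE).sum(axis=(1, 2))
        return (num / den) / self.denominator


def kmult(X: np.ndarray, cov: PhyloCovariance | np.ndarray) -> float:
    """The K statistic for an N x p trait matrix, rows ordered as the labels of C."""
    C = cov.C if isinstance(cov, PhyloCovariance) else np.asarray(cov, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.ndim == 2 and X.shape[0] == 1:
        X = X.T  # a single trait passed as a flat vector
    if X.shape[0] != C.shape[0]:
        raise ValidationError(
            f"trait matrix has {X.shape[0]} rows but covariance is "
            f"{C.shape[0]} x {C.shape[0]}"
        )
    return _KmultWorkspace.build(C).k(X)


@dataclass
class KmultResult:
    k: float
    p_value: float
    n_perm: int
    n_species: int
    perm_values: np.ndarray | None = field(default=None, repr=False)


def kmult_test_matrix(
    X: np.ndarray,
    cov: PhyloCovariance | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    keep_null: bool = False,
) -> KmultResult:
    """Permutation test on a raw trait matrix.

    The null shuffles which species' trait row sits at which tip; the
    one-sided P-value is (1 + #{K_perm >= K_obs}) / (n_perm + 1).
    """
    C = cov.C if isinstance(cov, PhyloCovariance) else np.asarray(cov, float)
    X = np.asarray(X, float)
    if n_perm < 99:
        raise ValidationError(f"n_perm={n_perm} too small; need >= 99")
    ws = _KmultWorkspace.build(C)
    observed = ws.k(X)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    null = ws.k_batch(X[perms])
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return KmultResult(
        k=observed,
        p_value=float(p),
        n_perm=n_perm,
        n_species=n,
        perm_values=null if keep_null else None,
    )


def kmult_test(
    dataset: StageDataset,
    tree: dendropy.Tree,
    n_perm: int = 999,
    seed: int | None = None,
) -> KmultResult:
    """Match species to the tree, vectorize patterns, and run the K test."""
    matched, pruned = match_and_prune(dataset, tree)
    species = matched.species
    X = matched.vector_matrix(species)
    cov = covariance_for_species(pruned, species)
    return kmult_test_matrix(X, cov, n_perm=n_perm, seed=seed)


@dataclass
class SignalComparison:
    """Per-tree K values for several datasets against a reference dataset."""

    reference: str
    labels: list[str]
    # per non-reference label: list of (k_reference, k_other, difference)
    per_tree: dict[str, list[tuple[float, float, float]]]
    n_trees_used: int
    n_trees_skipped: int

    @property
    def fraction_positive(self) -> dict[str, float]:
        """Per comparison, the fraction of trees where K_other - K_ref > 0."""
        return {
            lbl: float(np.mean([d > 0 for _, _, d in vals])) if vals else float("nan")
            for lbl, vals in self.per_tree.items()
        }


def signal_over_posterior(
    datasets: list[StageDataset],
    trees: list[dendropy.Tree],
    reference: str,
) -> SignalComparison:
    """Observed K per dataset on every tree of a posterior sample.

    For each tree, all datasets are restricted to the species common to every
    dataset and the tree, so the K values are comparable; trees with fewer
    than 3 usable species are skipped with a warning.  The summary records,
    per non-reference dataset, the fraction of trees on which its K exceeds
    the reference's — the posterior support for a signal difference.
    """
    labels = [d.label for d in datasets]
    if reference not in labels:
        raise ValidationError(f"reference {reference!r} not among {labels}")
    if not trees:
        raise ValidationError("no trees supplied")
    per_tree: dict[str, list[tuple[float, float, float]]] = {
        lbl: [] for lbl in labels if lbl != reference
    }
    used = skipped = 0
    norm_sets = [
        {normalize_species_id(s): s for s in d.patterns} for d in datasets
    ]
    for ti, tree in enumerate(trees):
        common = set(norm_sets[0])
        for ns in norm_sets[1:]:
            common &= set(ns)
        common &= {normalize_species_id(t.label) for t in tree.taxon_namespace}
        if len(common) < 3:
            logger.warning("tree %d: only %d matched species; skipped", ti, len(common))
            skipped += 1
            continue
        keys = sorted(common)
        pruned = tree.clone(depth=1)
        pruned.retain_taxa(
            [t for t in pruned.taxon_namespace
             if normalize_species_id(t.label) in common]
        )
        k_by_label = {}
        ws = None
        for d, ns in zip(datasets, norm_sets):
            species = [ns[k] for k in keys]
            X = d.vector_matrix(species)
            if ws is None:
                cov = covariance_for_species(pruned, species)
                ws = _KmultWorkspace.build(cov.C)
            k_by_label[d.label] = ws.k(X)
        k_ref = k_by_label[reference]
        for lbl in per_tree:
            k_other = k_by_label[lbl]
            per_tree[lbl].append((k_ref, k_other, k_other - k_ref))
        used += 1
    if used == 0:
        raise ValidationError("no tree had >= 3 matched species")
    return SignalComparison(
        reference=reference,
        labels=labels,
        per_tree=per_tree,
        n_trees_used=used,
        n_trees_skipped=skipped,
    )
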
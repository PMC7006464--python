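"""Phylogenetic generalized least squares and posterior-sample summaries.

PGLS is ordinary regression with error covariance proportional to the
Brownian covariance of the tree: residuals of close relatives are allowed to
be correlated.  With C_lambda the Pagel-transformed covariance
(off-diagonal entries scaled by lambda, tip variances kept),

    beta = (X' C^-1 X)^-1 X' C^-1 y,
    se   = sqrt(diag(sigma2 * (X' C^-1 X)^-1)),   sigma2 = r' C^-1 r / df,

with t = beta / se referred to a t distribution on df = N - k.  Because
comparative studies rarely have a single known tree, the fit can be repeated
over a posterior sample of trees and each parameter summarized by its
highest-posterior-density (HPD) interval — the shortest window containing
the stated fraction of per-tree values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .datamodel import ValidationError
from .phylo import PhyloCovariance, covariance_for_species, lambda_transform, normalize_species_id

__all__ = ["PglsFit", "PosteriorSummary", "pgls_fit", "pgls_over_posterior", "hpd"]


@dataclass
class PglsFit:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float
    df: int
    lam: float
    loglik: float
    term_names: list[str] = field(default_factory=list)


def _gls(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    n, k = X.shape
    try:
        factor = cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        factor = cho_factor(C + 1e-10 * np.mean(np.diag(C)) * np.eye(n), lower=True)
    Ci_X = cho_solve(factor, X)
    Ci_y = cho_solve(factor, y)
    XtCiX = X.T @ Ci_X
    try:
        XtCiX_inv = np.linalg.inv(XtCiX)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular design matrix") from exc
    beta = XtCiX_inv @ (X.T @ Ci_y)
    resid = y - X @ beta
    Ci_r = cho_solve(factor, resid)
    rss = float(resid @ Ci_r)
    logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
    return beta, XtCiX_inv, rss, logdet


def _loglik(rss: float, logdet: float, n: int) -> float:
    sigma2_ml = rss / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)


def pgls_fit(
    y: np.ndarray,
    x: np.ndarray,
    cov: PhyloCovariance | np.ndarray,
    lam: float | str = 1.0,
    add_intercept: bool = True,
    term_names: list[str] | None = None,
) -> PglsFit:
    """GLS regression under a (lambda-scaled) Brownian covariance.

    ``y`` and the columns of ``x`` must be ordered as the covariance labels.
    ``lam`` is a fixed branch-length scaling in [0, 1] (1 = pure Brownian,
    the default) or ``"ml"`` for a bounded maximum-likelihood search.
    Binary predictors (e.g. contrasting vs. not) are fit by the same
    machinery with a 0/1 encoding.
    """
    C = cov.C if isinstance(cov, PhyloCovariance) else np.asarray(cov, float)
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(x, float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    n, k = X.shape
    if C.shape != (n, n):
        raise ValidationError(
            f"covariance is {C.shape} but data has {n} rows"
        )
    if n <= k:
        raise ValidationError(f"N={n} too small for {k} coefficients")

    if lam == "ml":
        res = minimize_scalar(
            lambda l: -_loglik(*_gls(y, X, lambda_transform(C, l))[2:4], n),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        lam_hat = float(res.x)
    else:
        lam_hat = float(lam)
    Cl = lambda_transform(C, lam_hat)
    beta, XtCiX_inv, rss, logdet = _gls(y, X, Cl)
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(sigma2 * np.diag(XtCiX_inv))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    if term_names is None:
        term_names = (["intercept"] if add_intercept else []) + [
            f"x{i}" for i in range(k - int(add_intercept))
        ]
    return PglsFit(
        beta=beta,
        se=se,
        t=t,
        p=p,
        sigma2=float(sigma2),
        df=df,
        lam=lam_hat,
        loglik=_loglik(rss, logdet, n),
        term_names=term_names,
    )


def hpd(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest window of the sorted sample containing ceil(prob * n) values.

    Ties between equally short windows go to the earliest (leftmost) one,
    so the interval is deterministic.
    """
    s = np.sort(np.asarray(samples, float).ravel())
    n = len(s)
    if n < 2:
        raise ValidationError("need at least 2 samples for an HPD interval")
    if not (0.0 < prob < 1.0):
        raise ValidationError(f"prob must be in (0, 1), got {prob}")
    m = int(np.ceil(prob * n))
    m = max(2, min(m, n))
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: earliest window
    return float(s[i]), float(s[i + m - 1])


@dataclass
class PosteriorSummary:
    """Per-tree PGLS fits plus HPD intervals across a posterior tree sample."""

    fits: list[PglsFit]
    prob: float
    term_names: list[str]
    hpd_estimate: list[tuple[float, float]]
    hpd_t: list[tuple[float, float]]
    hpd_p: list[tuple[float, float]]

    @property
    def n_trees(self) -> int:
        return len(self.fits)

    def estimates(self, term: int | str = 1) -> np.ndarray:
        i = self.term_names.index(term) if isinstance(term, str) else term
        return np.array([f.beta[i] for f in self.fits])


def pgls_over_posterior(
    y: dict[str, float],
    x: dict[str, float],
    trees: list[dendropy.Tree],
    prob: float = 0.95,
    lam: float | str = 1.0,
) -> PosteriorSummary:
    """Repeat a PGLS fit over every tree and HPD-summarize each parameter.

    ``y`` and ``x`` map species ids to values; per tree, the fit uses the
    species present in both maps and among that tree's tips.  HPD intervals
    of estimate, t, and P are computed per term across trees.
    """
    if len(trees) < 2:
        raise ValidationError("need at least 2 trees for a posterior summary")
    common = set(y) & set(x)
    fits: list[PglsFit] = []
    term_names: list[str] = []
    for tree in trees:
        tip_norm = {normalize_species_id(t.label) for t in tree.taxon_namespace}
        species = sorted(s for s in common if normalize_species_id(s) in tip_norm)
        if len(species) < 4:
            continue
        pruned = tree.clone(depth=1)
        pruned.retain_taxa(
            [t for t in pruned.taxon_namespace
             if normalize_species_id(t.label) in {normalize_species_id(s) for s in species}]
        )
        cov = covariance_for_species(pruned, species)
        yv = np.array([y[s] for s in species])
        xv = np.array([x[s] for s in species])
        fit = pgls_fit(yv, xv, cov, lam=lam, term_names=["intercept", "slope"])
        fits.append(fit)
        term_names = fit.term_names
    if not fits:
        raise ValidationError("no tree could be matched to the data")
    k = len(fits[0].beta)
    hpd_estimate = [hpd([f.beta[i] for f in fits], prob) for i in range(k)]
    hpd_t = [hpd([f.t[i] for f in fits], prob) for i in range(k)]
    hpd_p = [hpd([f.p[i] for f in fits], prob) for i in range(k)]
    return PosteriorSummary(
        fits=fits,
        prob=prob,
        term_names=term_names,
        hpd_estimate=hpd_estimate,
        hpd_t=hpd_t,
        hpd_p=hpd_p,
    )
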
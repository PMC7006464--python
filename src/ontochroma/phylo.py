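"""Phylogenetic plumbing: Brownian covariance matrices and species matching.

Under Brownian motion on a rooted tree with branch lengths, trait covariance
between two tips is proportional to the branch length their root-to-tip paths
share, i.e. the depth of their most recent common ancestor.  ``PhyloCovariance``
holds that N x N matrix together with its tip-label order; it is the backbone
of both the multivariate phylogenetic-signal statistic and PGLS.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import dendropy
import numpy as np

from .datamodel import StageDataset, ValidationError

__all__ = [
    "PhyloCovariance",
    "phylo_covariance",
    "normalize_species_id",
    "match_and_prune",
    "lambda_transform",
]

logger = logging.getLogger(__name__)


@dataclass
class PhyloCovariance:
    """Brownian trait covariance among tips: C[i,j] = depth of MRCA(i, j)."""

    labels: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, float)
        n = len(self.labels)
        if self.C.shape != (n, n):
            raise ValidationError(
                f"covariance shape {self.C.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.C, self.C.T):
            raise ValidationError("covariance matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: list[str]) -> "PhyloCovariance":
        idx = [self.labels.index(l) for l in labels]
        return PhyloCovariance(labels=list(labels), C=self.C[np.ix_(idx, idx)])


def phylo_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Build the Brownian covariance of a rooted tree with branch lengths.

    Each edge contributes its length to C[i,j] for every pair of tips below
    it (including i == j), which sums exactly the shared root-to-tip path
    lengths.  Raises on unrooted trees, missing branch lengths, or negative
    branch lengths.
    """
    if not tree.is_rooted:
        raise ValidationError("tree is unrooted; Brownian covariance needs a root")
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValidationError(f"tree has {len(leaves)} tips; need at least 3")
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate tip labels")
    index = {id(lf): i for i, lf in enumerate(leaves)}

    n = len(leaves)
    C = np.zeros((n, n))
    # Postorder pass: collect tip indices below each node, then add each
    # edge's length over the block of its descendant tips.
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips = [index[id(node)]]
        else:
            tips = []
            for ch in node.child_nodes():
                tips.extend(below.pop(id(ch)))
        below[id(node)] = tips
        if node.parent_node is not None:
            if node.edge.length is None:
                raise ValidationError(
                    f"edge above {node.taxon.label if node.taxon else 'internal node'} "
                    f"has no branch length"
                )
            if node.edge.length < 0:
                raise ValidationError("negative branch length")
            if node.edge.length:
                ix = np.array(tips)
                C[np.ix_(ix, ix)] += node.edge.length
    return PhyloCovariance(labels=labels, C=C)


_WS = re.compile(r"[\s_]+")


def normalize_species_id(name: str) -> str:
    """Canonical species key: lowercase, underscores/whitespace collapsed."""
    return _WS.sub(" ", name.strip()).lower()


def match_and_prune(
    dataset: StageDataset, tree: dendropy.Tree
) -> tuple[StageDataset, dendropy.Tree]:
    """Restrict a dataset and a tree to their common species.

    Matching is on normalized ids (photograph tables and trees typically
    differ in case and underscore conventions).  The tree is pruned on a
    clone; the input tree is untouched.  Raises if fewer than 3 species
    remain.
    """
    ds_norm = {normalize_species_id(s): s for s in dataset.patterns}
    tree_taxa = {normalize_species_id(t.label): t for t in tree.taxon_namespace}
    common = sorted(set(ds_norm) & set(tree_taxa))
    if len(common) < 3:
        raise ValidationError(
            f"only {len(common)} species shared between dataset "
            f"{dataset.label!r} and tree; need at least 3"
        )
    logger.info(
        "matched %d species between dataset %r (%d) and tree (%d tips)",
        len(common), dataset.label, len(dataset), len(tree.taxon_namespace),
    )
    pruned_ds = dataset.subset([ds_norm[k] for k in common])
    pruned_tree = tree.clone(depth=1)
    pruned_tree.migrate_taxon_namespace(dendropy.TaxonNamespace())
    keep = [t for t in pruned_tree.taxon_namespace
            if normalize_species_id(t.label) in set(common)]
    pruned_tree.retain_taxa(keep)
    pruned_tree.purge_taxon_namespace()
    return pruned_ds, pruned_tree


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: scale off-diagonal (shared) covariance, keep the diagonal.

    lambda = 1 is pure Brownian structure; lambda = 0 removes all shared
    history (a star phylogeny with the original tip depths).
    """
    if not (0.0 <= lam <= 1.0 + 1e-12):
        raise ValueError(f"lambda={lam} outside [0, 1]")
    C = np.asarray(C, float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def covariance_for_species(
    tree: dendropy.Tree, species: list[str]
) -> PhyloCovariance:
    """Covariance over a species subset, labels in the requested order.

    Species ids are matched to tip labels after normalization; the returned
    covariance uses the caller's (dataset-side) ids.
    """
    cov = phylo_covariance(tree)
    tree_norm = {normalize_species_id(l): i for i, l in enumerate(cov.labels)}
    idx = []
    for s in species:
        key = normalize_species_id(s)
        if key not in tree_norm:
            raise ValidationError(f"species {s!r} not among tree tips")
        idx.append(tree_norm[key])
    return PhyloCovariance(
        labels=list(species), C=cov.C[np.ix_(idx, idx)]
    )
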
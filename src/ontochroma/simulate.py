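"""Synthetic ground truth: trees, two-stage color data, body sizes, backgrounds.

The generator emulates the statistical structure the comparative analysis
assumes so every statistic can be validated against known parameters:

* a pure-birth (Yule) tree, plus a posterior-like sample made by jittering
  its branch lengths with lognormal noise;
* latent 6-D colors evolving by Brownian motion on the tree, with Pagel's
  lambda degrading the phylogenetic signal per stage (``lambda_cat``,
  ``lambda_adult``) and ``rho_stage`` coupling the adult latent trait to the
  larval one (rho = 1: fully coupled stages; rho = 0: independent evolution);
* latents mapped affinely to RGB (per-stage spread controls how much color
  space a stage occupies) and packaged as 1-2 primary patches per species,
  optionally with secondary patches;
* body sizes built so that larval internal contrast predicts larval size
  with a known slope, and adult size tracks larval size;
* green and brown background palettes.

Everything is driven by one seed; identical configs give identical bundles.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from dendropy.model import birthdeath

from .datamodel import ColorPatch, ColorPattern, StageDataset
from .distances import internal_contrast
from .phylo import lambda_transform, phylo_covariance

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "simulate_tree",
    "jitter_posterior",
    "simulate_bm_traits",
    "simulate_stage_colors",
    "simulate_body_size",
    "make_backgrounds",
    "make_bundle",
]

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Generating parameters; defaults mirror the emulated study's conditions.

    98 species (the number with phylogenetic information in the emulated
    dataset), a posterior-like sample of trees, decoupled stages
    (``rho_stage = 0``) with adult signal degraded relative to larval
    (``lambda_adult < lambda_cat``) and adults occupying three times the
    larval color spread — the qualitative regime the analysis is designed to
    detect.
    """

    n_species: int = 98
    birth_rate: float = 1.0
    n_trees: int = 2500
    jitter_sd: float = 0.1
    sigma2: float = 1.0
    rho_stage: float = 0.0
    lambda_cat: float = 1.0
    lambda_adult: float = 0.3
    #: probability that a species has two primary colors (vs. one)
    p_two_primary: float = 0.7
    #: probabilities of 0, 1, 2 extra secondary patches (categories 3/4)
    secondary_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    #: RGB spread (sd around 127.5) per stage; adult = 3x larval spread
    rgb_sd_cat: float = 20.0
    rgb_sd_adult: float = 60.0
    contrast_slope: float = 0.5
    size_bm_sigma: float = 0.3
    noise_sd: float = 0.1
    seed: int = 1

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho_stage <= 1.0):
            raise ValueError("rho_stage must lie in [-1, 1]")
        for name in ("lambda_cat", "lambda_adult"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if abs(sum(self.secondary_probs) - 1.0) > 1e-9:
            raise ValueError("secondary_probs must sum to 1")


@dataclass
class SyntheticBundle:
    trees: list[dendropy.Tree]
    caterpillars: StageDataset
    adults: StageDataset
    body_size_larval: dict[str, float]
    body_size_adult: dict[str, float]
    greens: np.ndarray
    browns: np.ndarray
    config: SyntheticConfig
    latent_cat: np.ndarray = field(repr=False, default=None)
    latent_adult: np.ndarray = field(repr=False, default=None)

    @property
    def species(self) -> list[str]:
        return self.caterpillars.species


def simulate_tree(n: int, birth_rate: float = 1.0, seed: int | None = None) -> dendropy.Tree:
    """Pure-birth tree with ``n`` extant tips, labels sp0001, sp0002, ..."""
    if n < 3:
        raise ValueError(f"need at least 3 tips, got {n}")
    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n,
        rng=rng,
    )
    tree.is_rooted = True
    # The simulator stops exactly at the nth birth, leaving two zero-length
    # terminals; run the clock forward by the waiting time to the next
    # speciation (Exp with rate n * birth_rate) so the tree stays ultrametric
    # and the covariance matrix is nonsingular.
    extra = rng.expovariate(n * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += extra
    taxa = dendropy.TaxonNamespace()
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)):
        leaf.taxon = taxa.new_taxon(label=f"sp{i + 1:04d}")
    tree.taxon_namespace = taxa
    # Drop the stem edge so root-to-tip depths start at the crown.
    tree.seed_node.edge.length = None
    return tree


def jitter_posterior(
    tree: dendropy.Tree, n_trees: int, sd: float, seed: int | None = None
) -> list[dendropy.Tree]:
    """Posterior-like sample: same topology, branch lengths x lognormal(0, sd)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        t = tree.clone(depth=1)
        if sd > 0:
            for edge in t.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = float(edge.length * rng.lognormal(0.0, sd))
        out.append(t)
    return out


def _chol_with_ridge(C: np.ndarray) -> np.ndarray:
    n = C.shape[0]
    scale = float(np.mean(np.diag(C)))
    for eps in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(C + eps * scale * np.eye(n))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance not factorizable")


def simulate_bm_traits(
    C: np.ndarray, p: int, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """p independent Brownian traits with tip covariance sigma2 * C."""
    L = _chol_with_ridge(np.asarray(C, float) * sigma2)
    return L @ rng.standard_normal((C.shape[0], p))


def _latent_to_rgb(latent: np.ndarray, sd: float, rng=None) -> np.ndarray:
    """Standardize per column, rescale to mean 127.5 / given sd, clamp, round.

    Clamping is logged when it touches more than 1% of values; heavy
    clamping flattens the Brownian structure at the gamut boundary.
    """
    z = (latent - latent.mean(axis=0)) / latent.std(axis=0)
    rgb = 127.5 + sd * z
    clamped = ((rgb < 0) | (rgb > 255)).mean()
    if clamped > 0.01:
        logger.info("RGB clamping touched %.1f%% of values (sd=%.0f)", 100 * clamped, sd)
    return np.clip(np.round(rgb), 0, 255).astype(int)


def simulate_stage_colors(
    tree: dendropy.Tree, cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[StageDataset, StageDataset, np.ndarray, np.ndarray]:
    """Two coupled stage datasets from Brownian latents on the tree.

    Returns (caterpillar dataset, adult dataset, larval latents, adult
    latents).  The adult latent is ``rho * larval + sqrt(1 - rho^2) *
    independent replicate``, each stage simulated on its own
    lambda-transformed covariance.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cov = phylo_covariance(tree)
    species = cov.labels
    n = len(species)
    C_cat = lambda_transform(cov.C, cfg.lambda_cat)
    C_adult = lambda_transform(cov.C, cfg.lambda_adult)
    z_cat = simulate_bm_traits(C_cat, 6, cfg.sigma2, rng)
    z_ind = simulate_bm_traits(C_adult, 6, cfg.sigma2, rng)
    rho = cfg.rho_stage
    z_adult = rho * z_cat + np.sqrt(1.0 - rho**2) * z_ind

    rgb_cat = _latent_to_rgb(z_cat, cfg.rgb_sd_cat)
    rgb_adult = _latent_to_rgb(z_adult, cfg.rgb_sd_adult)

    def build(stage: str, rgb: np.ndarray, sex: str, side: str) -> StageDataset:
        # Patch counts are drawn independently per stage: sharing them would
        # couple the stages' internal contrasts even at rho = 0 and break the
        # generator's own decoupling ground truth.
        two_primary = rng.random(n) < cfg.p_two_primary
        n_secondary = rng.choice(3, size=n, p=list(cfg.secondary_probs))
        label = stage if stage == "caterpillar" else f"{stage}-{sex}-{side}"
        ds = StageDataset(label=label)
        for i, sp in enumerate(species):
            patches = []
            if two_primary[i]:
                patches.append(ColorPatch(*map(int, rgb[i, 0:3]), area_category=2))
                patches.append(ColorPatch(*map(int, rgb[i, 3:6]), area_category=2))
            else:
                patches.append(ColorPatch(*map(int, rgb[i, 0:3]), area_category=1))
            for _ in range(min(n_secondary[i], 4 - len(patches))):
                sec = rng.integers(0, 256, size=3)
                patches.append(
                    ColorPatch(int(sec[0]), int(sec[1]), int(sec[2]),
                               area_category=int(rng.choice([3, 4])))
                )
            ds.add(ColorPattern(
                species_id=sp, stage=stage, sex=sex, side=side,
                patches=tuple(patches),
            ))
        return ds

    cats = build("caterpillar", rgb_cat, "unspecified", "unspecified")
    adults = build("adult", rgb_adult, "male", "upperside")
    return cats, adults, z_cat, z_adult


def simulate_body_size(
    tree: dendropy.Tree,
    cfg: SyntheticConfig,
    larval_contrasts: dict[str, float],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Log body sizes: Brownian baseline + contrast effect + noise.

    log larval size = BM(sigma = size_bm_sigma) + contrast_slope * z(contrast)
    + N(0, noise_sd); adult size adds independent N(0, noise_sd) to the
    larval value, so the two are tightly correlated at small noise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    cov = phylo_covariance(tree)
    species = cov.labels
    contrasts = np.array([larval_contrasts[s] for s in species], float)
    sd = contrasts.std()
    z = (contrasts - contrasts.mean()) / (sd if sd > 0 else 1.0)
    bm = simulate_bm_traits(cov.C, 1, cfg.size_bm_sigma**2, rng).ravel()
    larval = bm + cfg.contrast_slope * z + rng.normal(0.0, cfg.noise_sd, len(species))
    adult = larval + rng.normal(0.0, cfg.noise_sd, len(species))
    return dict(zip(species, larval)), dict(zip(species, adult))


#: Channel ranges the background samples are drawn from (uniform per channel).
GREEN_RANGES = ((60, 120), (120, 200), (40, 100))
BROWN_RANGES = ((90, 160), (60, 110), (30, 80))


def make_backgrounds(seed: int | None = None, n_each: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Seeded green and brown background palettes, 10 samples each."""
    rng = np.random.default_rng(seed)

    def draw(ranges):
        return np.column_stack(
            [rng.integers(lo, hi + 1, size=n_each) for lo, hi in ranges]
        ).astype(float)

    return draw(GREEN_RANGES), draw(BROWN_RANGES)


def make_bundle(cfg: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate a complete, internally consistent synthetic study."""
    cfg = cfg or SyntheticConfig()
    tree = simulate_tree(cfg.n_species, cfg.birth_rate, seed=cfg.seed)
    trees = jitter_posterior(tree, cfg.n_trees, cfg.jitter_sd, seed=cfg.seed + 10)
    rng = np.random.default_rng(cfg.seed + 20)
    cats, adults, z_cat, z_adult = simulate_stage_colors(tree, cfg, rng)
    contrasts = {s: internal_contrast(cats[s]) for s in cats.species}
    larval_size, adult_size = simulate_body_size(
        tree, cfg, contrasts, np.random.default_rng(cfg.seed + 30)
    )
    greens, browns = make_backgrounds(seed=cfg.seed + 40)
    return SyntheticBundle(
        trees=trees,
        caterpillars=cats,
        adults=adults,
        body_size_larval=larval_size,
        body_size_adult=adult_size,
        greens=greens,
        browns=browns,
        config=cfg,
        latent_cat=z_cat,
        latent_adult=z_adult,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write a bundle in the standard interchange formats plus a JSON sidecar."""
    from . import io as oio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    oio.write_color_table(
        [bundle.caterpillars[s] for s in bundle.species], out / "caterpillars.csv"
    )
    oio.write_color_table(
        [bundle.adults[s] for s in bundle.species], out / "adults.csv"
    )
    oio.write_trees(bundle.trees, out / "trees.nwk")
    oio.write_backgrounds(bundle.greens, bundle.browns, out / "backgrounds.json")
    import pandas as pd

    pd.DataFrame(
        {
            "species": bundle.species,
            "log_size_larval": [bundle.body_size_larval[s] for s in bundle.species],
            "log_size_adult": [bundle.body_size_adult[s] for s in bundle.species],
        }
    ).to_csv(out / "body_sizes.csv", index=False)
    with open(out / "true_parameters.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(bundle.config), fh, indent=1)
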
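import dendropy
import numpy as np
import pytest

from ontochroma import ColorPatch, ColorPattern, StageDataset


def make_pattern(species, stage="caterpillar", colors=((100, 150, 60),),
                 categories=None, sex="unspecified", side="unspecified"):
    """Build a ColorPattern from RGB triples; first 1-2 colors are primary."""
    if categories is None:
        categories = [1] if len(colors) == 1 else [2, 2] + [3] * (len(colors) - 2)
    patches = tuple(
        ColorPatch(r, g, b, area_category=c)
        for (r, g, b), c in zip(colors, categories)
    )
    return ColorPattern(species_id=species, stage=stage, sex=sex, side=side,
                        patches=patches)


def make_dataset(colors_by_species, stage="caterpillar", label=None, **kw):
    ds = StageDataset(label=label or stage)
    for sp, colors in colors_by_species.items():
        ds.add(make_pattern(sp, stage=stage, colors=colors, **kw))
    return ds


def random_dataset(rng, n_species, stage="caterpillar", label=None, spread=255):
    """iid random patterns (no phylogenetic structure), 2 primaries each."""
    ds = StageDataset(label=label or stage)
    for i in range(n_species):
        colors = [tuple(int(v) for v in rng.integers(0, spread, 3)) for _ in range(2)]
        ds.add(make_pattern(f"sp{i:03d}", stage=stage, colors=colors))
    return ds


def newick_tree(text):
    return dendropy.Tree.get(data=text, schema="newick", rooting="default-rooted")


@pytest.fixture
def three_taxon_tree():
    return newick_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def six_taxon_tree():
    return newick_tree("((A:1.0,B:1.0):0.5,((C:0.6,D:0.6):0.5,(E:0.3,F:0.3):0.8):0.4);")


@pytest.fixture(scope="session")
def bm_tree64():
    from ontochroma import simulate_tree

    return simulate_tree(64, birth_rate=1.0, seed=2024)


@pytest.fixture(scope="session")
def bm_cov64(bm_tree64):
    from ontochroma import phylo_covariance

    return phylo_covariance(bm_tree64)
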
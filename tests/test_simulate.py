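"""Synthetic generator: trees, posterior jitter, stage colors, sizes, backgrounds."""

import dataclasses

import numpy as np
import pytest

import ontochroma as oc
from ontochroma import SyntheticConfig
from ontochroma.simulate import make_bundle, write_bundle


def small_cfg(**kw):
    base = dict(n_species=24, n_trees=5, seed=3)
    base.update(kw)
    return SyntheticConfig(**base)


class TestSimulateTree:
    def test_tip_count_and_labels(self):
        t = oc.simulate_tree(12, seed=0)
        leaves = list(t.leaf_node_iter())
        assert len(leaves) == 12
        assert sorted(l.taxon.label for l in leaves)[0] == "sp0001"

    def test_three_tips_two_internal_nodes(self):
        t = oc.simulate_tree(3, seed=1)
        internal = [n for n in t.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 2

    def test_same_seed_identical_newick(self):
        s1 = oc.simulate_tree(10, seed=5).as_string(schema="newick")
        s2 = oc.simulate_tree(10, seed=5).as_string(schema="newick")
        assert s1 == s2

    def test_ultrametric_and_nonsingular(self):
        for seed in range(10):
            cov = oc.phylo_covariance(oc.simulate_tree(16, seed=seed))
            depths = np.diag(cov.C)
            assert np.allclose(depths, depths[0], rtol=1e-9)
            assert np.linalg.eigvalsh(cov.C).min() > 1e-12

    def test_depth_grows_with_n(self):
        # Yule expectation: mean root-to-tip depth increases with tip count
        def mean_depth(n, seeds):
            out = []
            for s in seeds:
                cov = oc.phylo_covariance(oc.simulate_tree(n, seed=s))
                out.append(np.diag(cov.C).mean())
            return np.mean(out)

        assert mean_depth(40, range(100)) > mean_depth(8, range(100))

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            oc.simulate_tree(2, seed=0)


class TestJitterPosterior:
    def test_sd_zero_identical(self):
        t = oc.simulate_tree(8, seed=0)
        trees = oc.jitter_posterior(t, 3, 0.0, seed=1)
        base = t.as_string(schema="newick")
        assert all(x.as_string(schema="newick") == base for x in trees)

    def test_count(self):
        t = oc.simulate_tree(6, seed=0)
        assert len(oc.jitter_posterior(t, 25, 0.1, seed=1)) == 25

    def test_lognormal_moment(self):
        t = oc.simulate_tree(8, seed=0)
        sd = 0.3
        base = [e.length for e in t.preorder_edge_iter() if e.length]
        trees = oc.jitter_posterior(t, 400, sd, seed=2)
        ratios = []
        for jt in trees:
            jit = [e.length for e in jt.preorder_edge_iter() if e.length]
            ratios.extend(np.array(jit) / np.array(base))
        assert np.mean(ratios) == pytest.approx(np.exp(sd**2 / 2), rel=0.02)


class TestStageColors:
    def test_coupled_stages_high_mantel_r(self):
        cfg = small_cfg(n_species=50, rho_stage=1.0, lambda_adult=1.0,
                        rgb_sd_adult=20.0, secondary_probs=(1.0, 0.0, 0.0))
        tree = oc.simulate_tree(50, seed=7)
        cats, adults, _, _ = oc.simulate_stage_colors(tree, cfg,
                                                      np.random.default_rng(7))
        dm_c = oc.pairwise_matrix(cats, "A")
        dm_a = oc.pairwise_matrix(adults, "A")
        res = oc.mantel(dm_c, dm_a, n_perm=99, seed=0)
        assert res.r >= 0.8

    def test_decoupled_stages_type_i_rate(self):
        # A clean decoupled null needs lambda_adult = 0: with residual tree
        # signal in both stages the two distance matrices correlate through
        # shared ancestry even when the traits are independent, and the
        # Mantel test is mildly anticonservative.
        rejections = 0
        n_rep = 50
        for seed in range(n_rep):
            cfg = small_cfg(rho_stage=0.0, lambda_adult=0.0, seed=seed)
            tree = oc.simulate_tree(24, seed=seed)
            cats, adults, _, _ = oc.simulate_stage_colors(
                tree, cfg, np.random.default_rng(seed)
            )
            res = oc.mantel(oc.pairwise_matrix(cats, "A"),
                            oc.pairwise_matrix(adults, "A"),
                            n_perm=199, seed=seed)
            rejections += res.p_value <= 0.05
        # decoupled stages are a Mantel null; rejections should be rare
        assert rejections / n_rep <= 0.15

    def test_signal_contrast_between_stages(self):
        wins = 0
        for seed in range(25):
            cfg = small_cfg(n_species=48, lambda_cat=1.0, lambda_adult=0.0, seed=seed)
            tree = oc.simulate_tree(48, seed=seed + 100)
            cats, adults, _, _ = oc.simulate_stage_colors(
                tree, cfg, np.random.default_rng(seed)
            )
            cov = oc.phylo_covariance(tree)
            kc = oc.kmult(cats.vector_matrix(cov.labels), cov)
            ka = oc.kmult(adults.vector_matrix(cov.labels), cov)
            wins += kc > ka
        assert wins >= 24

    def test_patterns_pass_validators(self):
        cfg = small_cfg()
        tree = oc.simulate_tree(cfg.n_species, seed=cfg.seed)
        cats, adults, _, _ = oc.simulate_stage_colors(tree, cfg,
                                                      np.random.default_rng(0))
        assert len(cats) == len(adults) == cfg.n_species
        for ds in (cats, adults):
            for sp in ds.species:
                assert 1 <= len(ds[sp].patches) <= 4
                assert any(p.is_primary for p in ds[sp].patches)


class TestBodySize:
    def test_slope_recovery(self):
        ests = []
        for seed in range(30):
            cfg = small_cfg(n_species=48, contrast_slope=0.5, seed=seed)
            tree = oc.simulate_tree(48, seed=seed)
            cats, _, _, _ = oc.simulate_stage_colors(tree, cfg,
                                                     np.random.default_rng(seed))
            contrasts = {s: oc.internal_contrast(cats[s]) for s in cats.species}
            larval, _ = oc.simulate_body_size(tree, cfg, contrasts,
                                              np.random.default_rng(seed + 1))
            cov = oc.phylo_covariance(tree)
            z = np.array([contrasts[s] for s in cov.labels])
            z = (z - z.mean()) / z.std()
            y = np.array([larval[s] for s in cov.labels])
            ests.append(oc.pgls_fit(y, z, cov).beta[1])
        assert np.mean(ests) == pytest.approx(0.5, abs=0.05)

    def test_null_slope_centered_on_zero(self):
        ests = []
        for seed in range(30):
            cfg = small_cfg(n_species=32, contrast_slope=0.0, seed=seed)
            tree = oc.simulate_tree(32, seed=seed)
            cats, _, _, _ = oc.simulate_stage_colors(tree, cfg,
                                                     np.random.default_rng(seed))
            contrasts = {s: oc.internal_contrast(cats[s]) for s in cats.species}
            larval, _ = oc.simulate_body_size(tree, cfg, contrasts,
                                              np.random.default_rng(seed + 1))
            cov = oc.phylo_covariance(tree)
            z = np.array([contrasts[s] for s in cov.labels])
            z = (z - z.mean()) / (z.std() or 1.0)
            y = np.array([larval[s] for s in cov.labels])
            ests.append(oc.pgls_fit(y, z, cov).beta[1])
        assert abs(np.mean(ests)) < 0.05

    def test_adult_size_tracks_larval(self):
        cfg = small_cfg(n_species=60, noise_sd=0.05)
        tree = oc.simulate_tree(60, seed=9)
        cats, _, _, _ = oc.simulate_stage_colors(tree, cfg, np.random.default_rng(9))
        contrasts = {s: oc.internal_contrast(cats[s]) for s in cats.species}
        larval, adult = oc.simulate_body_size(tree, cfg, contrasts,
                                              np.random.default_rng(10))
        l = np.array([larval[s] for s in sorted(larval)])
        a = np.array([adult[s] for s in sorted(adult)])
        assert np.corrcoef(l, a)[0, 1] > 0.9


class TestBackgrounds:
    def test_counts_and_bounds(self):
        greens, browns = oc.make_backgrounds(seed=0)
        assert greens.shape == (10, 3) and browns.shape == (10, 3)
        for arr in (greens, browns):
            assert arr.min() >= 0 and arr.max() <= 255

    def test_greens_greener_than_browns(self):
        greens, browns = oc.make_backgrounds(seed=1)
        assert greens[:, 1].mean() > browns[:, 1].mean()

    def test_same_seed_identical(self):
        assert np.array_equal(oc.make_backgrounds(seed=2)[0],
                              oc.make_backgrounds(seed=2)[0])


class TestBundle:
    def test_full_bundle_deterministic_on_disk(self, tmp_path):
        cfg = small_cfg()
        for d in ("one", "two"):
            write_bundle(make_bundle(dataclasses.replace(cfg)), tmp_path / d)
        for name in ("caterpillars.csv", "adults.csv", "trees.nwk",
                     "backgrounds.json", "body_sizes.csv", "true_parameters.json"):
            assert (tmp_path / "one" / name).read_bytes() == \
                   (tmp_path / "two" / name).read_bytes()

    def test_bundle_species_consistent(self):
        b = make_bundle(small_cfg())
        assert b.caterpillars.species == b.adults.species
        assert set(b.body_size_larval) == set(b.species)
        tips = sorted(l.taxon.label for l in b.trees[0].leaf_node_iter())
        assert tips == b.species

    def test_written_tables_pass_validators(self, tmp_path):
        write_bundle(make_bundle(small_cfg()), tmp_path)
        cats = oc.read_color_table(tmp_path / "caterpillars.csv")
        adults = oc.read_color_table(tmp_path / "adults.csv")
        trees = oc.read_trees(tmp_path / "trees.nwk")
        assert len(cats) == len(adults) == 24
        assert len(trees) == 5
        oc.read_backgrounds(tmp_path / "backgrounds.json")
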
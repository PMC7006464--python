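"""Mantel test, color diversity D, D_dif permutation test, PCA view."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform

import ontochroma as oc
from ontochroma import DistanceMatrix, ValidationError
from ontochroma.decoupling import ddif_test, diversity_D, mantel, pca_colorspace

from conftest import make_dataset, random_dataset


def dm(labels, condensed):
    return DistanceMatrix(list(labels), squareform(np.asarray(condensed, float)))


class TestMantel:
    def test_self_correlation_is_one(self):
        d = dm("ABCDE", [1.0, 2, 3, 1.5, 2.5, 0.5, 3.5, 1.2, 2.2, 0.8])
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        d1 = dm("ABC", [1.0, 2.0, 3.0])
        d2 = dm("ABC", [3.0, 2.0, 1.0])
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(-1.0)

    def test_matches_vegan_statistic(self):
        # frozen from vegan::mantel on the same matrices
        d1 = dm("ABCDE", [1.0, 2, 3, 1.5, 2.5, 0.5, 3.5, 1.2, 2.2, 0.8])
        d2 = dm("ABCDE", [2.0, 1, 2.5, 1.8, 3.0, 0.9, 2.8, 1.1, 1.9, 1.4])
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(
            0.761456681612, abs=1e-9
        )

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(0)
        v1, v2 = rng.uniform(1, 10, 15), rng.uniform(1, 10, 15)
        d1, d2 = dm("ABCDEF", v1), dm("ABCDEF", v2)
        want, _, _ = sk_mantel(
            SkDM(d1.values, list("ABCDEF")), SkDM(d2.values, list("ABCDEF")),
            permutations=0,
        )
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(want, abs=1e-9)

    def test_label_alignment_by_reordering(self):
        d1 = dm("ABCD", [1.0, 2, 3, 4, 5, 6])
        # same matrix with rows renamed in a different order
        perm = [2, 0, 3, 1]
        labels2 = ["ABCD"[i] for i in perm]
        d2 = DistanceMatrix(labels2, d1.values[np.ix_(perm, perm)])
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mantel(dm("ABC", [1.0, 2, 3]), dm("ABD", [1.0, 2, 3]), n_perm=99)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            mantel(dm("ABC", [1.0, 1, 1]), dm("ABC", [1.0, 2, 3]), n_perm=99)

    def test_same_seed_same_p(self):
        rng = np.random.default_rng(1)
        d1 = dm("ABCDEFG", rng.uniform(1, 5, 21))
        d2 = dm("ABCDEFG", rng.uniform(1, 5, 21))
        p1 = mantel(d1, d2, n_perm=499, seed=9).p_value
        p2 = mantel(d1, d2, n_perm=499, seed=9).p_value
        assert p1 == p2

    def test_p_uniform_under_null(self):
        # P is uniform on (0,1] for independent random matrices (KS check)
        from scipy.stats import kstest

        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(500):
            d1 = dm("ABCDEFGHIJKL", rng.uniform(1, 10, 66))
            d2 = dm("ABCDEFGHIJKL", rng.uniform(1, 10, 66))
            pvals.append(
                mantel(d1, d2, n_perm=199,
                       seed=int(rng.integers(2**31))).p_value
            )
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestDiversityD:
    def test_two_species_single_distance(self):
        ds = make_dataset({"A": [(0, 0, 0)], "B": [(255, 0, 0)]})
        assert diversity_D(ds, "A") == pytest.approx(np.sqrt(2) * 255)

    def test_three_species_direct_mean(self):
        ds = make_dataset({"A": [(0, 0, 0)], "B": [(0, 0, 100)], "C": [(0, 0, 30)]})
        # pairwise metric-A distances: AB, AC, BC over duplicated channels
        want = np.mean([np.sqrt(2) * 100, np.sqrt(2) * 30, np.sqrt(2) * 70])
        assert diversity_D(ds, "A") == pytest.approx(want)

    def test_identical_patterns_zero(self):
        ds = make_dataset({s: [(5, 5, 5)] for s in "ABCD"})
        assert diversity_D(ds, "A") == 0.0

    def test_grouped_by_family(self):
        ds = make_dataset({"A": [(0, 0, 0)], "B": [(0, 0, 100)],
                           "C": [(200, 0, 0)], "D": [(200, 0, 80)], "E": [(9, 9, 9)]})
        fam = {"A": "f1", "B": "f1", "C": "f2", "D": "f2", "E": "f3"}
        out = diversity_D(ds, "A", group_by=fam)
        assert out["f1"] == pytest.approx(np.sqrt(2) * 100)
        assert out["f2"] == pytest.approx(np.sqrt(2) * 80)
        assert "f3" not in out  # singleton group skipped
        assert "overall" in out

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, 8)
        renamed = oc.StageDataset(label=ds.label)
        for i, s in enumerate(ds.species):
            p = ds[s]
            import dataclasses

            renamed.add(dataclasses.replace(p, species_id=f"zz{i}"))
        assert diversity_D(ds, "A") == pytest.approx(diversity_D(renamed, "A"))


class TestDdif:
    def test_equal_stages_null_behaviour(self):
        rng = np.random.default_rng(4)
        cats = random_dataset(rng, 12, stage="caterpillar")
        adults = oc.StageDataset(label="adult")
        import dataclasses

        for s in cats.species:
            adults.add(dataclasses.replace(cats[s], stage="adult"))
        res = ddif_test(cats, adults, metric="A", n_perm=199, seed=0)
        assert res.d_dif == pytest.approx(0.0)
        assert res.p_lower > 0.4 and res.p_upper > 0.4

    def test_d_dif_is_exact_difference(self):
        rng = np.random.default_rng(5)
        cats = random_dataset(rng, 10, stage="caterpillar")
        adults = random_dataset(rng, 10, stage="adult", label="adult")
        res = ddif_test(cats, adults, metric="A", n_perm=99, seed=0)
        assert res.d_dif == pytest.approx(res.d_caterpillar - res.d_adult)
        assert res.d_caterpillar == pytest.approx(diversity_D(cats, "A"))

    def test_more_diverse_adults_detected(self):
        # adults spread 3x wider than caterpillars -> significantly negative D_dif
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cats = random_dataset(rng, 20, stage="caterpillar", spread=80)
            adults = random_dataset(rng, 20, stage="adult", label="adult", spread=255)
            adults = oc.StageDataset(
                "adult",
                {c: __import__("dataclasses").replace(adults[a], species_id=c)
                 for c, a in zip(cats.species, adults.species)},
            )
            res = ddif_test(cats, adults, metric="A", n_perm=199, seed=seed)
            hits += res.p_lower <= 0.05
        assert hits >= 18

    def test_p_lower_plus_p_upper_at_least_one(self):
        rng = np.random.default_rng(6)
        cats = random_dataset(rng, 8, stage="caterpillar")
        adults = random_dataset(rng, 8, stage="adult", label="adult")
        res = ddif_test(cats, adults, metric="A", n_perm=199, seed=1)
        assert res.p_lower + res.p_upper >= 1.0

    def test_species_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        cats = random_dataset(rng, 5, stage="caterpillar")
        adults = random_dataset(rng, 6, stage="adult", label="adult")
        with pytest.raises(ValidationError):
            ddif_test(cats, adults)

    @pytest.mark.parametrize("scheme", ["within_species_swap", "free_relabel"])
    def test_deterministic_given_seed(self, scheme):
        rng = np.random.default_rng(8)
        cats = random_dataset(rng, 8, stage="caterpillar")
        adults = random_dataset(rng, 8, stage="adult", label="adult")
        adults = oc.StageDataset(
            "adult",
            {c: __import__("dataclasses").replace(adults[a], species_id=c)
             for c, a in zip(cats.species, adults.species)},
        )
        r1 = ddif_test(cats, adults, scheme=scheme, n_perm=99, seed=3)
        r2 = ddif_test(cats, adults, scheme=scheme, n_perm=99, seed=3)
        assert (r1.p_lower, r1.p_upper) == (r2.p_lower, r2.p_upper)


class TestPcaColorspace:
    def test_single_axis_variance(self):
        ds = make_dataset({f"s{i}": [(int(i * 25), 50, 50)] for i in range(10)})
        df = pca_colorspace([ds])
        assert df.attrs["explained_variance_ratio"][0] == pytest.approx(1.0)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(9)
        ds = random_dataset(rng, 10)
        df1 = pca_colorspace([ds])
        shuffled = oc.StageDataset(ds.label, dict(reversed(list(ds.patterns.items()))))
        df2 = pca_colorspace([shuffled])
        m1 = df1.set_index("species")[["pc1", "pc2"]]
        m2 = df2.set_index("species")[["pc1", "pc2"]]
        assert np.allclose(m1.loc[m1.index], m2.loc[m1.index], atol=1e-9)

    def test_two_clusters_separate_on_pc1(self):
        dark = {f"d{i}": [(i, i, i)] for i in range(5)}
        bright = {f"b{i}": [(250 - i, 250 - i, 250 - i)] for i in range(5)}
        df = pca_colorspace([make_dataset({**dark, **bright})])
        signs = df.assign(dark=df.species.str.startswith("d")).groupby("dark").pc1.mean()
        assert np.sign(signs[True]) != np.sign(signs[False])

    def test_degenerate_input_rejected(self):
        ds = make_dataset({s: [(5, 5, 5)] for s in "ABC"})
        with pytest.raises(ValidationError):
            pca_colorspace([ds])
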
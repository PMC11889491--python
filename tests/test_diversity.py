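"""Diversity statistics against closed forms, scipy and scikit-bio oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import mannwhitneyu

from sexome.cohort import AsvCountTable
from sexome.diversity import (
    DistanceMatrix,
    alpha_table,
    bray_curtis,
    bray_curtis_matrix,
    exhaustive_permanova_p,
    pcoa,
    permanova,
    rank_sum_test,
    shannon_index,
)
from sexome.errors import EmptySampleError
from tests.conftest import make_cohort


class TestShannon:
    def test_single_taxon_zero(self):
        assert shannon_index([10, 0, 0]) == 0.0

    def test_uniform_closed_form(self):
        assert shannon_index([1, 1, 1, 1]) == pytest.approx(np.log(4), abs=1e-12)

    def test_direct_summation_oracle(self):
        counts = [5, 3, 2]
        expected = -sum(c / 10 * np.log(c / 10) for c in counts)
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(EmptySampleError):
            shannon_index([0, 0])


class TestRankSum:
    def test_identical_multisets_p_one(self):
        assert rank_sum_test([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_most_extreme_small_case(self):
        # most extreme of the C(4,2)=6 equally likely orderings, two-sided
        assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(3, 10))
        b = rng.normal(loc=rng.normal(), size=rng.integers(3, 10))
        expected = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert rank_sum_test(a, b) == pytest.approx(float(expected), rel=1e-10)

    def test_tied_large_groups_match_permutation_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 6, size=12).astype(float)
        b = (rng.integers(0, 6, size=12) + 1).astype(float)
        p = rank_sum_test(a, b)
        # sampled-permutation oracle on the rank-sum statistic
        pooled = np.concatenate([a, b])
        ranks = pd.Series(pooled).rank().to_numpy()
        w_obs = ranks[:12].sum()
        reps = 40000
        stat = np.empty(reps)
        for i in range(reps):
            stat[i] = ranks[rng.permutation(24)[:12]].sum()
        # mid-p tails: the continuous normal approximation splits the
        # probability atom at the observed statistic
        atom = np.mean(np.abs(stat - w_obs) < 1e-9)
        lower = np.mean(stat < w_obs - 1e-9) + atom / 2
        upper = np.mean(stat > w_obs + 1e-9) + atom / 2
        p_mc = min(1.0, 2.0 * min(lower, upper))
        assert p == pytest.approx(p_mc, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestBrayCurtis:
    def test_identity_disjoint_and_formula(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0], [0, 2]) == 1.0
        assert bray_curtis([1, 0, 1], [0, 1, 1]) == pytest.approx(0.5)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            x = rng.integers(0, 50, size=20)
            y = rng.integers(0, 50, size=20)
            x[0] += 1
            y[1] += 1
            assert bray_curtis(x, y) == pytest.approx(
                float(scipy_braycurtis(x, y)), abs=1e-12
            )

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            x = rng.integers(0, 20, size=10)
            y = rng.integers(0, 20, size=10)
            x[0] += 1
            y[0] += 1
            d = bray_curtis(x, y)
            assert d == bray_curtis(y, x)
            assert 0 <= d <= 1
            assert (d == 0) == bool((x == y).all())

    def test_both_zero_rejected(self):
        with pytest.raises(EmptySampleError):
            bray_curtis([0, 0], [0, 0])


class TestPcoa:
    def test_equilateral_degeneracy(self):
        d = DistanceMatrix(("a", "b", "c"), np.array(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float
        ))
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)
        assert abs(res.eigenvalues[2]) < 1e-9

    def test_planted_euclidean_geometry_recovered(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(tuple("abcde"), d))
        emb = res.coordinates[:, :2]
        d_emb = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d_emb, d, atol=1e-8)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(15, 10)),
            index=[f"a{i}" for i in range(15)],
            columns=[f"S{j}" for j in range(10)],
        )
        dm = bray_curtis_matrix(AsvCountTable(counts))
        res = pcoa(dm)
        assert res.proportion_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_skbio(self):
        import skbio

        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(20, 8)) + 1,
            index=[f"a{i}" for i in range(20)],
            columns=[f"S{j}" for j in range(8)],
        )
        dm = bray_curtis_matrix(AsvCountTable(counts))
        res = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, ids=list(dm.sample_ids))
        )
        n_pos = res.coordinates.shape[1]
        np.testing.assert_allclose(
            res.eigenvalues[:n_pos], ref.eigvals.to_numpy()[:n_pos], atol=1e-8
        )
        # embeddings agree up to axis sign
        ref_coords = ref.samples.to_numpy()[:, :n_pos]
        for k in range(n_pos):
            col = res.coordinates[:, k]
            assert min(
                np.abs(col - ref_coords[:, k]).max(),
                np.abs(col + ref_coords[:, k]).max(),
            ) < 1e-6

    def test_asymmetric_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b", "c"), m)


def random_distance_matrix(rng, n):
    counts = pd.DataFrame(
        rng.integers(0, 60, size=(12, n)) + 1,
        index=[f"a{i}" for i in range(12)],
        columns=[f"S{j}" for j in range(n)],
    )
    return bray_curtis_matrix(AsvCountTable(counts))


class TestPermanova:
    def test_no_between_group_signal(self):
        # each group holds the same pair of distinct points
        d = np.zeros((4, 4))
        c = 0.8
        for i, j in [(0, 1), (0, 3), (1, 2), (2, 3)]:
            d[i, j] = d[j, i] = c
        dm = DistanceMatrix(("u1", "v1", "u2", "v2"), d)
        res = permanova(dm, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_skbio_f_statistic(self):
        import skbio
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(12)
        dm = random_distance_matrix(rng, 10)
        labels = ["a"] * 5 + ["b"] * 5
        res = permanova(dm, labels, n_permutations=999, seed=1)
        ref = skbio_permanova(
            skbio.DistanceMatrix(dm.values, ids=list(dm.sample_ids)),
            grouping=labels,
            permutations=999,
        )
        assert res.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-9)
        assert abs(res.p_value - float(ref["p-value"])) < 0.05

    def test_exhaustive_enumeration_matches_independent_oracle(self):
        import skbio
        from itertools import combinations
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(2)
        dm = random_distance_matrix(rng, 6)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        p_exh = exhaustive_permanova_p(dm, labels)

        sk_dm = skbio.DistanceMatrix(dm.values, ids=list(dm.sample_ids))

        def sk_f(lab):
            return float(
                skbio_permanova(sk_dm, grouping=list(lab), permutations=0)[
                    "test statistic"
                ]
            )

        f_obs = sk_f(labels)
        fs = []
        for idx in combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(idx)] = "a"
            fs.append(sk_f(lab))
        p_oracle = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert p_exh == pytest.approx(p_oracle)

    def test_p_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        dm = random_distance_matrix(rng, 8)
        labels = ["a"] * 4 + ["b"] * 4
        p1 = permanova(dm, labels, n_permutations=499, seed=42).p_value
        p2 = permanova(dm, labels, n_permutations=499, seed=42).p_value
        assert p1 == p2

    def test_group_size_validation(self):
        rng = np.random.default_rng(4)
        dm = random_distance_matrix(rng, 5)
        with pytest.raises(ValueError):
            permanova(dm, ["a", "a", "a", "a", "b"], seed=0)

    def test_null_r_squared_near_analytic_expectation(self):
        """With no group effect E[R^2] is about (a-1)/(N-1)."""
        rng = np.random.default_rng(10)
        r2 = []
        for _ in range(60):
            dm = random_distance_matrix(rng, 12)
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            res = permanova(dm, labels, n_permutations=9, seed=0)
            r2.append(res.r_squared)
        assert np.mean(r2) < 2 * (2 - 1) / (12 - 1)


class TestAlphaTable:
    def test_richness_and_single_group(self):
        counts = pd.DataFrame(
            {
                "S1": [3, 1, 0, 2, 1, 1, 4, 0],
                "S2": [1, 0, 0, 0, 2, 0, 0, 0],
                "S3": [2, 2, 2, 0, 0, 0, 0, 0],
                "S4": [5, 0, 1, 0, 0, 0, 0, 0],
            },
            index=[f"a{i}" for i in range(8)],
        )
        records = [
            ("S1", "C1_F", "C1", "female", "before", "specimen"),
            ("S2", "C1_F", "C1", "female", "after", "specimen"),
            ("S3", "C1_M", "C1", "male", "before", "specimen"),
            ("S4", "C1_M", "C1", "male", "after", "specimen"),
        ]
        ds = make_cohort(counts, records)
        alpha, comps = alpha_table(ds, grouping="sex")
        assert alpha.loc["S1", "richness"] == 6
        assert set(comps[["group_a", "group_b"]].itertuples(index=False, name=None)) == {
            ("female", "male")
        }
        # constant grouping emits no comparisons
        alpha2, comps2 = alpha_table(ds, grouping="couple_id")
        assert comps2.empty and len(alpha2) == 4

    def test_unknown_grouping(self, default_cohort):
        ds, _ = default_cohort
        with pytest.raises(KeyError):
            alpha_table(ds, grouping="smoking")
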
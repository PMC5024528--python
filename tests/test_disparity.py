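import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphodtt.disparity import (
    assign_bins,
    bonferroni,
    disparity_curve,
    disparity_size_correlation,
    group_membership_sets,
    npmanova,
    permutation_disparity_test,
    sum_of_variances,
)


@pytest.fixture
def bins():
    return pd.DataFrame(
        {
            "name": ["Anisian", "Ladinian"],
            "older": [247.2, 242.0],
            "younger": [242.0, 237.0],
        }
    )


class TestAssignBins:
    def test_midpoint_inside_bin(self, bins):
        out = assign_bins({"X": 244.5}, bins)
        assert out["X"] == "Anisian"

    def test_older_edge_inclusive_younger_exclusive(self, bins):
        # convention: B.older >= a > B.younger, so a bin boundary age belongs
        # to the younger bin's older edge
        out = assign_bins({"older_edge": 247.2, "boundary": 242.0}, bins)
        assert out["older_edge"] == "Anisian"
        assert out["boundary"] == "Ladinian"

    def test_out_of_range_warns_and_flags(self, bins):
        with pytest.warns(UserWarning, match="old_taxon"):
            out = assign_bins({"old_taxon": 260.0, "ok": 243.0}, bins)
        assert pd.isna(out["old_taxon"])
        assert out["ok"] == "Anisian"


class TestSumOfVariances:
    def test_hand_computed(self):
        scores = np.array([[0.0, 1.0], [2.0, 1.0], [4.0, 1.0]])
        assert sum_of_variances(scores) == pytest.approx(4.0)

    def test_identical_rows_zero(self):
        assert sum_of_variances(np.tile([3.0, -1.0], (4, 1))) == 0.0

    def test_matches_centroid_distance_formula(self, rng):
        X = rng.normal(size=(20, 8))
        direct = np.sum((X - X.mean(axis=0)) ** 2) / (20 - 1)
        assert sum_of_variances(X) == pytest.approx(direct, abs=1e-10)

    def test_invariant_to_orthogonal_rotation(self, rng):
        X = rng.normal(size=(15, 6))
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        assert sum_of_variances(X @ Q) == pytest.approx(
            sum_of_variances(X), abs=1e-10
        )

    def test_subsample_does_not_exceed_pool_in_expectation(self, rng):
        X = rng.normal(size=(60, 4))
        pooled = sum_of_variances(X)
        sub = np.mean(
            [
                sum_of_variances(X[rng.choice(60, 10, replace=False)])
                for _ in range(300)
            ]
        )
        assert sub <= pooled * 1.05  # Monte-Carlo trend, not per-draw


class TestDisparityCurve:
    def test_min_taxa_rule_and_composites(self):
        scores = pd.DataFrame(
            {"PC1": [0.0, 1, 2, 3, 4, 5], "PC2": [1.0, 0, 1, 0, 1, 0]},
            index=list("abcdef"),
        )
        bin_assignment = pd.Series(
            {"a": "B1", "b": "B1", "c": "B1", "d": "B1", "e": "B2", "f": "B2"}
        )
        membership = {
            "a": frozenset({"stem"}),
            "b": frozenset({"stem"}),
            "c": frozenset({"crownA"}),
            "d": frozenset({"crownB"}),
            "e": frozenset({"crownA"}),
            "f": frozenset({"crownA", "crownB"}),  # a crown ancestor
        }
        group_sets = {
            "stem": ("stem",),
            "crown": ("crownA", "crownB"),
            "all": ("stem", "crownA", "crownB"),
        }
        curve = disparity_curve(
            scores, bin_assignment, membership, group_sets, ["B1", "B2"], min_taxa=3
        )
        row = curve.set_index(["group", "bin"])
        assert row.loc[("all", "B1"), "n"] == 4
        assert row.loc[("all", "B1"), "sov"] == pytest.approx(
            sum_of_variances(scores.loc[list("abcd")].to_numpy())
        )
        # crown ancestor 'f' counts for crown but not for stem
        assert row.loc[("crown", "B2"), "n"] == 2
        assert np.isnan(row.loc[("crown", "B2"), "sov"])  # below min_taxa
        assert row.loc[("stem", "B1"), "n"] == 2
        assert np.isnan(row.loc[("stem", "B1"), "sov"])

    def test_three_identical_taxa_zero_sov(self):
        scores = pd.DataFrame(
            np.tile([1.0, 2.0], (3, 1)), index=list("abc"), columns=["PC1", "PC2"]
        )
        curve = disparity_curve(
            scores,
            pd.Series({"a": "B1", "b": "B1", "c": "B1"}),
            {t: frozenset({"g"}) for t in "abc"},
            {"g": ("g",)},
            ["B1"],
        )
        assert curve.loc[0, "n"] == 3
        assert curve.loc[0, "sov"] == 0.0

    def test_unknown_base_group_rejected(self):
        scores = pd.DataFrame({"PC1": [0.0, 1, 2]}, index=list("abc"))
        with pytest.raises(ValueError, match="nope"):
            disparity_curve(
                scores,
                pd.Series({"a": "B1", "b": "B1", "c": "B1"}),
                {t: frozenset({"g"}) for t in "abc"},
                {"bad": ("nope",)},
                ["B1"],
            )


class TestGroupMembership:
    def test_ancestor_carries_union_of_descendant_groups(self):
        import dendropy

        tree = dendropy.Tree.get(
            data="((A,B)ab,(C,D)cd)root;",
            schema="newick",
            suppress_internal_node_taxa=True,
        )
        sets = group_membership_sets(
            {"A": "x", "B": "x", "C": "y", "D": "x"}, tree
        )
        assert sets["ab"] == frozenset({"x"})
        assert sets["cd"] == frozenset({"x", "y"})
        assert sets["root"] == frozenset({"x", "y"})


class TestPermutationDisparityTest:
    def test_no_signal_gives_p_one(self, rng):
        X = rng.normal(size=(4, 3))
        obs, p = permutation_disparity_test(X, X.copy(), n_permutations=200, seed=0)
        assert obs == pytest.approx(0.0)
        assert p == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        A = rng.normal(size=(3, 2)) * 3
        B = rng.normal(size=(3, 2))
        pool = np.vstack([A, B])
        observed = abs(sum_of_variances(A) - sum_of_variances(B))
        count = 0
        splits = list(itertools.combinations(range(6), 3))
        for idx_a in splits:
            idx_b = [i for i in range(6) if i not in idx_a]
            stat = abs(
                sum_of_variances(pool[list(idx_a)]) - sum_of_variances(pool[idx_b])
            )
            if stat >= observed - 1e-12:
                count += 1
        p_exact = count / len(splits)
        nreps = 10_000
        _, p_mc = permutation_disparity_test(A, B, n_permutations=nreps, seed=7)
        se = np.sqrt(p_exact * (1 - p_exact) / nreps) + 1 / nreps
        assert abs(p_mc - p_exact) < 3 * se + 2 / (nreps + 1)

    def test_reproducible_and_in_unit_interval(self, rng):
        A, B = rng.normal(size=(5, 4)), rng.normal(size=(8, 4))
        r1 = permutation_disparity_test(A, B, n_permutations=500, seed=11)
        r2 = permutation_disparity_test(A, B, n_permutations=500, seed=11)
        assert r1 == r2
        assert 0 < r1[1] <= 1

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            permutation_disparity_test(
                rng.normal(size=(2, 3)), rng.normal(size=(5, 3))
            )


class TestNpmanova:
    def test_hand_computed_f(self):
        scores = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
        res = npmanova(scores, ["a", "a", "b", "b"], n_permutations=50, seed=0)
        # SS_T = 101, SS_W = 1, SS_A = 100 -> F = 100 / (1/2) = 200
        assert res.f_statistic == pytest.approx(200.0)
        assert res.group_sizes == {"a": 2, "b": 2}

    def test_identical_points_f_zero(self):
        scores = np.tile([1.0, 2.0], (6, 1))
        res = npmanova(scores, ["a"] * 3 + ["b"] * 3, n_permutations=50, seed=0)
        assert res.f_statistic == 0.0

    def test_matches_scikit_bio_permanova(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        scores = rng.normal(size=(12, 4))
        scores[:4] += 1.5
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        diff = scores[:, None, :] - scores[None, :, :]
        dm = DistanceMatrix(np.sqrt((diff**2).sum(axis=2)), ids=[str(i) for i in range(12)])
        ref = skbio_permanova(dm, labels, permutations=0)
        res = npmanova(scores, labels, n_permutations=10, seed=0)
        assert res.f_statistic == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_reproducible_given_seed(self, rng):
        scores = rng.normal(size=(10, 3))
        labels = ["a"] * 5 + ["b"] * 5
        p1 = npmanova(scores, labels, n_permutations=300, seed=4).p_value
        p2 = npmanova(scores, labels, n_permutations=300, seed=4).p_value
        assert p1 == p2 and 0 < p1 <= 1

    def test_degenerate_groups_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            npmanova(rng.normal(size=(4, 2)), ["a", "a", "a", "b"])


class TestBonferroni:
    def test_scales_and_caps(self):
        np.testing.assert_allclose(
            bonferroni([0.01, 0.4], m=5), [0.05, 1.0]
        )

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(bonferroni([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])


class TestSizeCorrelation:
    def test_monotone_pairs(self):
        rho, _ = disparity_size_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, _ = disparity_size_correlation([5, 4, 3, 2, 1], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(-1.0)

    def test_missing_bins_dropped_pairwise(self):
        rho, _ = disparity_size_correlation(
            [1, np.nan, 3, 4, 5], [10, 20, 30, 40, 50]
        )
        assert rho == pytest.approx(1.0)

    def test_p_matches_exact_enumeration_at_n6(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho_obs, p = disparity_size_correlation(x, y)
        rhos = [
            stats.spearmanr(x, np.asarray(y)[list(perm)]).statistic
            for perm in itertools.permutations(range(6))
        ]
        p_exact = np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)
        assert p == pytest.approx(p_exact, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="4"):
            disparity_size_correlation([1, 2, np.nan, np.nan, 3], [1, 2, 3, 4, 5])
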
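"""BH, filtered BH, and the discrete permutation FDR procedure."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from dsfdr import (
    AbundanceMatrix,
    GroupAssignment,
    ValidationError,
    bh_adjust,
    build_null,
    dsfdr_adjusted_pvalues,
    dsfdr_threshold,
    estimate_fdr_at_cutpoint,
    exhaustive_null,
    fbh_procedure,
    min_achievable_pvalue,
    permutation_pvalues,
)
from dsfdr.stats_core import StatisticProfile
from conftest import random_count_matrix

QGRID = np.round(np.arange(0.05, 1.0, 0.05), 2)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.05], [0.05]),
            ([0.5, 0.04], [0.5, 0.08]),
        ],
    )
    def test_closed_form_toys(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p).values, expected)

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            p = rng.uniform(size=25)
            mine = bh_adjust(p).values
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(mine, theirs)

    def test_rejection_equivalence_with_step_up(self):
        # adjusted <= q iff the classic step-up rejects, via statsmodels
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(0, 0.01, 5), rng.uniform(size=20)])
        for q in (0.05, 0.1, 0.2):
            reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
            np.testing.assert_array_equal(bh_adjust(p).values <= q, reject)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestMinAchievablePvalue:
    def test_all_zero_row(self, groups_5_5):
        assert min_achievable_pvalue(np.zeros(10), groups_5_5) == 1.0

    def test_singleton_presence(self, groups_5_5):
        row = np.zeros(10)
        row[3] = 7.0
        # |T| is the same whichever group holds the one nonzero sample
        assert min_achievable_pvalue(row, groups_5_5) == 1.0

    def test_three_tied_nonzeros(self, groups_5_5):
        row = np.zeros(10)
        row[[1, 4, 7]] = 5.0
        # extreme iff all three land in one group: 2*C(5,3)/C(10,3)
        assert min_achievable_pvalue(row, groups_5_5) == pytest.approx(1 / 6)

    def test_permutation_route_tracks_exact(self, groups_5_5):
        row = np.zeros(10)
        row[[1, 4, 7]] = 5.0
        approx = min_achievable_pvalue(
            row, groups_5_5, enumeration_cap=1, B=4000, seed=0
        )
        assert approx == pytest.approx(1 / 6, abs=0.02)


class TestEstimateFdrAtCutpoint:
    def test_worked_profile(self, worked_profile):
        assert estimate_fdr_at_cutpoint(worked_profile, 10) == pytest.approx(
            (0.2, 1, 0.2)
        )
        assert estimate_fdr_at_cutpoint(worked_profile, 2) == pytest.approx(
            (1.2, 2, 0.6)
        )

    def test_cutpoint_above_everything(self, worked_profile):
        assert estimate_fdr_at_cutpoint(worked_profile, 99) == (0.0, 0, 0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            obs = rng.normal(size=6)
            perm = rng.normal(size=(6, 11))
            prof = StatisticProfile(obs, perm, "meanrank")
            for C in (0.0, 0.3, 1.0, 2.5):
                v = sum(
                    (sum(abs(perm[j, b]) >= C for b in range(11)) + (abs(obs[j]) >= C))
                    / 12
                    for j in range(6)
                )
                r = sum(abs(obs[j]) >= C for j in range(6))
                v_hat, r_hat, fdr_hat = estimate_fdr_at_cutpoint(prof, C)
                assert v_hat == pytest.approx(v)
                assert r_hat == r
                assert fdr_hat == pytest.approx(v / r if r else 0.0)


class TestDsFdrThreshold:
    def test_worked_profile_q025(self, worked_profile):
        res = dsfdr_threshold(worked_profile, 0.25)
        assert res.c_hat == 10.0
        np.testing.assert_array_equal(res.rejected, [True, False])

    def test_worked_profile_q07(self, worked_profile):
        res = dsfdr_threshold(worked_profile, 0.7)
        assert res.c_hat == 2.0
        np.testing.assert_array_equal(res.rejected, [True, True])

    def test_no_solution_gives_infinite_cutpoint(self):
        # permuted values dominate the observed everywhere
        prof = StatisticProfile(
            observed=[1.0, 1.0],
            permuted=[[5.0, 6.0, 7.0], [5.0, 6.0, 7.0]],
            statistic_name="meanrank",
        )
        res = dsfdr_threshold(prof, 0.05)
        assert np.isinf(res.c_hat)
        assert res.n_rejected == 0

    def test_cutpoint_table_monotone(self, toy_matrix, toy_groups):
        prof = build_null(toy_matrix, toy_groups, B=60, seed=3)
        res = dsfdr_threshold(prof, 0.1)
        assert (np.diff(res.r_hat) <= 0).all()
        assert (np.diff(res.v_hat) <= 1e-12).all()

    def test_table_agrees_with_single_cutpoint_estimates(self, worked_profile):
        res = dsfdr_threshold(worked_profile, 0.5)
        for c, v, r, f in zip(res.cutpoints, res.v_hat, res.r_hat, res.fdr_hat):
            assert (v, r, f) == pytest.approx(estimate_fdr_at_cutpoint(worked_profile, c))


def shared_null_matrix(rng, m, n):
    """Rows are permutations of one multiset: identical per-feature nulls."""
    base = np.array([0, 0, 1, 3, 5, 9], dtype=float)[:n]
    values = np.stack([rng.permutation(base) for _ in range(m)])
    return AbundanceMatrix(
        values, tuple(f"f{i}" for i in range(m)), tuple(f"s{j}" for j in range(n))
    )


class TestDsFdrAdjusted:
    def test_single_feature_equals_raw_p(self, toy_matrix, toy_groups):
        prof = build_null(
            toy_matrix.select_features(np.array([True, False, False])),
            toy_groups,
            B=40,
            seed=4,
        )
        adj = dsfdr_adjusted_pvalues(prof).values
        assert adj[0] == pytest.approx(permutation_pvalues(prof)[0])

    def test_collapses_to_bh_under_identical_nulls(self, groups_5_5):
        """With one shared null across features the discrete procedure loses
        its edge: adjusted values match BH's up to the (m-1)/(B+1)
        granularity of the plug-in estimator, never exceeding them."""
        rng = np.random.default_rng(17)
        base = np.array([0, 0, 0, 0, 1, 2, 3, 5, 9, 9], dtype=float)
        for _ in range(10):
            values = np.stack([rng.permutation(base) for _ in range(8)])
            m = AbundanceMatrix(
                values,
                tuple(f"f{i}" for i in range(8)),
                tuple(f"s{j}" for j in range(10)),
            )
            prof = exhaustive_null(m, groups_5_5)  # identical per-row nulls
            adj = dsfdr_adjusted_pvalues(prof).values
            bh = bh_adjust(permutation_pvalues(prof)).values
            gap = (prof.n_features - 1) / (prof.B + 1)
            assert (adj <= bh + 1e-12).all()
            assert (bh - adj <= gap + 1e-12).all()
            # identical rejection sets at every level not straddled by the
            # estimator granularity
            for q in QGRID:
                if np.min(np.abs(np.concatenate([adj, bh]) - q)) > gap:
                    np.testing.assert_array_equal(
                        dsfdr_threshold(prof, q).rejected, bh <= q
                    )

    def test_threshold_and_adjusted_always_agree(self, toy_matrix, toy_groups):
        """Thresholding the adjusted values at q reproduces the cut-point
        procedure's rejections at every q, for heterogeneous and shared
        tie structures alike."""
        rng = np.random.default_rng(23)
        g6 = GroupAssignment([0, 0, 0, 1, 1, 1])
        profiles = [exhaustive_null(toy_matrix, toy_groups)]
        for _ in range(10):
            profiles.append(exhaustive_null(random_count_matrix(rng, 5, 6, high=4), g6))
        for prof in profiles:
            adj = dsfdr_adjusted_pvalues(prof).values
            for q in QGRID:
                np.testing.assert_array_equal(
                    dsfdr_threshold(prof, q).rejected, adj <= q
                )

    def test_bh_rejections_subset_at_moderate_levels(self):
        """At the q levels used in practice, the discrete procedure rejects
        everything BH rejects on sparse exhaustive toys."""
        rng = np.random.default_rng(29)
        g = GroupAssignment([0, 0, 0, 1, 1, 1])
        for _ in range(10):
            m = random_count_matrix(rng, 6, 6, high=4)
            prof = exhaustive_null(m, g)
            adj = dsfdr_adjusted_pvalues(prof).values
            bh = bh_adjust(permutation_pvalues(prof)).values
            for q in QGRID[QGRID <= 0.4]:
                assert not np.any((bh <= q) & (adj > q))


class TestFbh:
    def test_all_zero_features_filtered(self, groups_5_5):
        values = np.zeros((4, 10))
        m = AbundanceMatrix(values, tuple("abcd"), tuple(f"s{i}" for i in range(10)))
        res = fbh_procedure(m, groups_5_5, B=50, q=0.1, seed=0)
        assert not res.kept.any()
        assert not res.rejected.any()

    def test_no_filtering_means_plain_bh(self):
        """When every feature can reach q, FBH equals BH on all m features."""
        rng = np.random.default_rng(31)
        g = GroupAssignment([0] * 6 + [1] * 6)
        values = rng.integers(10, 100, size=(5, 12)).astype(float)  # dense, untied
        values += rng.uniform(0, 0.5, size=values.shape)
        m = AbundanceMatrix(values, tuple("abcde"), tuple(f"s{i}" for i in range(12)))
        res = fbh_procedure(m, g, B=400, q=0.2, seed=1)
        assert res.kept.all()
        prof = build_null(m, g, "meanrank", 400, 1)
        bh = bh_adjust(permutation_pvalues(prof)).values <= 0.2
        np.testing.assert_array_equal(res.rejected, bh)

    def test_filtering_dominates_bh_on_mixed_fixture(self, groups_5_5):
        """Three singleton-presence features (unable to reach q) plus three
        strongly separated features: FBH rejects at least what BH does."""
        rng = np.random.default_rng(37)
        values = np.zeros((6, 10))
        for j in range(3):
            values[j, j] = 5.0  # singleton presence: min achievable p = 1
        for j in range(3, 6):
            values[j] = np.r_[rng.uniform(0, 1, 5), rng.uniform(50, 60, 5)]
        m = AbundanceMatrix(
            values, tuple(f"f{i}" for i in range(6)), tuple(f"s{i}" for i in range(10))
        )
        res = fbh_procedure(m, groups_5_5, B=500, q=0.1, seed=2)
        np.testing.assert_array_equal(res.kept, [False] * 3 + [True] * 3)
        prof = build_null(m, groups_5_5, "meanrank", 500, 2)
        bh_rejected = bh_adjust(permutation_pvalues(prof)).values <= 0.1
        assert (res.rejected | ~bh_rejected).all()  # superset
        assert res.rejected.sum() >= bh_rejected.sum()


class TestProcedureDominance:
    def test_dsfdr_rejects_superset_of_bh_at_practical_level(self):
        """On sampled permutation profiles of sparse count tables, the
        cut-point procedure rejects a superset of BH at q = 0.1."""
        rng = np.random.default_rng(41)
        g = GroupAssignment([0] * 5 + [1] * 5)
        for _ in range(10):
            m = random_count_matrix(rng, 30, 10, high=5)
            prof = build_null(m, g, "meanrank", 200, int(rng.integers(1 << 30)))
            ds = dsfdr_threshold(prof, 0.1).rejected
            bh = bh_adjust(permutation_pvalues(prof)).values <= 0.1
            assert (ds | ~bh).all()
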
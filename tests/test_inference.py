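"""cNBS permutation inference: p-value formulas, SES, mv pooling, FDR,
permutation plans and the enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from densefc.atlas import toy_labels
from densefc.connectome import cell_name
from densefc.datasets import CohortParams, generate_behavior, generate_connectomes
from densefc.edge_models import build_observation_table
from densefc.inference import (
    PermutationPlan,
    build_null,
    cnbs_test,
    exact_p,
    fdr_adjust,
    mv_cnbs,
    mv_statistic,
    network_observed,
    permutation_p,
    permute_observations,
    ses,
)


class TestPermutationP:
    def test_observed_beats_all_nulls(self):
        null = np.arange(1000, dtype=float)
        assert permutation_p(2000.0, null, "greater") == pytest.approx(1 / 1001)

    def test_observed_ties_every_null(self):
        null = np.zeros(500)
        assert permutation_p(0.0, null, "greater") == 1.0
        assert permutation_p(0.0, null, "less") == 1.0

    def test_two_sided_at_null_median_is_large(self, rng):
        null = rng.normal(size=1001)
        med = float(np.median(null))
        p = permutation_p(med, null, "two_sided")
        assert p > 0.9

    def test_tail_directions_are_complementary(self, rng):
        null = rng.normal(size=400)
        obs = 1.3
        pg = permutation_p(obs, null, "greater")
        pl = permutation_p(obs, null, "less")
        # (1+k_g)/(1+B) + (1+k_l)/(1+B) = (2 + B + ties)/(1+B)
        assert pg + pl == pytest.approx((2 + len(null)) / (1 + len(null)), abs=1e-12)


class TestSES:
    def test_at_null_mean_is_zero(self, rng):
        null = rng.normal(5.0, 2.0, size=800)
        assert ses(float(null.mean()), null) == pytest.approx(0.0, abs=1e-12)

    def test_two_sd_above_mean_is_two(self, rng):
        null = rng.normal(size=800)
        target = null.mean() + 2 * null.std(ddof=1)
        assert ses(float(target), null) == pytest.approx(2.0)

    def test_degenerate_null_warns_and_returns_nan(self):
        with pytest.warns(RuntimeWarning, match="SES undefined"):
            out = ses(1.0, np.zeros(3))
        assert np.isnan(out)

    def test_sign_agrees_with_offset(self, rng):
        null = rng.normal(size=200)
        mu = null.mean()
        assert ses(mu + 0.5, null) > 0 > ses(mu - 0.5, null)


class TestMvStatistic:
    def test_closed_forms(self):
        assert mv_statistic([0.0, 0.0, 0.0]) == 0.0
        assert mv_statistic([-2.5]) == pytest.approx(2.5)
        assert mv_statistic([3.0, 4.0]) == pytest.approx(2.5)       # 5 / 2
        assert mv_statistic([3.0, 4.0], "rms") == pytest.approx(5 / np.sqrt(2))

    def test_empty_grouping_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mv_statistic([])


class TestFDR:
    def test_single_p_is_identity(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=20)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestNetworkObserved:
    def test_mean_and_identity(self):
        assert network_observed(np.array([1.0, 2.0, 3.0]), np.array([0, 1, 2])) == 2.0
        assert network_observed(np.array([1.5, 9.9]), np.array([0])) == 1.5
        assert network_observed(np.zeros(4), np.arange(4)) == 0.0

    def test_non_finite_edges_dropped(self):
        t = np.array([1.0, np.nan, 3.0])
        assert network_observed(t, np.arange(3)) == 2.0

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            network_observed(np.array([1.0]), np.array([], dtype=int))


class TestPermutationPlan:
    def test_each_entry_is_bijection(self, toy_table):
        plan = PermutationPlan.sample(toy_table, B=20, seed=3)
        for entry in plan.assignment:
            for perm in entry:
                assert sorted(perm) == list(range(len(perm)))

    def test_enumeration_covers_space_exactly(self, toy_table):
        sub = toy_table.subset(
            toy_table.meta["subject"].isin(toy_table.subjects[:2]).to_numpy()
        )
        plan = PermutationPlan.enumerate(sub)
        assert plan.B == 24 * 24  # two subjects with 4 sessions: (4!)^2
        seen = {tuple(tuple(p) for p in entry) for entry in plan.assignment}
        assert len(seen) == plan.B

    def test_space_size(self):
        assert PermutationPlan.space_size([3, 3]) == 36
        assert PermutationPlan.space_size([2, 3, 4]) == 2 * 6 * 24


class TestPermuteObservations:
    def test_identity_leaves_table_unchanged(self, toy_table):
        entry = [np.arange(4) for _ in toy_table.subjects]
        out = permute_observations(toy_table, entry)
        np.testing.assert_array_equal(out.Z, toy_table.Z)

    def test_swap_moves_session_blocks_together(self, toy_table):
        entry = [np.arange(4) for _ in toy_table.subjects]
        entry[0] = np.array([1, 0, 2, 3])  # swap sessions 1 and 2 for subject 0
        out = permute_observations(toy_table, entry)
        meta = toy_table.meta
        subj = toy_table.subjects[0]
        for cond in toy_table.conditions:
            i1 = meta.index[(meta.subject == subj) & (meta.session == 1)
                            & (meta.condition == cond)][0]
            i2 = meta.index[(meta.subject == subj) & (meta.session == 2)
                            & (meta.condition == cond)][0]
            np.testing.assert_array_equal(out.Z[i1], toy_table.Z[i2])
            np.testing.assert_array_equal(out.Z[i2], toy_table.Z[i1])
        untouched = meta.subject != subj
        np.testing.assert_array_equal(out.Z[untouched.to_numpy()],
                                      toy_table.Z[untouched.to_numpy()])
        # predictors never move
        pd.testing.assert_frame_equal(out.meta, toy_table.meta)

    def test_inverse_restores_original(self, toy_table, rng):
        entry = [rng.permutation(4) for _ in toy_table.subjects]
        inverse = [np.argsort(p) for p in entry]
        once = permute_observations(toy_table, entry)
        back = permute_observations(once, inverse)
        np.testing.assert_array_equal(back.Z, toy_table.Z)


class TestBuildNull:
    def test_null_has_requested_size(self, toy_table):
        plan = PermutationPlan.sample(toy_table, B=25, seed=1)
        null = build_null(toy_table, plan=plan)
        assert null.cell_t.shape == (25, len(toy_table.partition))
        assert null.edge_t.shape == (25, toy_table.n_edges)

    def test_reproducible_given_seed(self, toy_table):
        a = build_null(toy_table, plan=PermutationPlan.sample(toy_table, 10, 9))
        b = build_null(toy_table, plan=PermutationPlan.sample(toy_table, 10, 9))
        np.testing.assert_array_equal(a.edge_t, b.edge_t)

    def test_tiny_instance_sampled_null_matches_enumeration(self):
        """On a 2-subject × 3-session instance the sampled null's moments
        match the exactly enumerated 36-relabeling null."""
        params = CohortParams(n_subjects=2, n_sessions=3,
                              node_labels=toy_labels(2, 2), seed=31,
                              null_mode=True)
        bt = generate_behavior(params)
        conns, _ = generate_connectomes(params, bt)
        table = build_observation_table(conns, bt)
        # with 2 subjects the subject-level covariates are collinear
        drop = ("age_c", "sex_c")
        exact = build_null(table, drop=drop)  # auto-enumerates: (3!)^2 = 36
        assert exact.exact and exact.cell_t.shape[0] == 36
        sampled = build_null(
            table, plan=PermutationPlan.sample(table, B=2000, seed=5), drop=drop
        )
        for cell in exact.cell_t.columns:
            ex = exact.cell_t[cell].to_numpy()
            sa = sampled.cell_t[cell].to_numpy()
            mc_se = ex.std(ddof=1) / np.sqrt(2000)
            assert sa.mean() == pytest.approx(ex.mean(), abs=4 * mc_se)
            assert sa.std(ddof=1) == pytest.approx(ex.std(ddof=1), rel=0.15)


class TestCnbsTest:
    def test_result_contract(self, toy_table):
        res, null = cnbs_test(toy_table, B=30, seed=2,
                              null=build_null(
                                  toy_table,
                                  plan=PermutationPlan.sample(toy_table, 30, 2)))
        assert set(res["cell"]) == {cell_name(c) for c in toy_table.partition}
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()
        assert np.isfinite(res["ses"]).all()
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_ses_sign_matches_observed_vs_null_mean(self, toy_table):
        res, _ = cnbs_test(toy_table, B=30, seed=4,
                           null=build_null(
                               toy_table,
                               plan=PermutationPlan.sample(toy_table, 30, 4)))
        diff = res["observed_t"] - res["null_mean"]
        assert np.all(np.sign(res["ses"]) == np.sign(diff))


class TestMvCnbs:
    def test_ses_absent_when_observed_below_null_mean(self, rng):
        null_cells = pd.DataFrame(rng.normal(2.0, 0.1, size=(100, 2)),
                                  columns=["a", "b"])
        out = mv_cnbs({"a": 0.0, "b": 0.0}, null_cells, {"grp": ["a", "b"]})
        assert out["grp"].ses is None
        assert out["grp"].p > 0.9

    def test_pooled_statistic_nonnegative_and_p_valid(self, toy_table):
        null = build_null(toy_table, plan=PermutationPlan.sample(toy_table, 40, 6))
        res, _ = cnbs_test(toy_table, null=null)
        observed = dict(zip(res["cell"], res["observed_t"]))
        from densefc.inference import default_groupings

        out = mv_cnbs(observed, null.cell_t, default_groupings(toy_table.partition))
        for eff in out.values():
            assert eff.observed >= 0
            assert 0 < eff.p <= 1

    def test_unknown_cell_rejected(self, rng):
        null_cells = pd.DataFrame(rng.normal(size=(10, 1)), columns=["a"])
        with pytest.raises(KeyError, match="unknown"):
            mv_cnbs({"a": 1.0}, null_cells, {"grp": ["a", "zzz"]})
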
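import math

import numpy as np
import pytest

from prognet import (
    EffectEstimate,
    MetaAnalysis,
    effects_from_records,
    heterogeneity,
    leave_one_out,
    meta_regression,
    pool_auto,
    pool_fixed,
    pool_random_dl,
    subgroup_analysis,
    tau2_dl,
)
from prognet.simulate import MetaSimConfig, simulate_meta


def est(y, se, sid="s"):
    return EffectEstimate(study_id=sid, y=y, se=se)


TWO = [est(0.0, 1.0, "a"), est(1.0, 1.0, "b")]
IDENTICAL = [est(0.5, 0.2, "a"), est(0.5, 0.2, "b")]


class TestFixedPooling:
    def test_single_study_identity(self):
        res = pool_fixed([est(0.5, 0.2)])
        assert (res.mu, res.se_mu) == (0.5, pytest.approx(0.2))
        assert res.Q == 0 and res.df == 0

    def test_two_study_closed_form(self):
        res = pool_fixed(TWO)
        assert res.mu == pytest.approx(0.5)
        assert res.se_mu == pytest.approx(1 / math.sqrt(2))
        assert res.Q == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            MetaAnalysis([])

    def test_weighted_mean_within_range_and_weights_sum(self, table1_effects):
        res = pool_fixed(table1_effects)
        ys = [e.y for e in table1_effects]
        assert min(ys) <= res.mu <= max(ys)
        assert sum(res.weights_pct.values()) == pytest.approx(100.0, abs=1e-9)


class TestHeterogeneity:
    def test_identical_studies_homogeneous(self):
        het = heterogeneity(IDENTICAL)
        assert het.Q == pytest.approx(0.0) and het.i2 == 0.0

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity([est(0.5, 0.2)])

    def test_serum_subgroup_i2(self, table1):
        serum = effects_from_records(r for r in table1 if r.specimen == "serum")
        assert heterogeneity(serum).i2 == pytest.approx(86.5, abs=0.2)


class TestTau2DL:
    def test_zero_when_q_below_df(self):
        assert tau2_dl(IDENTICAL) == 0.0
        assert tau2_dl(TWO) == 0.0  # Q=0.5 < df=1

    def test_full_table_value(self, table1_effects):
        # independent spreadsheet-style evaluation of the moment formula
        y = np.array([e.y for e in table1_effects])
        w = np.array([e.w_fixed for e in table1_effects])
        mu = (w * y).sum() / w.sum()
        Q = (w * (y - mu) ** 2).sum()
        C = w.sum() - (w**2).sum() / w.sum()
        expected = max(0.0, (Q - (len(y) - 1)) / C)
        assert expected == pytest.approx(0.295, abs=0.005)
        assert tau2_dl(table1_effects) == pytest.approx(expected, rel=1e-12)


class TestRandomPooling:
    def test_reduces_to_fixed_when_tau2_zero(self):
        fr, rr = pool_fixed(IDENTICAL), pool_random_dl(IDENTICAL)
        assert rr.mu == pytest.approx(fr.mu)
        assert rr.se_mu == pytest.approx(fr.se_mu)

    def test_random_se_never_smaller_than_fixed(self, table1_effects):
        assert pool_random_dl(table1_effects).se_mu >= pool_fixed(table1_effects).se_mu

    def test_statsmodels_cross_check(self, table1_effects):
        """Independent oracle: statsmodels' DL combine_effects."""
        sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
        y = np.array([e.y for e in table1_effects])
        v = np.array([e.var for e in table1_effects])
        res = sm_meta.combine_effects(y, v, method_re="dl")
        ours = pool_random_dl(table1_effects)
        assert ours.tau2 == pytest.approx(res.tau2, rel=1e-10)
        assert ours.mu == pytest.approx(res.mean_effect_re, rel=1e-10)
        assert pool_fixed(table1_effects).mu == pytest.approx(
            res.mean_effect_fe, rel=1e-10
        )

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            pool_random_dl([est(0.5, 0.2)])


class TestModelSelection:
    def test_full_table_selects_random(self, table1_effects):
        assert pool_auto(table1_effects).model == "random"

    def test_non_asian_selects_fixed(self, table1):
        ests = effects_from_records(r for r in table1 if r.ethnicity == "non-Asian")
        res = pool_auto(ests)
        assert res.model == "fixed"
        assert res.p_Q == pytest.approx(0.709, abs=0.005)

    def test_identical_studies_select_fixed(self):
        assert pool_auto(IDENTICAL).model == "fixed"


class TestInvariances:
    def test_permutation_invariance(self, table1_effects):
        res = pool_auto(table1_effects)
        rev = pool_auto(list(reversed(table1_effects)))
        assert rev.mu == pytest.approx(res.mu, rel=1e-12)
        assert rev.Q == pytest.approx(res.Q, rel=1e-12)

    def test_shift_equivariance(self, table1_effects):
        shifted = [est(e.y + 0.7, e.se, e.study_id) for e in table1_effects]
        base, moved = pool_auto(table1_effects), pool_auto(shifted)
        assert moved.mu == pytest.approx(base.mu + 0.7, rel=1e-9)
        assert moved.Q == pytest.approx(base.Q, rel=1e-9)
        assert moved.tau2 == pytest.approx(base.tau2, rel=1e-9)
        assert moved.i2 == pytest.approx(base.i2, rel=1e-9)

    def test_small_k_matches_direct_formula(self):
        ests = [est(0.1, 0.3, "a"), est(0.4, 0.2, "b"), est(-0.2, 0.5, "c"), est(0.9, 0.4, "d")]
        y = np.array([e.y for e in ests]); w = np.array([e.w_fixed for e in ests])
        mu = float((w * y).sum() / w.sum())
        Q = float((w * (y - mu) ** 2).sum())
        res = pool_fixed(ests)
        assert res.mu == pytest.approx(mu, abs=1e-12)
        assert res.Q == pytest.approx(Q, abs=1e-12)


class TestSubgroups:
    def test_ethnicity_levels(self, table1):
        t = subgroup_analysis(table1, "ethnicity")
        asian, non_asian = t.levels["Asian"], t.levels["non-Asian"]
        assert asian.hr == pytest.approx(1.28, abs=0.01)
        assert (non_asian.hr, non_asian.model) == (pytest.approx(2.08, abs=0.01), "fixed")
        assert sum(r.k for r in t.levels.values()) == len(table1)

    def test_size_class_levels(self, table1):
        t = subgroup_analysis(table1, "size_class")
        assert t.levels["large"].hr == pytest.approx(2.05, abs=0.01)
        assert t.levels["small"].hr == pytest.approx(1.24, abs=0.01)

    def test_degenerate_single_level(self, table1):
        tissue_only = [r for r in table1 if r.specimen == "tissue"]
        t = subgroup_analysis(tissue_only, "specimen")
        assert list(t.levels) == ["tissue"]

    def test_unknown_factor_rejected(self, table1):
        with pytest.raises(ValueError, match="unknown subgroup factor"):
            subgroup_analysis(table1, "country_code")


class TestLeaveOneOut:
    def test_count_and_ids(self, table1_effects):
        rows = leave_one_out(table1_effects)
        assert len(rows) == 11
        assert [sid for sid, _ in rows] == [e.study_id for e in table1_effects]

    def test_stability_on_bundled_table(self, table1_effects):
        for _, res in leave_one_out(table1_effects):
            assert 1.0 < res.hr < 2.5

    def test_three_identical_studies(self):
        ests = [est(0.5, 0.2, s) for s in "abc"]
        two = pool_auto(ests[:2])
        for _, res in leave_one_out(ests):
            assert res.mu == pytest.approx(two.mu)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            leave_one_out(TWO)


class TestMetaRegression:
    def test_saturated_two_group_slope(self):
        a, b = 0.2, 0.9
        ests = [est(a, 0.3, "a1"), est(a, 0.3, "a2"), est(b, 0.3, "b1"), est(b, 0.3, "b2")]
        res = meta_regression(ests, {"x": [0, 0, 1, 1]})
        assert res.params["x"] == pytest.approx(b - a, abs=1e-10)
        assert res.params["intercept"] == pytest.approx(a, abs=1e-10)

    def test_constant_covariate_rejected(self):
        ests = [est(0.1 * i, 0.3, f"s{i}") for i in range(5)]
        with pytest.raises(ValueError, match="rank"):
            meta_regression(ests, {"x": [0, 0, 0, 0, 0]})

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            meta_regression(TWO + [est(0.2, 0.3, "c")], {"x": [0, 1, 2]})

    def test_slope_recovery_by_simulation(self):
        """True moderator effect 0.5 recovered within 3 Monte-Carlo SEs."""
        slope, reps = 0.5, 500
        slopes = []
        for rep in range(reps):
            recs, truth = simulate_meta(
                MetaSimConfig(k_studies=40, mu=0.0, tau2=0.1,
                              se_low=0.1, se_high=0.4, seed=50_000 + rep)
            )
            x = np.array([i % 2 for i in range(40)], dtype=float)
            # scale equivariance: multiplying HR/CI by exp(slope*x) shifts y
            ests = [
                est(truth["y"][i] + slope * x[i], truth["se"][i], recs[i].study_id)
                for i in range(40)
            ]
            slopes.append(meta_regression(ests, {"x": x}).params["x"])
        mc_se = np.std(slopes, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(slopes) - slope) < 3 * mc_se
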
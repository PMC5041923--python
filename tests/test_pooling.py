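"""Fixed and DerSimonian–Laird pooling, heterogeneity, Wald test, subgroups."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import genemeta as gm


def _estimate(log_or, se, model=gm.RECESSIVE, study_id="s"):
    return gm.EffectEstimate(
        study_id=study_id, model=model, log_or=log_or, se_log_or=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - 1.959963984540054 * se),
        ci_high=math.exp(log_or + 1.959963984540054 * se),
    )


def _estimate_lists(min_k=2, max_k=8):
    return st.lists(
        st.tuples(
            st.floats(-2.0, 2.0, allow_nan=False), st.floats(0.05, 1.0, allow_nan=False)
        ),
        min_size=min_k,
        max_size=max_k,
    ).map(lambda lst: [_estimate(y, s, study_id=f"s{i}") for i, (y, s) in enumerate(lst)])


class TestPoolFixed:
    def test_single_study_identity(self):
        est = _estimate(0.3, 0.1)
        pooled = gm.pool_fixed([est])
        assert pooled.pooled_log_or == pytest.approx(0.3)
        assert pooled.se_pooled == pytest.approx(0.1)
        assert pooled.q == 0.0 and pooled.df == 0 and pooled.i2 == 0.0

    def test_two_identical_estimates(self):
        pooled = gm.pool_fixed([_estimate(0.5, 0.2, study_id="a"),
                                _estimate(0.5, 0.2, study_id="b")])
        assert pooled.pooled_log_or == pytest.approx(0.5)
        assert pooled.q == pytest.approx(0.0, abs=1e-12)
        assert pooled.i2 == 0.0
        assert pooled.se_pooled == pytest.approx(0.2 / math.sqrt(2))

    def test_empty_and_mixed_model_inputs_rejected(self):
        with pytest.raises(gm.DomainError):
            gm.pool_fixed([])
        with pytest.raises(gm.ValidationError):
            gm.pool_fixed([_estimate(0.1, 0.1, gm.RECESSIVE),
                           _estimate(0.1, 0.1, gm.DOMINANT)])

    def test_white_european_recessive_heterogeneity(self, table1):
        """Six white-European recessive studies show moderate heterogeneity."""
        studies = [s for s in table1 if s.subgroup == "white_european"]
        pooled = gm.pool_fixed(gm.estimates_for(studies, gm.RECESSIVE))
        assert pooled.i2 == pytest.approx(44, abs=1)


class TestPoolRandom:
    def test_hand_built_triple_against_frozen_dl_oracle(self):
        # log ORs (0, 0.5, 1.0), all SE 0.2: w=25 each, Q=12.5, C=50,
        # tau2=(12.5-2)/50=0.21, w*=4 each, pooled=0.5, SE=1/sqrt(12)
        ests = [_estimate(0.0, 0.2, study_id="a"),
                _estimate(0.5, 0.2, study_id="b"),
                _estimate(1.0, 0.2, study_id="c")]
        pooled = gm.pool_random(ests)
        assert pooled.q == pytest.approx(12.5, rel=1e-12)
        assert pooled.tau2 == pytest.approx(0.21, rel=1e-12)
        assert pooled.pooled_log_or == pytest.approx(0.5, abs=1e-12)
        assert pooled.se_pooled == pytest.approx(0.2886751345948129, rel=1e-12)

    def test_truncation_reproduces_fixed_pooling_exactly(self, table1):
        """When Q <= df, tau2 truncates to 0 and random == fixed bit-for-bit."""
        ests = gm.estimates_for(table1, gm.ADDITIVE)  # homogeneous contrast
        random = gm.pool_random(ests)
        fixed = gm.pool_fixed(ests)
        assert random.tau2 == 0.0
        assert random.pooled_log_or == fixed.pooled_log_or
        assert random.se_pooled == fixed.se_pooled
        assert random.ci_low == fixed.ci_low and random.ci_high == fixed.ci_high

    def test_overall_dominant_matches_published_value(self, table1):
        pooled = gm.pool_random(gm.estimates_for(table1, gm.DOMINANT))
        assert pooled.pooled_or == pytest.approx(1.10, abs=0.005)
        assert pooled.ci_low == pytest.approx(0.91, abs=0.005)
        assert pooled.ci_high == pytest.approx(1.34, abs=0.005)

    @given(ests=_estimate_lists())
    def test_pooled_value_is_convex_combination(self, ests):
        logs = [e.log_or for e in ests]
        for pooled in (gm.pool_fixed(ests), gm.pool_random(ests)):
            assert min(logs) - 1e-9 <= pooled.pooled_log_or <= max(logs) + 1e-9

    @given(ests=_estimate_lists())
    def test_random_se_and_ci_at_least_fixed(self, ests):
        fixed = gm.pool_fixed(ests)
        random = gm.pool_random(ests)
        assert random.se_pooled >= fixed.se_pooled - 1e-12
        fixed_width = math.log(fixed.ci_high) - math.log(fixed.ci_low)
        random_width = math.log(random.ci_high) - math.log(random.ci_low)
        assert random_width >= fixed_width - 1e-12

    @given(ests=_estimate_lists())
    def test_i2_in_range_and_zero_iff_q_small(self, ests):
        pooled = gm.pool_fixed(ests)
        assert 0.0 <= pooled.i2 <= 100.0
        if pooled.q <= pooled.df:
            assert pooled.i2 == 0.0
        assert pooled.tau2 == 0.0  # fixed scheme reports tau2 = 0


class TestZTest:
    def test_zero_effect(self):
        z, p = gm.z_test(0.0, 0.5)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_quantile_cdf_inverse_pair(self):
        _, p = gm.z_test(1.959963984540054, 1.0)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(gm.DomainError):
            gm.z_test(0.1, 0.0)

    def test_white_european_recessive_significance(self, table1):
        studies = [s for s in table1 if s.subgroup == "white_european"]
        pooled = gm.pool_random(gm.estimates_for(studies, gm.RECESSIVE))
        assert round(pooled.p_value, 2) == pytest.approx(0.02)


class TestSubgroupAnalysis:
    def test_single_subgroup_equals_overall(self, table1):
        sub = gm.subgroup_analysis(table1, gm.DOMINANT, "random", grouping=lambda s: "all")
        (only,) = sub.per_subgroup.values()
        assert only.pooled_log_or == sub.overall.pooled_log_or
        assert only.se_pooled == sub.overall.se_pooled

    def test_subgroup_ks_sum_to_overall(self, table1):
        sub = gm.subgroup_analysis(table1, gm.RECESSIVE, "random")
        assert sum(r.k for r in sub.per_subgroup.values()) == sub.overall.k == 9

    def test_east_asian_recessive_matches_published(self, table1):
        sub = gm.subgroup_analysis(table1, gm.RECESSIVE, "random")
        ea = sub.per_subgroup["east_asian"]
        assert ea.pooled_or == pytest.approx(0.98, abs=0.005)
        assert ea.ci_low == pytest.approx(0.47, abs=0.005)
        assert ea.ci_high == pytest.approx(2.04, abs=0.005)

    def test_east_asian_dominant_i2_matches_published(self, table1):
        sub = gm.subgroup_analysis(table1, gm.DOMINANT, "random")
        assert sub.per_subgroup["east_asian"].i2 == pytest.approx(25, abs=1)

    def test_unmapped_study_rejected(self, table1):
        with pytest.raises(gm.ValidationError):
            gm.subgroup_analysis(table1, gm.DOMINANT, grouping=lambda s: "")
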
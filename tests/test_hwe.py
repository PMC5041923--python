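"""Hardy–Weinberg χ² test and control-arm screening filter."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import genemeta as gm


class TestHweChisq:
    def test_matches_published_p_for_oskina_controls(self):
        res = gm.hwe_chisq(gm.GenotypeCounts(87, 177, 77))
        assert res.p_value == pytest.approx(0.471, abs=0.005)
        assert res.df == 1
        assert res.allele_freq_g == pytest.approx((2 * 87 + 177) / (2 * 341))

    def test_matches_independent_oracle_for_cheng_controls(self):
        # frozen from a direct high-precision evaluation of the expected
        # counts (n p^2, 2np(1-p), n(1-p)^2) and the chi2 upper tail
        res = gm.hwe_chisq(gm.GenotypeCounts(105, 206, 106))
        assert res.chi2 == pytest.approx(0.05989523309814389, rel=1e-12)
        assert res.p_value == pytest.approx(0.8066616055170657, rel=1e-12)
        assert res.p_value == pytest.approx(0.807, abs=0.005)

    def test_exact_hwe_proportions_give_zero_statistic(self):
        res = gm.hwe_chisq(gm.GenotypeCounts(25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_arm_is_domain_error(self):
        with pytest.raises(gm.DomainError):
            gm.hwe_chisq(gm.GenotypeCounts(0, 0, 0))

    @pytest.mark.parametrize("counts", [(10, 0, 0), (0, 0, 10)])
    def test_monomorphic_sample_is_degenerate(self, counts):
        with pytest.raises(gm.DegenerateInputError):
            gm.hwe_chisq(gm.GenotypeCounts(*counts))

    @given(
        gg=st.integers(0, 500), tg=st.integers(0, 500), tt=st.integers(0, 500)
    )
    def test_allele_label_swap_invariance(self, gg, tg, tt):
        """Relabelling G<->T (gg<->tt) leaves chi2 and p unchanged."""
        counts = gm.GenotypeCounts(gg, tg, tt)
        swapped = gm.GenotypeCounts(tt, tg, gg)
        n = counts.total()
        if n == 0 or counts.allele_freq_g() in (0.0, 1.0):
            return
        a, b = gm.hwe_chisq(counts), gm.hwe_chisq(swapped)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12, abs=1e-12)

    def test_null_rejection_rate_near_alpha(self):
        """P-values are ~Uniform(0,1) for multinomial draws from exact HWE."""
        rng = np.random.default_rng(20260927)
        p = 0.5
        probs = [p * p, 2 * p * (1 - p), (1 - p) ** 2]
        draws = rng.multinomial(500, probs, size=2000)
        rejections = sum(
            gm.hwe_chisq(gm.GenotypeCounts(*map(int, d))).p_value <= 0.05 for d in draws
        )
        # 3 sigma MC band around 0.05 at 2000 replicates is ~ +/- 0.015
        assert rejections / 2000 == pytest.approx(0.05, abs=0.02)


class TestHweFilter:
    def test_all_nine_fixture_studies_kept_at_alpha_05(self, table1):
        kept, excluded = gm.hwe_filter(table1, alpha=0.05)
        assert [s.study_id for s in kept] == [s.study_id for s in table1]
        assert excluded == []

    def test_extreme_alpha_excludes_everything(self, table1):
        kept, excluded = gm.hwe_filter(table1, alpha=0.999)
        assert kept == []
        assert len(excluded) == 9
        # exclusion records carry the failing test result
        assert all(isinstance(res, gm.HWEResult) for _, res in excluded)

    def test_gross_violation_is_excluded(self):
        study = gm.StudyRecord(
            study_id="synthetic_bad",
            author="synthetic",
            year=2020,
            country="synthetic",
            subgroup="g",
            cases=gm.GenotypeCounts(30, 40, 30),
            controls=gm.GenotypeCounts(50, 10, 50),  # huge heterozygote deficit
        )
        kept, excluded = gm.hwe_filter([study])
        assert kept == []
        ((_, res),) = excluded
        assert res.p_value < 1e-10

    def test_error_annotated_with_study_id(self):
        study = gm.StudyRecord(
            study_id="mono", author="x", year=2000, country="x", subgroup="g",
            cases=gm.GenotypeCounts(1, 1, 1), controls=gm.GenotypeCounts(10, 0, 0),
        )
        with pytest.raises(gm.DegenerateInputError, match="mono"):
            gm.hwe_filter([study])
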
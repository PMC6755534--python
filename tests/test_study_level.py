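"""Per-study fits, DerSimonian–Laird meta-analysis, ratio IV estimator."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from bwmr.grs import WeightSet, compute_grs
from bwmr.simulate import seven_snp_config, simulate_cohort
from bwmr.study_level import (
    MetaResult,
    fit_study_assocs,
    forest_table,
    meta_analyze,
    ratio_iv_estimate,
)
from bwmr.summary_io import StudyAssoc


def assoc(beta, se, study_id="s", n=1000, **kw):
    return StudyAssoc(study_id=study_id, assoc_kind="grs_on_outcome",
                      beta=beta, se=se, n=n, **kw)


def meta_of(beta, se):
    z = 1.959963984540054
    return MetaResult(beta, se, beta - z * se, beta + z * se, 0.05,
                      0.0, 1, 0.0, 0.0, "random", 2)


class TestMetaAnalyze:
    def test_two_identical_studies_closed_form(self):
        m = meta_analyze([assoc(1.0, 1.0, "a"), assoc(1.0, 1.0, "b")], model="fixed")
        assert m.beta == pytest.approx(1.0)
        assert m.se == pytest.approx(1 / math.sqrt(2))
        assert m.q == pytest.approx(0.0) and m.i2 == 0.0 and m.tau2 == 0.0

    def test_equal_weights_pool_to_arithmetic_mean(self):
        betas = [0.2, 0.5, 0.8, 1.1]
        m = meta_analyze([assoc(b, 0.3, f"s{i}") for i, b in enumerate(betas)],
                         model="fixed")
        assert m.beta == pytest.approx(np.mean(betas))

    def test_order_invariance(self):
        studies = [assoc(b, s, f"s{i}") for i, (b, s) in
                   enumerate([(0.1, 0.2), (0.4, 0.1), (0.9, 0.5)])]
        a = meta_analyze(studies, model="fixed")
        b = meta_analyze(studies[::-1], model="fixed")
        assert a.beta == pytest.approx(b.beta) and a.q == pytest.approx(b.q)

    def test_random_equals_fixed_when_tau2_zero(self):
        studies = [assoc(0.5, 0.2, "a"), assoc(0.5, 0.3, "b"), assoc(0.5, 0.25, "c")]
        fixed = meta_analyze(studies, model="fixed")
        random = meta_analyze(studies, model="random")
        assert random.tau2 == 0.0
        assert random.beta == pytest.approx(fixed.beta)
        assert random.se == pytest.approx(fixed.se)

    def test_heterogeneity_detected_by_i2(self, rng):
        # oracle: direct evaluation of Q/I2 formulas on the same numbers
        base = rng.normal(0.5, 0.02, size=20)
        se = np.full(20, 0.1)
        homog = meta_analyze([assoc(b, s, f"s{i}") for i, (b, s) in
                              enumerate(zip(base, se))])
        shifted = base.copy()
        shifted[:10] += 0.5
        heterog = meta_analyze([assoc(b, s, f"s{i}") for i, (b, s) in
                                enumerate(zip(shifted, se))])
        assert homog.i2 < 25
        assert heterog.i2 > 25
        w = 1 / se**2
        bf = np.sum(w * shifted) / np.sum(w)
        q = np.sum(w * (shifted - bf) ** 2)
        assert heterog.q == pytest.approx(q)
        assert heterog.i2 == pytest.approx(max(0, (q - 19) / q) * 100)

    def test_matches_statsmodels_dersimonian_laird(self, rng):
        betas = rng.normal(0.3, 0.25, size=12)
        ses = rng.uniform(0.1, 0.4, size=12)
        ours = meta_analyze([assoc(b, s, f"s{i}") for i, (b, s) in
                             enumerate(zip(betas, ses))], model="random")
        ref = combine_effects(betas, ses**2, method_re="dl")
        frame = ref.summary_frame()
        assert ours.beta == pytest.approx(frame.loc["random effect", "eff"], rel=1e-6)
        assert ours.se == pytest.approx(frame.loc["random effect", "sd_eff"], rel=1e-6)
        assert ours.tau2 == pytest.approx(ref.tau2, rel=1e-6)

    def test_single_study_returned_flagged(self):
        m = meta_analyze([assoc(0.4, 0.1)])
        assert m.flag == "single study" and m.beta == 0.4

    def test_all_flagged_estimates_error(self):
        bad = StudyAssoc("s", "grs_on_outcome", None, None, 100, flag="non-convergence")
        with pytest.raises(ValueError, match="no usable"):
            meta_analyze([bad])

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            meta_analyze([assoc(1, 1)], model="bayes")


class TestRatioIv:
    def test_pooled_coefficients_exponentiate_to_or(self):
        # 0.03 / 0.04 -> OR exp(0.75) ~ 2.12 per 1-SD decrease
        iv = ratio_iv_estimate(meta_of(0.03, 0.01), meta_of(0.04, 0.005))
        assert iv.beta == pytest.approx(0.75)
        assert round(iv.or_, 2) == 2.12

    def test_null_numerator_gives_unit_or(self):
        iv = ratio_iv_estimate(meta_of(0.0, 0.01), meta_of(0.04, 0.005))
        assert iv.or_ == pytest.approx(1.0)

    def test_simple_arithmetic(self):
        iv = ratio_iv_estimate(meta_of(0.03, 0.01), meta_of(0.09, 0.01))
        assert iv.beta == pytest.approx(1 / 3)

    def test_self_ratio_is_one(self):
        for b in (0.02, -0.4, 1.3):
            iv = ratio_iv_estimate(meta_of(b, abs(b) / 10), meta_of(b, abs(b) / 10))
            assert iv.beta == pytest.approx(1.0)

    def test_delta_method_se(self):
        iv = ratio_iv_estimate(meta_of(0.03, 0.01), meta_of(0.04, 0.005))
        expected = math.sqrt(0.01**2 / 0.04**2 + 0.03**2 * 0.005**2 / 0.04**4)
        assert iv.se == pytest.approx(expected)
        second = ratio_iv_estimate(meta_of(0.03, 0.01), meta_of(0.04, 0.005),
                                   second_order=True)
        assert second.se > iv.se

    def test_weak_denominator_refused(self):
        with pytest.raises(ValueError, match="uninformative"):
            ratio_iv_estimate(meta_of(0.03, 0.01), meta_of(0.004, 0.005))


@pytest.fixture(scope="module")
def fitted(cohort_7snp):
    ws = WeightSet.from_config_betas(seven_snp_config(seed=42))
    score = compute_grs(cohort_7snp, ws, orientation="bw_lowering")
    return fit_study_assocs(
        cohort_7snp, score,
        covariates=cohort_7snp.covariates[["age", "sex", "pc1", "pc2", "pc3"]],
        study_id="nhs")


class TestFitStudyAssocs:
    def test_three_kinds_produced(self, fitted):
        assert [a.assoc_kind for a in fitted] == [
            "grs_on_exposure", "grs_on_outcome", "exposure_on_outcome"]
        assert all(a.usable() for a in fitted)

    def test_lowering_score_reduces_birth_weight(self, fitted):
        # positive coefficient: more score units -> larger SD *deficit*
        exp = fitted[0]
        assert exp.beta > 0 and exp.beta / exp.se > 5

    def test_observational_association_positive(self, fitted):
        obs = fitted[2]
        assert obs.beta > 0  # lower birth weight, higher T2D risk

    def test_ratio_of_fits_near_theta(self, fitted):
        iv = ratio_iv_estimate(meta_analyze([fitted[1]]), meta_analyze([fitted[0]]))
        assert abs(iv.beta - 0.7) < 3 * iv.se

    def test_degenerate_cohort_flagged_not_raised(self):
        cfg = seven_snp_config(seed=77, baseline_prevalence=0.1)
        cohort = simulate_cohort(cfg, 10)
        ws = WeightSet.from_config_betas(cfg)
        score = compute_grs(cohort, ws)
        # a single case holding the top score: quasi-complete separation
        cohort.t2d_status[:] = 0
        cohort.t2d_status[int(np.argmax(score))] = 1
        out = fit_study_assocs(cohort, score)
        kinds = {a.assoc_kind: a for a in out}
        assert kinds["grs_on_exposure"].usable()
        assert not kinds["grs_on_outcome"].usable()
        assert kinds["grs_on_outcome"].flag is not None


def test_forest_table_shape():
    studies = [assoc(0.2, 0.1, "a"), assoc(0.4, 0.2, "b")]
    pooled = meta_analyze(studies)
    table = forest_table(studies, pooled)
    assert list(table.columns) == ["study", "beta", "se", "ci_low", "ci_high", "weight_pct"]
    assert len(table) == 3
    assert table["weight_pct"].iloc[:2].sum() == pytest.approx(100.0)
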
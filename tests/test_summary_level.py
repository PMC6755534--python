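"""Two-sample MR estimators: Wald ratios, IVW, medians, MR-Egger."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bwmr.summary_level import (
    all_methods,
    egger,
    ivw,
    leave_loci_out,
    median_estimators,
    wald_ratios,
)

from conftest import make_variant


def variant_set(ratios, bx=0.05, sy=0.02, sx=0.002, **kw):
    """Variants whose Wald ratios equal `ratios` exactly."""
    return [
        make_variant(rsid=f"rs{i}", bx=bx, sx=sx, by=r * bx, sy=sy, **kw)
        for i, r in enumerate(ratios)
    ]


def flip(v):
    return dataclasses.replace(
        v,
        effect_allele=v.other_allele,
        other_allele=v.effect_allele,
        eaf=None if v.eaf is None else 1 - v.eaf,
        beta_exposure=-v.beta_exposure,
        beta_outcome=-v.beta_outcome,
    )


class TestWaldRatios:
    def test_arithmetic(self):
        out = wald_ratios([make_variant(bx=0.1, by=0.07, sy=0.02)])
        rsid, ratio, se = out[0]
        assert ratio == pytest.approx(0.7) and se == pytest.approx(0.2)

    def test_sign_flip_invariance(self):
        v = make_variant(bx=0.1, by=0.07, sy=0.02)
        assert wald_ratios([v])[0][1:] == wald_ratios([flip(v)])[0][1:]

    def test_zero_exposure_effect_excluded(self):
        out = wald_ratios([make_variant(bx=0.0), make_variant(rsid="rs2")])
        assert [r[0] for r in out] == ["rs2"]


class TestIvw:
    def test_identical_ratios_recovered_exactly(self):
        est = ivw(variant_set([0.7, 0.7]), orientation="increase")
        assert est.beta == pytest.approx(0.7, abs=1e-14)
        # RSS = 0 so the multiplicative scale stays at 1 (fixed-effect SE)
        fixed = ivw(variant_set([0.7, 0.7]), se_model="fixed", orientation="increase")
        assert est.se == pytest.approx(fixed.se)

    def test_single_variant_delegates_to_wald_ratio(self):
        v = make_variant(bx=0.1, by=0.07, sy=0.02)
        est = ivw([v], orientation="increase")
        assert est.method == "wald_ratio"
        assert est.beta == pytest.approx(0.7, abs=1e-15)
        assert est.se == pytest.approx(0.2, abs=1e-15)

    def test_decrease_orientation_negates(self):
        vs = variant_set([0.7, 0.6, 0.8])
        assert ivw(vs, orientation="decrease").beta == pytest.approx(
            -ivw(vs, orientation="increase").beta)

    def test_or_only_for_binary_outcomes(self):
        vs = variant_set([0.5, 0.6], outcome_type="quantitative")
        assert ivw(vs).or_ is None

    def test_multiplicative_se_never_below_fixed(self, two_sample_43snp):
        mult = ivw(two_sample_43snp.variants, se_model="multiplicative")
        fixed = ivw(two_sample_43snp.variants, se_model="fixed")
        assert mult.se >= fixed.se
        assert mult.beta == pytest.approx(fixed.beta)


class TestMedians:
    def test_equal_weights_reduce_to_simple_median(self):
        vs = variant_set([0.2, 0.9, 0.4, 1.3, 0.6])
        sm_ = median_estimators(vs, weighted=False, n_boot=400, seed=2,
                                orientation="increase")
        wm = median_estimators(vs, weighted=True, n_boot=400, seed=2,
                               orientation="increase")
        assert sm_.beta == pytest.approx(np.median([0.2, 0.9, 0.4, 1.3, 0.6]))
        assert wm.beta == pytest.approx(sm_.beta)

    def test_dominant_weight_pulls_median(self):
        # ratios (1,2,3) with weights (0.98,0.01,0.01): by-hand interpolation
        # s = (0.49, 0.985, 0.995) -> 1 + (0.5-0.49)/(0.985-0.49) = 1.0202...
        bx = np.sqrt(np.array([0.98, 0.01, 0.01]))
        vs = [make_variant(rsid=f"rs{i}", bx=b, by=r * b, sy=1.0)
              for i, (b, r) in enumerate(zip(bx, [1.0, 2.0, 3.0]))]
        est = median_estimators(vs, weighted=True, n_boot=400, seed=3,
                                orientation="increase")
        assert est.beta == pytest.approx(1.0 + 0.01 / 0.495, abs=1e-12)

    def test_seed_required_and_reproducible(self):
        vs = variant_set([0.2, 0.9, 0.4])
        with pytest.raises(ValueError, match="seed"):
            median_estimators(vs)
        a = median_estimators(vs, n_boot=300, seed=7)
        b = median_estimators(vs, n_boot=300, seed=7)
        assert a == b

    def test_low_bootstrap_warns(self):
        vs = variant_set([0.2, 0.9, 0.4])
        with pytest.warns(UserWarning, match="n_boot"):
            median_estimators(vs, n_boot=50, seed=1)

    def test_needs_three_variants(self):
        with pytest.raises(ValueError, match=">= 3"):
            median_estimators(variant_set([0.2, 0.9]), n_boot=300, seed=1)


class TestEgger:
    def test_constrained_intercept_equals_fixed_effect_ivw(self, two_sample_43snp):
        vs = two_sample_43snp.variants
        e = egger(vs, se_model="fixed", constrain_intercept=True)
        i = ivw(vs, se_model="fixed")
        assert e.beta == pytest.approx(i.beta, abs=1e-12)
        assert e.se == pytest.approx(i.se, abs=1e-12)

    def test_recovers_slope_and_intercept_of_exact_line(self):
        # beta_outcome = 0.01 + 0.5 * beta_exposure exactly
        bxs = [0.02, 0.04, 0.06, 0.08]
        vs = [make_variant(rsid=f"rs{i}", bx=b, by=0.01 + 0.5 * b, sy=0.02)
              for i, b in enumerate(bxs)]
        est = egger(vs, orientation="increase")
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.01, abs=1e-10)

    def test_no_exposure_spread_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            egger(variant_set([0.5, 0.7, 0.9], bx=0.05))

    def test_intercept_orientation_fixed_under_reporting_flip(self, two_sample_43snp):
        vs = two_sample_43snp.variants
        a = egger(vs, orientation="increase")
        b = egger(vs, orientation="decrease")
        assert a.intercept == pytest.approx(b.intercept)
        assert a.beta == pytest.approx(-b.beta)


class TestLeaveLociOut:
    def test_excluding_nothing_is_identity(self, two_sample_43snp):
        res = leave_loci_out(two_sample_43snp.variants, ["rs_not_there"])
        assert res.full == res.reduced
        assert res.excluded == ()

    def test_excluding_all_but_one_leaves_wald_ratio(self):
        vs = variant_set([0.5, 0.9, 1.3])
        res = leave_loci_out(vs, ["rs0", "rs1"], orientation="increase")
        assert res.reduced.method == "wald_ratio"
        assert res.reduced.beta == pytest.approx(1.3, abs=1e-12)

    def test_excluding_everything_errors(self):
        vs = variant_set([0.5, 0.9])
        with pytest.raises(ValueError, match="removes all"):
            leave_loci_out(vs, ["rs0", "rs1"])

    def test_removing_pleiotropic_snps_moves_estimate_toward_truth(self):
        # half the SNPs carry a large positive direct effect
        clean = variant_set([0.7] * 5)
        dirty = [dataclasses.replace(v, rsid=f"rsP{i}", beta_outcome=v.beta_outcome + 0.04)
                 for i, v in enumerate(variant_set([0.7] * 5))]
        res = leave_loci_out(clean + dirty, [f"rsP{i}" for i in range(5)],
                             orientation="increase")
        assert abs(res.reduced.beta - 0.7) < abs(res.full.beta - 0.7)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(mask=st.lists(st.booleans(), min_size=5, max_size=5))
def test_allele_reorientation_invariance(mask):
    """Flipping any subset of variants (both betas together) leaves every
    estimator unchanged."""
    ratios = [0.3, 0.6, 0.8, 1.1, 0.2]
    bxs = [0.03, 0.05, 0.07, 0.04, 0.06]
    vs = [make_variant(rsid=f"rs{i}", bx=b, by=r * b, sy=0.02)
          for i, (b, r) in enumerate(zip(bxs, ratios))]
    flipped = [flip(v) if m else v for v, m in zip(vs, mask)]
    a = all_methods(vs, n_boot=200, seed=5)
    b = all_methods(flipped, n_boot=200, seed=5)
    for name in a:
        assert a[name].beta == pytest.approx(b[name].beta, abs=1e-10), name
        assert a[name].se == pytest.approx(b[name].se, rel=0.3), name
    assert a["egger"].intercept == pytest.approx(b["egger"].intercept, abs=1e-10)
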
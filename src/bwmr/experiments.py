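"""Replicated simulation experiments: calibration, recovery, robustness.

These are the package's built-in simulation studies — the same machinery
backs the test suite and the reproduction script.  Each experiment draws
many independent two-sample (or multi-study) datasets from the generator
and summarizes estimator behaviour across replicates: bias, CI coverage,
type-I error of the pleiotropy test, instrument-strength distributions.

Replicate seeds are derived deterministically from one base seed via
``numpy.random.SeedSequence``, so every experiment is reproducible from a
single integer.
"""

from __future__ import annotations

import dataclasses
import numpy as np
import pandas as pd

from .grs import WeightSet, compute_grs, instrument_strength
from .simulate import SimConfig, simulate_cohort, simulate_two_sample_summary
from .study_level import fit_study_assocs, meta_analyze, ratio_iv_estimate
from .summary_level import egger, ivw, median_estimators

__all__ = [
    "replicate_seeds",
    "two_sample_replicates",
    "full_chain_replicates",
    "instrument_strength_replicates",
]


def replicate_seeds(base_seed: int, n_reps: int) -> np.ndarray:
    """Deterministic per-replicate seeds (all < 2**31)."""
    state = np.random.SeedSequence(base_seed).generate_state(n_reps, dtype=np.uint32)
    return (state % (2**31)).astype(np.int64)


def two_sample_replicates(
    config: SimConfig,
    n_reps: int,
    base_seed: int,
    n_boot: int = 600,
    run_medians: bool = True,
    run_egger: bool = True,
) -> pd.DataFrame:
    """Summary-level estimator battery over ``n_reps`` independent draws.

    Returns one row per replicate with the IVW estimate/CI, median
    estimates (bootstrap SEs at ``n_boot`` draws), and the Egger slope and
    intercept with its test p-value.  All estimates are per 1-SD decrease
    in birth weight.
    """
    rows = []
    for rep, seed in enumerate(replicate_seeds(base_seed, n_reps)):
        cfg = dataclasses.replace(config, seed=int(seed))
        variants = simulate_two_sample_summary(cfg).variants
        e_ivw = ivw(variants)
        row = {
            "rep": rep,
            "ivw_beta": e_ivw.beta, "ivw_se": e_ivw.se,
            "ivw_ci_low": e_ivw.ci_low, "ivw_ci_high": e_ivw.ci_high,
        }
        if run_medians:
            for weighted, tag in ((False, "simple_median"), (True, "weighted_median")):
                est = median_estimators(variants, weighted=weighted,
                                        n_boot=n_boot, seed=int(seed) + 1)
                row.update({f"{tag}_beta": est.beta, f"{tag}_se": est.se,
                            f"{tag}_ci_low": est.ci_low, f"{tag}_ci_high": est.ci_high})
        if run_egger:
            e_eg = egger(variants)
            row.update({
                "egger_beta": e_eg.beta, "egger_se": e_eg.se,
                "egger_ci_low": e_eg.ci_low, "egger_ci_high": e_eg.ci_high,
                "egger_intercept": e_eg.intercept,
                "egger_intercept_se": e_eg.intercept_se,
                "egger_intercept_p": e_eg.intercept_p,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def full_chain_replicates(
    config: SimConfig,
    n_reps: int,
    base_seed: int,
    n_studies: int = 20,
    mean_study_n: int = 2500,
    adjust_covariates: bool = True,
) -> pd.DataFrame:
    """Study-level chain (simulate studies → fit → meta → ratio IV) over
    replicates; returns the per-replicate ratio estimates."""
    weights = WeightSet.from_config_betas(config)
    rows = []
    for rep, seed in enumerate(replicate_seeds(base_seed, n_reps)):
        rng = np.random.default_rng(int(seed))
        exp_assocs, out_assocs = [], []
        for s in range(n_studies):
            n = int(np.clip(rng.lognormal(np.log(mean_study_n), 0.3), 500, 20000))
            cohort = simulate_cohort(config, n, rng=rng)
            score = compute_grs(cohort, weights, orientation="bw_lowering")
            cov = cohort.covariates[["age", "sex"]] if adjust_covariates else None
            a = fit_study_assocs(cohort, score, covariates=cov,
                                 study_id=f"s{s}", sd_bw=config.sd_bw)
            exp_assocs.append(a[0])
            out_assocs.append(a[1])
        pooled_exp = meta_analyze(exp_assocs, model="random")
        pooled_out = meta_analyze(out_assocs, model="random")
        iv = ratio_iv_estimate(pooled_out, pooled_exp)
        rows.append({
            "rep": rep, "beta": iv.beta, "se": iv.se,
            "ci_low": iv.ci_low, "ci_high": iv.ci_high,
            "k_dropped": n_studies - pooled_out.k_studies,
            "i2_outcome": pooled_out.i2,
        })
    return pd.DataFrame(rows)


def instrument_strength_replicates(
    config: SimConfig,
    n: int,
    n_reps: int,
    base_seed: int,
) -> pd.DataFrame:
    """Distribution of the instrument F statistic across simulated cohorts
    of size ``n`` using the true-weight GRS."""
    weights = WeightSet.from_config_betas(config)
    rows = []
    for rep, seed in enumerate(replicate_seeds(base_seed, n_reps)):
        cohort = simulate_cohort(dataclasses.replace(config, seed=int(seed)), n)
        score = compute_grs(cohort, weights, orientation="bw_lowering")
        out = instrument_strength(cohort, score)
        rows.append({"rep": rep, "r2": out["r2"], "f_stat": out["f_stat"]})
    return pd.DataFrame(rows)
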
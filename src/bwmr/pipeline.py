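"""End-to-end orchestration: simulate → harmonize → estimate → report.

The pipeline reproduces the two-component design of the analysis:

* a *study-level* arm — many cohorts each contributing GRS→birth-weight
  and GRS→T2D coefficients, pooled by meta-analysis and combined into a
  ratio IV estimate, with stratified variants (age group, sex, ancestry,
  design, size);
* a *summary-level* arm — per-SNP two-sample summary statistics pushed
  through the IVW / median / MR-Egger battery.

Every report bundle contains a machine-readable ``results.json`` holding
every number that appears in the human-readable ``summary.txt``, plus
delimited tables and a structured log of counts in/out at each stage.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import grs as grs_mod
from . import summary_level
from .risk import RiskContext, ari_per_1000
from .simulate import (
    SimConfig,
    forty_three_snp_config,
    simulate_cohort,
    simulate_two_sample_summary,
)
from .study_level import MetaResult, fit_study_assocs, forest_table, meta_analyze, ratio_iv_estimate
from .summary_io import (
    StudyAssoc,
    harmonize,
    read_study_assocs,
    read_summary_table,
    write_study_assocs,
    write_summary_table,
)

__all__ = ["RunConfig", "run", "simulate_study_system", "DEFAULT_STRATA"]

log = logging.getLogger("bwmr")

#: stratification used for the stratified-causality table
DEFAULT_STRATA: dict[str, dict] = {
    "all": {},
    "age_ge_50": {"age_group": ">=50"},
    "age_lt_50": {"age_group": "<50"},
    "male": {"sex_group": "male"},
    "female": {"sex_group": "female"},
    "european": {"ancestry": "European"},
    "east_asian": {"ancestry": "East Asian"},
    "cohort_design": {"design": "cohort"},
    "case_control_design": {"design": "case-control"},
    "n_ge_1500": {"min_n": 1500},
    "n_lt_1500": {"max_n": 1499},
}


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    mode: str = "full"  # study_level | summary_level | simulate | full
    outdir: str | Path = "bwmr_out"
    seed: int | None = None
    methods: tuple[str, ...] = ("simple_median", "weighted_median", "ivw", "egger")
    sd_bw: float = 543.0
    baseline_incidence: float | None = 5.0  # events per 1000 participant-years
    n_boot: int = 10_000
    se_model: str = "multiplicative"
    exclude_rsids: tuple[str, ...] = ()
    # inputs for data-driven modes
    exposure_path: str | None = None
    outcome_path: str | None = None
    study_table_path: str | None = None
    sim_config_path: str | None = None
    outcome_binary: bool = True
    # simulation sizes for simulate/full modes
    n_studies: int = 20
    strata: Mapping[str, dict] = field(default_factory=lambda: dict(DEFAULT_STRATA))

    def __post_init__(self) -> None:
        if self.mode not in ("study_level", "summary_level", "simulate", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.methods:
            raise ValueError("empty method list")
        stochastic = self.mode in ("simulate", "full") or (
            "simple_median" in self.methods or "weighted_median" in self.methods
        )
        if stochastic and self.seed is None:
            raise ValueError("seed is required when any stochastic step is enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("methods", "exclude_rsids"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _match_stratum(assoc: StudyAssoc, rule: Mapping[str, object]) -> bool:
    for key, want in rule.items():
        if key == "min_n":
            if assoc.n < int(want):
                return False
        elif key == "max_n":
            if assoc.n > int(want):
                return False
        elif key in ("ancestry", "design"):
            if getattr(assoc, key) != want:
                return False
        else:
            if assoc.meta.get(key) != want:
                return False
    return True


def simulate_study_system(
    config: SimConfig,
    n_studies: int = 20,
    mean_study_n: int = 3000,
    rng: np.random.Generator | None = None,
) -> list[StudyAssoc]:
    """Simulate a multi-cohort study system and fit per-study models.

    Each study draws its own cohort from the shared generating process
    (sizes log-normal around ``mean_study_n``), computes the weighted GRS
    from the true per-allele weights, and contributes the three standard
    association estimates tagged with stratification metadata (age group,
    sex mix, ancestry, design).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = grs_mod.WeightSet.from_config_betas(config)
    designs = ["cohort"] * 6 + ["case-control", "cross-sectional"]
    assocs: list[StudyAssoc] = []
    for s in range(n_studies):
        n = int(np.clip(rng.lognormal(math.log(mean_study_n), 0.4), 300, 20000))
        cohort = simulate_cohort(config, n, rng=rng)
        score = grs_mod.compute_grs(cohort, weights, orientation="bw_lowering")
        meta = {
            "age_group": ">=50" if s % 4 else "<50",
            "sex_group": ["male", "female", "mixed"][s % 3],
        }
        assocs.extend(
            fit_study_assocs(
                cohort,
                score,
                covariates=cohort.covariates[["age", "sex", "pc1", "pc2", "pc3"]],
                study_id=f"study_{s + 1:02d}",
                sd_bw=config.sd_bw,
                ancestry="East Asian" if s % 7 == 0 else "European",
                design=designs[s % len(designs)],
                meta=meta,
            )
        )
    return assocs


def _meta_result_dict(m: MetaResult) -> dict:
    return {
        "beta": m.beta, "se": m.se, "ci_low": m.ci_low, "ci_high": m.ci_high,
        "p": m.p, "q": m.q, "df": m.df, "i2": m.i2, "tau2": m.tau2,
        "model": m.model, "k_studies": m.k_studies,
    }


def _estimate_dict(e) -> dict:
    d = {
        "method": e.method, "beta": e.beta, "se": e.se,
        "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p, "n_snps": e.n_snps,
    }
    for k in ("or_", "or_ci_low", "or_ci_high", "intercept", "intercept_se", "intercept_p"):
        v = getattr(e, k)
        if v is not None:
            d[k] = v
    return d


def _study_level_analysis(
    assocs: Sequence[StudyAssoc],
    strata: Mapping[str, dict],
    outdir: Path,
    risk: RiskContext,
) -> dict:
    results: dict = {"strata": {}}
    rows = []
    for name, rule in strata.items():
        exp = [a for a in assocs if a.assoc_kind == "grs_on_exposure" and _match_stratum(a, rule)]
        out = [a for a in assocs if a.assoc_kind == "grs_on_outcome" and _match_stratum(a, rule)]
        if not exp or not out:
            log.info("stratum=%s skipped (no studies)", name)
            continue
        try:
            pooled_exp = meta_analyze(exp, model="random")
            pooled_out = meta_analyze(out, model="random")
            iv = ratio_iv_estimate(pooled_out, pooled_exp)
        except ValueError as exc:
            log.warning("stratum=%s failed: %s — skipped", name, exc)
            results["strata"][name] = {"error": str(exc)}
            continue
        entry = {
            "grs_on_exposure": _meta_result_dict(pooled_exp),
            "grs_on_outcome": _meta_result_dict(pooled_out),
            "ratio_iv": _estimate_dict(iv),
        }
        if risk.baseline_incidence is not None and iv.or_ is not None:
            entry["ari_per_1000"] = ari_per_1000(iv.or_, risk)
        results["strata"][name] = entry
        rows.append({
            "stratum": name,
            "k_exposure_studies": pooled_exp.k_studies,
            "beta_grs_bw": pooled_exp.beta, "beta_grs_bw_se": pooled_exp.se,
            "k_outcome_studies": pooled_out.k_studies,
            "beta_grs_t2d": pooled_out.beta, "beta_grs_t2d_se": pooled_out.se,
            "or_per_sd_decrease": iv.or_,
            "or_ci_low": iv.or_ci_low, "or_ci_high": iv.or_ci_high, "p": iv.p,
        })
        log.info("stratum=%s k_exp=%d k_out=%d OR=%.3f", name,
                 pooled_exp.k_studies, pooled_out.k_studies, iv.or_ or float("nan"))
    pd.DataFrame(rows).to_csv(outdir / "stratified_causality.tsv", sep="\t", index=False)

    all_exp = [a for a in assocs if a.assoc_kind == "grs_on_exposure"]
    all_out = [a for a in assocs if a.assoc_kind == "grs_on_outcome"]
    if all_exp and all_out:
        forest_table(all_exp, meta_analyze(all_exp)).to_csv(
            outdir / "forest_grs_birthweight.tsv", sep="\t", index=False)
        forest_table(all_out, meta_analyze(all_out)).to_csv(
            outdir / "forest_grs_t2d.tsv", sep="\t", index=False)
    dropped = [a for a in assocs if not a.usable()]
    results["n_assocs"] = len(assocs)
    results["n_flagged_assocs"] = len(dropped)
    log.info("study-level: %d assocs in, %d flagged", len(assocs), len(dropped))
    return results


def _summary_level_analysis(
    variants,
    cfg: RunConfig,
    outdir: Path,
    risk: RiskContext,
    dropped: Sequence[tuple[str, str]] = (),
) -> dict:
    method_runs: dict = {}
    available = {
        "simple_median": lambda v: summary_level.median_estimators(
            v, weighted=False, n_boot=cfg.n_boot, seed=cfg.seed),
        "weighted_median": lambda v: summary_level.median_estimators(
            v, weighted=True, n_boot=cfg.n_boot, seed=cfg.seed),
        "ivw": lambda v: summary_level.ivw(v, se_model=cfg.se_model),
        "egger": lambda v: summary_level.egger(v, se_model=cfg.se_model),
    }
    unknown = [m for m in cfg.methods if m not in available]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; choose from {sorted(available)}")
    for m in cfg.methods:
        est = available[m](variants)
        method_runs[m] = _estimate_dict(est)
        if m == "ivw" and risk.baseline_incidence is not None and est.or_ is not None:
            method_runs[m]["ari_per_1000"] = ari_per_1000(est.or_, risk)
        log.info("method=%s beta=%.4f se=%.4f p=%.3g", m, est.beta, est.se, est.p)
    results = {"methods": method_runs, "n_snps": len(variants),
               "harmonization_dropped": list(map(list, dropped))}
    if cfg.exclude_rsids:
        lo = summary_level.leave_loci_out(variants, cfg.exclude_rsids,
                                          se_model=cfg.se_model)
        results["leave_loci_out"] = {
            "excluded": list(lo.excluded),
            "full": _estimate_dict(lo.full),
            "reduced": _estimate_dict(lo.reduced),
        }
    pd.DataFrame(method_runs.values()).to_csv(
        outdir / "mr_estimates.tsv", sep="\t", index=False)
    with open(outdir / "harmonization_log.tsv", "w") as fh:
        fh.write("rsid\treason\n")
        for rsid, reason in dropped:
            fh.write(f"{rsid}\t{reason}\n")
    return results


def _diagnostics(config: SimConfig, rng: np.random.Generator, outdir: Path) -> dict:
    cohort = simulate_cohort(config, 5000, rng=rng)
    weights = grs_mod.WeightSet.from_config_betas(config)
    score = grs_mod.compute_grs(cohort, weights, orientation="bw_lowering")
    strength = grs_mod.instrument_strength(
        cohort, score, covariates=cohort.covariates[["age", "sex", "pc1", "pc2", "pc3"]])
    screen = grs_mod.confounder_screen(
        score, cohort.covariates[["age", "pc1", "pc2", "pc3"]])
    screen.to_csv(outdir / "confounder_screen.tsv", sep="\t", index=False)
    ld = grs_mod.pairwise_r2(cohort)
    off = ld.to_numpy()[~np.eye(len(ld), dtype=bool)]
    max_r2 = float(off.max()) if off.size else 0.0
    diag = {
        "f_stat": strength["f_stat"],
        "r2": strength["r2"],
        "n": strength["n"],
        "max_pairwise_r2": max_r2,
        "ld_threshold": 0.05,
        "ld_check_pass": bool(max_r2 <= 0.05),
        "confounder_screen_min_p": float(screen["p"].min()),
    }
    log.info("diagnostics: F=%.1f r2=%.4f max pairwise r2=%.4f",
             diag["f_stat"], diag["r2"], max_r2)
    return diag


def _render_summary(results: dict, path: Path) -> None:
    lines = ["bwmr run summary", "================", ""]
    sl = results.get("summary_level")
    if sl:
        lines.append(f"Two-sample MR on {sl['n_snps']} SNPs "
                     f"(per 1-SD decrease in birth weight):")
        for name, est in sl["methods"].items():
            if "or_" in est:
                lines.append(
                    f"  {name:16s} OR {est['or_']:.2f} "
                    f"({est['or_ci_low']:.2f} to {est['or_ci_high']:.2f}), p={est['p']:.3g}")
            else:
                lines.append(
                    f"  {name:16s} beta {est['beta']:.3f} (SE {est['se']:.3f}), "
                    f"p={est['p']:.3g}")
            if est.get("intercept") is not None:
                lines.append(
                    f"  {'egger intercept':16s} {est['intercept']:.4f} "
                    f"(SE {est['intercept_se']:.4f}), p={est['intercept_p']:.3g}")
            if est.get("ari_per_1000") is not None:
                lines.append(
                    f"  {'ARI/1000 p-y':16s} {est['ari_per_1000']:.2f} "
                    f"(baseline {results['risk']['baseline_incidence']}, "
                    f"formula {results['risk']['ari_formula']})")
        if "leave_loci_out" in sl:
            red = sl["leave_loci_out"]["reduced"]
            lines.append(f"  leave-loci-out IVW on {red['n_snps']} SNPs: "
                         f"beta {red['beta']:.3f} (p={red['p']:.3g})")
        lines.append("")
    st = results.get("study_level")
    if st:
        lines.append(f"Study-level arm ({st['n_assocs']} association records, "
                     f"{st['n_flagged_assocs']} flagged):")
        for name, entry in st["strata"].items():
            if "error" in entry:
                lines.append(f"  {name:20s} skipped: {entry['error']}")
                continue
            iv = entry["ratio_iv"]
            ari = entry.get("ari_per_1000")
            ari_txt = f", ARI/1000 p-y {ari:.2f}" if ari is not None else ""
            lines.append(
                f"  {name:20s} OR {iv['or_']:.2f} ({iv['or_ci_low']:.2f} to "
                f"{iv['or_ci_high']:.2f}), p={iv['p']:.3g}{ari_txt}")
        lines.append("")
    dg = results.get("diagnostics")
    if dg:
        lines.append("Diagnostics:")
        lines.append(f"  instrument F = {dg['f_stat']:.1f} (strong if > 10), "
                     f"R² = {dg['r2']:.4f} at n = {dg['n']:.0f}")
        lines.append(f"  max pairwise instrument r² = {dg['max_pairwise_r2']:.4f} "
                     f"(threshold {dg['ld_threshold']}): "
                     f"{'pass' if dg['ld_check_pass'] else 'FAIL'}")
        lines.append(f"  confounder screen min p = {dg['confounder_screen_min_p']:.3f}")
    path.write_text("\n".join(lines) + "\n")


def run(config: RunConfig) -> dict:
    """Execute the configured pipeline and write the report bundle.

    Returns the machine-readable results dict (also written as
    ``results.json``).  A failing stratum is reported and skipped; I/O
    errors abort.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    risk = RiskContext(sd_bw=config.sd_bw, baseline_incidence=config.baseline_incidence)
    results: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "risk": {
            "sd_bw": risk.sd_bw,
            "baseline_incidence": risk.baseline_incidence,
            "ari_formula": "baseline_incidence * (OR - 1)  [rare-outcome RR≈OR]",
        },
    }

    sim_config: SimConfig | None = None
    if config.sim_config_path:
        sim_config = SimConfig.from_yaml(config.sim_config_path)
    elif config.mode in ("simulate", "full"):
        sim_config = forty_three_snp_config(seed=config.seed)

    if config.mode in ("simulate", "full") and sim_config is not None:
        sim_config = replace(sim_config, seed=config.seed)
        two = simulate_two_sample_summary(sim_config)
        write_summary_table(two.exposure, outdir / "exposure_summary.tsv")
        write_summary_table(two.outcome, outdir / "outcome_summary.tsv")
        log.info("simulated two-sample summary: %d SNPs", len(two.variants))
        if config.mode == "simulate":
            cohort = simulate_cohort(sim_config, 2000)
            cohort.write_tsv(outdir / "cohort.tsv")
            results["simulate"] = {
                "n_snps": sim_config.n_snps,
                "n_variants_harmonized": len(two.variants),
                "cohort_n": cohort.n,
            }
        variants = two.variants
        dropped: list[tuple[str, str]] = []
    elif config.mode == "summary_level":
        if not (config.exposure_path and config.outcome_path):
            raise ValueError("summary_level mode needs exposure_path and outcome_path")
        exp = read_summary_table(config.exposure_path)
        out = read_summary_table(config.outcome_path)
        log.info("read %d exposure (%d rejected), %d outcome (%d rejected) records",
                 len(exp), len(exp.rejected), len(out), len(out.rejected))
        rep = harmonize(exp.records, out.records,
                        outcome_type="binary" if config.outcome_binary else "quantitative")
        log.info("harmonized %d SNPs, dropped %d", len(rep.variants), len(rep.dropped))
        variants, dropped = rep.variants, rep.dropped
    else:
        variants, dropped = [], []

    if config.mode in ("summary_level", "full") and variants:
        results["summary_level"] = _summary_level_analysis(
            variants, config, outdir, risk, dropped)

    if config.mode in ("study_level", "full"):
        if config.mode == "study_level":
            if not config.study_table_path:
                raise ValueError("study_level mode needs study_table_path")
            assocs = read_study_assocs(config.study_table_path)
        else:
            rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 17]))
            assocs = simulate_study_system(sim_config, n_studies=config.n_studies, rng=rng)
            write_study_assocs(assocs, outdir / "study_assocs.tsv")
        results["study_level"] = _study_level_analysis(
            assocs, config.strata, outdir, risk)

    if config.mode == "full" and sim_config is not None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 23]))
        results["diagnostics"] = _diagnostics(sim_config, rng, outdir)

    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    _render_summary(results, outdir / "summary.txt")
    log.info("report bundle written to %s", outdir)
    return results
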
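"""Synthetic cohorts and two-sample summary statistics.

The generator emulates the data-generating process a birth-weight MR study
assumes:

* independent biallelic SNPs, genotypes ``Binomial(2, eaf)`` (the real
  instruments are screened for pairwise LD r² ≤ 0.05, so independence is
  the intended structure, not a shortcut);
* birth weight (grams) = Σⱼ βⱼ·gⱼ + confounder effect + Gaussian noise,
  with the per-allele effects rescaled by a common factor so the
  instrument explains exactly ``target_r2`` of the birth-weight variance
  and the total variance equals ``sd_bw²``;
* type 2 diabetes from a logistic model whose linear predictor contains
  the causal term ``theta`` per 1-SD *decrease* in birth weight, optional
  direct SNP effects (pleiotropy), and a direct confounder term; the
  intercept is solved numerically so the marginal prevalence matches
  ``baseline_prevalence``;
* an optional quantitative glycemic trait with the same causal structure
  on a linear scale.

Two-sample summary statistics are produced by actually drawing two
independent cohorts and fitting single-SNP regressions in each — linear
for the exposure, logistic for the case/control outcome (cases oversampled
from a large population draw, which leaves the log-OR estimand intact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .summary_io import SummaryRecord, InstrumentVariant, harmonize

__all__ = [
    "SimConfig",
    "CohortDataset",
    "TwoSampleSummary",
    "seven_snp_config",
    "forty_three_snp_config",
    "simulate_cohort",
    "simulate_two_sample_summary",
]

# non-palindromic allele pairs cycled across SNPs
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated study system.

    ``beta_bw`` holds per-allele birth-weight effects in grams whose
    *relative* sizes are kept; a common rescaling factor (see
    :meth:`scaled_betas`) maps them onto ``target_r2``.  ``theta`` is the
    causal log-OR of T2D per 1-SD decrease in birth weight.
    """

    eaf: tuple[float, ...]
    beta_bw: tuple[float, ...]  # grams per effect allele, before rescaling
    target_r2: float = 0.02
    sd_bw: float = 543.0  # grams per SD of birth weight
    mean_bw: float = 3500.0  # grams
    theta: float = 0.7  # log-OR of T2D per 1-SD decrease in birth weight
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0  # SD of direct SNP->outcome log-OR
    pleiotropy_mean: float = 0.02  # mean direct effect (directional mode)
    pleiotropy_frac: float = 1.0  # fraction of SNPs with direct effects
    confounder_effect_bw: float = 80.0  # grams per confounder SD
    confounder_effect_t2d: float = 0.1  # log-OR per confounder SD
    baseline_prevalence: float = 0.08
    n_exposure_sample: int = 50_000
    n_outcome_cases: int = 10_000
    n_outcome_controls: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        eaf = np.asarray(self.eaf, dtype=float)
        beta = np.asarray(self.beta_bw, dtype=float)
        if eaf.ndim != 1 or beta.shape != eaf.shape or eaf.size == 0:
            raise ValueError("eaf and beta_bw must be equal-length non-empty vectors")
        if np.any(eaf <= 0) or np.any(eaf >= 1):
            raise ValueError("all effect-allele frequencies must lie strictly in (0,1)")
        if not np.all(np.isfinite(beta)):
            raise ValueError("beta_bw must be finite")
        if not 0 < self.target_r2 < 1:
            raise ValueError("target_r2 must lie in (0,1)")
        if self.sd_bw <= 0:
            raise ValueError("sd_bw must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0 <= self.pleiotropy_frac <= 1:
            raise ValueError("pleiotropy_frac must lie in [0,1]")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must lie in (0,1)")
        max_r2 = 1.0 - (self.confounder_effect_bw / self.sd_bw) ** 2
        if self.target_r2 >= max_r2:
            raise ValueError(
                f"target_r2={self.target_r2} infeasible: genetic plus confounder "
                f"variance would exceed sd_bw²; with confounder_effect_bw="
                f"{self.confounder_effect_bw} g the bound is target_r2 < {max_r2:.4f}"
            )

    @property
    def n_snps(self) -> int:
        return len(self.eaf)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(f"rs{1000001 + j}" for j in range(self.n_snps))

    @property
    def alleles(self) -> tuple[tuple[str, str], ...]:
        return tuple(_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(self.n_snps))

    def scaled_betas(self) -> tuple[np.ndarray, float]:
        """Per-allele effects (grams) rescaled so the instrument explains
        ``target_r2`` of ``sd_bw²``; returns (betas, rescaling factor)."""
        eaf = np.asarray(self.eaf)
        beta = np.asarray(self.beta_bw, dtype=float)
        raw_var = float(np.sum(beta**2 * 2 * eaf * (1 - eaf)))
        if raw_var <= 0:
            raise ValueError("beta_bw is identically zero; cannot rescale to target_r2")
        scale = math.sqrt(self.target_r2 * self.sd_bw**2 / raw_var)
        return beta * scale, scale

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["eaf"] = list(self.eaf)
        d["beta_bw"] = list(self.beta_bw)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["eaf"] = tuple(d["eaf"])
        d["beta_bw"] = tuple(d["beta_bw"])
        return cls(**d)


def _default_snp_panel(n_snps: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Deterministic EAFs and raw per-allele effects for a panel.

    Frequencies sweep the common range 0.15–0.85; raw effects fall off like
    a ranked GWAS hit list (largest ≈ 35 g, tail ≈ 10 g).  All effect
    alleles are taken as the birth-weight-raising alleles, the usual GWAS
    orientation.  Absolute sizes are irrelevant — they are rescaled to the
    configured instrument R².
    """
    j = np.arange(n_snps)
    eaf = 0.15 + 0.7 * ((j * 7 + 3) % n_snps + 0.5) / n_snps
    beta = 35.0 * (1.0 + j) ** (-0.35)
    beta = np.maximum(beta, 10.0)
    return (
        tuple(float(x) for x in np.round(eaf, 4)),
        tuple(float(x) for x in np.round(beta, 3)),
    )


def seven_snp_config(**overrides) -> SimConfig:
    """The primary instrument: 7 genome-wide-significant SNPs explaining
    1.52 % of birth-weight variance (upper end of the reported range)."""
    eaf, beta = _default_snp_panel(7)
    defaults = dict(eaf=eaf, beta_bw=beta, target_r2=0.0152)
    defaults.update(overrides)
    return SimConfig(**defaults)


def forty_three_snp_config(**overrides) -> SimConfig:
    """The extended instrument: 43 SNPs explaining 2.0 % of variance."""
    eaf, beta = _default_snp_panel(43)
    defaults = dict(eaf=eaf, beta_bw=beta, target_r2=0.02)
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class CohortDataset:
    """Individual-level data for one simulated study."""

    snp_ids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    other_alleles: tuple[str, ...]
    eaf: np.ndarray  # configured frequencies, per SNP
    genotypes: np.ndarray  # (n, m) effect-allele counts in {0,1,2}
    birth_weight: np.ndarray  # grams
    t2d_status: np.ndarray  # {0,1}
    glycemic_trait: np.ndarray | None
    confounder: np.ndarray  # SD units
    covariates: pd.DataFrame  # age, sex, pc1..pc3
    weight_scale: float  # rescaling factor applied to beta_bw
    per_allele_beta: np.ndarray  # realized per-allele effects (grams)

    @property
    def n(self) -> int:
        return len(self.birth_weight)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes, columns=list(self.snp_ids))
        df.insert(0, "birth_weight", self.birth_weight)
        df.insert(1, "t2d_status", self.t2d_status)
        if self.glycemic_trait is not None:
            df.insert(2, "glycemic_trait", self.glycemic_trait)
        df["confounder"] = self.confounder
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _draw_direct_effects(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Direct SNP→outcome log-OR effects γⱼ under the configured mode."""
    m = config.n_snps
    if config.pleiotropy_mode == "none":
        return np.zeros(m)
    k = int(round(config.pleiotropy_frac * m))
    idx = rng.choice(m, size=k, replace=False)
    gamma = np.zeros(m)
    if config.pleiotropy_mode == "balanced":
        gamma[idx] = rng.normal(0.0, config.pleiotropy_sd, size=k)
    else:  # directional
        gamma[idx] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k)
    return gamma


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept α with mean(expit(α + eta)) = prevalence on this sample."""

    def f(a: float) -> float:
        return float(np.mean(expit(a + eta))) - prevalence

    return brentq(f, -40.0, 40.0, xtol=1e-10)


def _simulate_population(
    config: SimConfig,
    n: int,
    rng: np.random.Generator,
    gamma: np.ndarray | None = None,
    glycemic: bool = False,
) -> CohortDataset:
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    eaf = np.asarray(config.eaf)
    m = config.n_snps
    beta, scale = config.scaled_betas()

    genotypes = rng.binomial(2, eaf, size=(n, m)).astype(np.int8)
    confounder = rng.standard_normal(n)
    gen_var = config.target_r2 * config.sd_bw**2
    env_var = config.sd_bw**2 - gen_var - config.confounder_effect_bw**2
    g = genotypes.astype(np.float64)
    genetic = g @ beta
    birth_weight = (
        config.mean_bw
        + genetic
        - float(2 * eaf @ beta)  # center at the expected genotype
        + config.confounder_effect_bw * confounder
        + rng.normal(0.0, math.sqrt(env_var), size=n)
    )

    bw_sd_units = (birth_weight - config.mean_bw) / config.sd_bw
    if gamma is None:
        gamma = _draw_direct_effects(config, rng)
    eta = config.theta * (-bw_sd_units) + g @ gamma + config.confounder_effect_t2d * confounder
    alpha = _solve_intercept(eta, config.baseline_prevalence)
    t2d = (rng.random(n) < expit(alpha + eta)).astype(np.int8)

    glyc = None
    if glycemic:
        # same causal structure on a linear scale; trait in SD units
        direct = g @ gamma
        signal_var = float(np.var(config.theta * (-bw_sd_units) + direct))
        resid = max(1.0 - signal_var, 0.05)
        glyc = (
            config.theta * (-bw_sd_units)
            + direct
            + rng.normal(0.0, math.sqrt(resid), size=n)
        )

    covariates = pd.DataFrame(
        {
            "age": rng.normal(55.0, 8.0, size=n),
            "sex": rng.integers(0, 2, size=n).astype(np.int8),
            "pc1": rng.standard_normal(n),
            "pc2": rng.standard_normal(n),
            "pc3": rng.standard_normal(n),
        }
    )
    ea = [a for a, _ in config.alleles]
    oa = [b for _, b in config.alleles]
    return CohortDataset(
        snp_ids=config.snp_ids,
        effect_alleles=tuple(ea),
        other_alleles=tuple(oa),
        eaf=eaf.copy(),
        genotypes=genotypes,
        birth_weight=birth_weight,
        t2d_status=t2d,
        glycemic_trait=glyc,
        confounder=confounder,
        covariates=covariates,
        weight_scale=scale,
        per_allele_beta=beta,
    )


def simulate_cohort(
    config: SimConfig, n: int, rng: np.random.Generator | None = None
) -> CohortDataset:
    """Simulate one individual-level cohort of ``n`` participants.

    Genotypes are independent ``Binomial(2, eaf)`` draws; birth weight has
    total variance ``sd_bw²`` with the instrument contributing exactly
    ``target_r2`` of it in expectation; T2D follows the logistic model with
    the intercept solved so the sample prevalence matches
    ``baseline_prevalence``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _simulate_population(config, n, rng, glycemic=True)


# -- two-sample summary statistics ------------------------------------------


def _single_snp_linear(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple linear regressions of y on each genotype column.

    Returns (beta, se, monomorphic mask); vectorized across SNPs.
    """
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    mono = sxx <= 0
    sxx_safe = np.where(mono, np.nan, sxx)
    sxy = gc.T @ yc
    beta = sxy / sxx_safe
    syy = float(yc @ yc)
    sse = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(sse / (n - 2) / sxx_safe)
    return beta, se, mono


def _single_snp_logistic(
    g: np.ndarray, d: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column logistic regressions (intercept + genotype), vectorized
    Newton–Raphson across SNPs.  Returns (beta, se, failed mask)."""
    n, m = g.shape
    a = np.full(m, float(np.log(d.mean() / (1 - d.mean()))))
    b = np.zeros(m)
    failed = np.zeros(m, dtype=bool)
    mono = g.std(axis=0) <= 0
    failed |= mono
    dcol = d[:, None]
    for _ in range(max_iter):
        eta = a[None, :] + g * b[None, :]
        p = expit(eta)
        w = p * (1 - p)
        r = dcol - p
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", g, r)
        s00 = w.sum(axis=0)
        s01 = np.einsum("ij,ij->j", g, w)
        s11 = np.einsum("ij,ij,ij->j", g, g, w)
        det = s00 * s11 - s01 * s01
        det = np.where(det <= 0, np.nan, det)
        da = (s11 * g0 - s01 * g1) / det
        db = (-s01 * g0 + s00 * g1) / det
        da = np.clip(np.nan_to_num(da), -5, 5)
        db = np.clip(np.nan_to_num(db), -5, 5)
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < tol:
            break
    else:
        conv = np.maximum(np.abs(da), np.abs(db)) < 1e-4
        failed |= ~conv
    eta = a[None, :] + g * b[None, :]
    p = expit(eta)
    w = p * (1 - p)
    s00 = w.sum(axis=0)
    s01 = np.einsum("ij,ij->j", g, w)
    s11 = np.einsum("ij,ij,ij->j", g, g, w)
    det = s00 * s11 - s01 * s01
    se = np.sqrt(np.where(det > 0, s00 / det, np.nan))
    failed |= ~np.isfinite(se)
    return b, se, failed


@dataclass
class TwoSampleSummary:
    """Exposure-side and outcome-side summary tables from two independent
    simulated cohorts, plus their harmonized join."""

    exposure: list[SummaryRecord]
    outcome: list[SummaryRecord]
    variants: list[InstrumentVariant] = field(default_factory=list)
    outcome_type: str = "binary"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.variants:
            report = harmonize(
                [r for r in self.exposure if r.flag != "monomorphic"],
                [r for r in self.outcome if r.flag != "monomorphic"],
                outcome_type=self.outcome_type,
            )
            self.variants = report.variants

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def simulate_two_sample_summary(
    config: SimConfig, outcome: str = "t2d"
) -> TwoSampleSummary:
    """Draw an exposure GWAS cohort and an independent outcome cohort and
    fit single-SNP regressions in each.

    The exposure side regresses birth weight *in SD units* on each genotype
    (linear).  For ``outcome="t2d"`` the outcome side oversamples cases from
    a large population draw to the configured case/control counts and fits
    single-SNP logistic regressions (log-OR per allele); case-control
    retention sampling leaves the log-OR consistent.  For
    ``outcome="glycemic"`` a quantitative trait is analysed linearly on
    ``n_outcome_cases + n_outcome_controls`` individuals.

    Monomorphic SNPs are flagged, never silently dropped.
    """
    if config.n_exposure_sample < 2:
        raise ValueError("n_exposure_sample must be >= 2")
    if outcome not in ("t2d", "glycemic"):
        raise ValueError(f"unknown outcome {outcome!r}")
    root = np.random.SeedSequence(config.seed)
    exp_rng, out_rng, gamma_rng = (np.random.default_rng(s) for s in root.spawn(3))

    # direct effects are a property of the SNPs, shared across cohorts
    gamma = _draw_direct_effects(config, gamma_rng)

    exp_cohort = _simulate_population(config, config.n_exposure_sample, exp_rng, gamma=gamma)
    g = exp_cohort.genotypes.astype(np.float64)
    bw_sd = (exp_cohort.birth_weight - config.mean_bw) / config.sd_bw
    bx, sx, mono_x = _single_snp_linear(g, bw_sd)

    if outcome == "t2d":
        n_cases, n_controls = config.n_outcome_cases, config.n_outcome_controls
        if n_cases < 1 or n_controls < 1:
            raise ValueError("n_outcome_cases and n_outcome_controls must be >= 1")
        prev = config.baseline_prevalence
        n_pop = int(math.ceil(max(n_cases / prev, n_controls / (1 - prev)) * 1.25))
        pop = _simulate_population(config, n_pop, out_rng, gamma=gamma)
        case_idx = np.flatnonzero(pop.t2d_status == 1)
        ctrl_idx = np.flatnonzero(pop.t2d_status == 0)
        if len(case_idx) < n_cases or len(ctrl_idx) < n_controls:
            raise RuntimeError(
                f"population draw of {n_pop} yielded {len(case_idx)} cases / "
                f"{len(ctrl_idx)} controls; increase the draw or prevalence"
            )
        keep = np.concatenate([case_idx[:n_cases], ctrl_idx[:n_controls]])
        go = pop.genotypes[keep].astype(np.float64)
        do = pop.t2d_status[keep].astype(np.float64)
        by, sy, fail_y = _single_snp_logistic(go, do)
        n_out = n_cases + n_controls
        eaf_out = go.mean(axis=0) / 2
    else:
        n_out = config.n_outcome_cases + config.n_outcome_controls
        pop = _simulate_population(config, n_out, out_rng, gamma=gamma, glycemic=True)
        go = pop.genotypes.astype(np.float64)
        by, sy, fail_y = _single_snp_linear(go, pop.glycemic_trait)
        eaf_out = go.mean(axis=0) / 2

    eaf_exp = g.mean(axis=0) / 2
    exposure, outcome_recs = [], []
    for j in range(config.n_snps):
        ea, oa = config.alleles[j]
        rsid = config.snp_ids[j]
        exposure.append(
            SummaryRecord(
                rsid, ea, oa, float(eaf_exp[j]),
                float(bx[j]) if not mono_x[j] else float("nan"),
                float(sx[j]) if not mono_x[j] else float("nan"),
                config.n_exposure_sample,
                flag="monomorphic" if mono_x[j] else None,
            )
        )
        bad = bool(fail_y[j])
        outcome_recs.append(
            SummaryRecord(
                rsid, ea, oa, float(eaf_out[j]),
                float(by[j]) if not bad else float("nan"),
                float(sy[j]) if not bad else float("nan"),
                n_out,
                flag="monomorphic" if bad else None,
            )
        )
    return TwoSampleSummary(
        exposure=exposure,
        outcome=outcome_recs,
        outcome_type="binary" if outcome == "t2d" else "quantitative",
        meta={"weight_scale": exp_cohort.weight_scale, "gamma": gamma},
    )
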
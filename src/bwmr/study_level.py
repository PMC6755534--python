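"""Study-level arm: per-study association models, meta-analysis, ratio IV.

Mirrors the multi-cohort design: each study fits (i) a linear model of
birth weight (SD units) on the GRS, (ii) a logistic model of T2D on the
GRS, and (iii) an observational logistic model of T2D on birth weight,
each adjusted for covariates.  The per-study coefficients are pooled by
fixed- or random-effects (DerSimonian–Laird) meta-analysis, and the causal
effect is the ratio of the pooled GRS→T2D and GRS→birth-weight
coefficients with a first-order delta-method standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .risk import BIRTH_WEIGHT_SD_GRAMS
from .simulate import CohortDataset
from .summary_io import StudyAssoc

__all__ = [
    "MetaResult",
    "MrEstimate",
    "fit_study_assocs",
    "meta_analyze",
    "ratio_iv_estimate",
    "forest_table",
]

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with heterogeneity statistics."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    df: int
    i2: float  # percentage in [0, 100]
    tau2: float
    model: str  # fixed | random
    k_studies: int
    flag: str | None = None


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate from one MR method.

    ``beta`` is on the log-OR scale for binary outcomes (per 1-SD decrease
    in birth weight under the package's reporting convention) or in SD of
    the trait for quantitative outcomes.  ``or_`` is present only for
    binary outcomes.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    or_: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def _or_fields(beta: float, se: float) -> dict[str, float]:
    return {
        "or_": math.exp(beta),
        "or_ci_low": math.exp(beta - Z95 * se),
        "or_ci_high": math.exp(beta + Z95 * se),
    }


def _logit_coef(y, X, name_idx: int):
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence issues become flags
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            return None, None, "non-convergence"
        se = float(fit.bse[name_idx])
        if not np.isfinite(se) or se > 50:
            return None, None, "unstable fit (separation?)"
        return float(fit.params[name_idx]), se, None
    except Exception as exc:  # perfect separation, singular matrix, ...
        return None, None, f"fit failed: {type(exc).__name__}"


def fit_study_assocs(
    cohort: CohortDataset,
    grs: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    study_id: str = "study",
    sd_bw: float = BIRTH_WEIGHT_SD_GRAMS,
    grs_orientation: str = "bw_lowering",
    ancestry: str = "European",
    design: str = "cohort",
    meta: dict | None = None,
) -> list[StudyAssoc]:
    """Fit the three per-study association models.

    With a birth-weight-lowering score (``grs_orientation="bw_lowering"``,
    the default) birth weight enters the regressions as an SD *deficit*
    (−BW/sd), so the GRS→exposure coefficient is positive and the ratio of
    pooled coefficients reads directly as an effect per 1-SD decrease in
    birth weight.  The observational model uses the same deficit scale
    (log-OR per 1-SD-lower birth weight).

    Non-converging logistic fits yield flagged records with missing beta —
    they are excluded downstream with a report, never silently.
    """
    if grs_orientation not in ("bw_lowering", "bw_raising"):
        raise ValueError(f"unknown grs_orientation {grs_orientation!r}")
    grs = np.asarray(grs, dtype=float)
    n = cohort.n
    bw_sd = (cohort.birth_weight - float(np.mean(cohort.birth_weight))) / sd_bw
    if grs_orientation == "bw_lowering":
        bw_sd = -bw_sd  # SD deficit: per 1-SD decrease
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = sm.add_constant(np.asarray(covariates, dtype=float))
    n_cases = int(np.sum(cohort.t2d_status))
    common = dict(
        study_id=study_id, n=n, n_cases=n_cases, ancestry=ancestry,
        design=design, meta=meta or {},
    )

    out: list[StudyAssoc] = []
    # GRS -> birth weight (SD units), linear
    X = np.column_stack([C, grs])
    fit = sm.OLS(bw_sd, X).fit()
    out.append(StudyAssoc(assoc_kind="grs_on_exposure",
                          beta=float(fit.params[-1]), se=float(fit.bse[-1]),
                          **common))
    # GRS -> T2D, logistic
    y = cohort.t2d_status.astype(float)
    beta, se, err = _logit_coef(y, X, X.shape[1] - 1)
    out.append(StudyAssoc(assoc_kind="grs_on_outcome", beta=beta, se=se,
                          flag=err, **common))
    # birth weight -> T2D, observational logistic
    Xo = np.column_stack([C, bw_sd])
    beta, se, err = _logit_coef(y, Xo, Xo.shape[1] - 1)
    out.append(StudyAssoc(assoc_kind="exposure_on_outcome", beta=beta, se=se,
                          flag=err, **common))
    return out


def meta_analyze(
    estimates: Sequence[StudyAssoc], model: str = "random"
) -> MetaResult:
    """Inverse-variance meta-analysis with DerSimonian–Laird tau².

    Fixed: wᵢ = 1/seᵢ², β̂ = Σwβ/Σw, se = 1/√Σw.  Heterogeneity:
    Q = Σw(β−β̂_fixed)², I² = max(0, (Q−df)/Q)·100,
    tau² = max(0, (Q−df)/(Σw − Σw²/Σw)).  Random: weights 1/(seᵢ²+tau²).
    Flagged estimates are dropped (reported via k_studies); a single usable
    estimate is returned as-is with a flag.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown meta-analysis model {model!r}")
    usable = [e for e in estimates if e.usable()]
    if not usable:
        raise ValueError("no usable study estimates to pool")
    b = np.array([e.beta for e in usable])
    se = np.array([e.se for e in usable])
    k = len(usable)
    if k == 1:
        beta, s = float(b[0]), float(se[0])
        p = 2 * stats.norm.sf(abs(beta / s))
        return MetaResult(beta, s, beta - Z95 * s, beta + Z95 * s, float(p),
                          0.0, 0, 0.0, 0.0, model, 1, flag="single study")
    w = 1.0 / se**2
    beta_f = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - beta_f) ** 2))
    df = k - 1
    i2 = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    if model == "fixed":
        beta_hat, s = beta_f, float(1.0 / math.sqrt(np.sum(w)))
        tau2_out = 0.0
    else:
        wr = 1.0 / (se**2 + tau2)
        beta_hat = float(np.sum(wr * b) / np.sum(wr))
        s = float(1.0 / math.sqrt(np.sum(wr)))
        tau2_out = tau2
    p = float(2 * stats.norm.sf(abs(beta_hat / s)))
    return MetaResult(beta_hat, s, beta_hat - Z95 * s, beta_hat + Z95 * s, p,
                      q, df, float(i2), float(tau2_out), model, k)


def ratio_iv_estimate(
    pooled_outcome: MetaResult,
    pooled_exposure: MetaResult,
    binary_outcome: bool = True,
    second_order: bool = False,
) -> MrEstimate:
    """Ratio (Wald) IV estimator from pooled coefficients.

    β_IV = β_ZY / β_ZX with the first-order delta-method SE
    √(se_ZY²/β_ZX² + β_ZY²·se_ZX²/β_ZX⁴); a second-order correction term
    is available behind a flag.  Both inputs must share the GRS
    orientation; with a birth-weight-lowering score the result is per 1-SD
    decrease in birth weight and is exponentiated to an OR.

    The denominator must be informative: |β_ZX|/se_ZX ≥ 1, else the
    instrument cannot support a ratio.
    """
    bzy, sy = pooled_outcome.beta, pooled_outcome.se
    bzx, sx = pooled_exposure.beta, pooled_exposure.se
    if abs(bzx) / sx < 1.0:
        raise ValueError(
            f"GRS–exposure coefficient uninformative (|beta|/se = "
            f"{abs(bzx) / sx:.2f} < 1); ratio estimate refused"
        )
    beta = bzy / bzx
    var = sy**2 / bzx**2 + bzy**2 * sx**2 / bzx**4
    if second_order:
        var += sy**2 * sx**2 / bzx**4
    se = math.sqrt(var)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    extra = _or_fields(beta, se) if binary_outcome else {}
    return MrEstimate(
        method="ratio_iv", beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        p=p, n_snps=0, **extra,
    )


def forest_table(estimates: Sequence[StudyAssoc], pooled: MetaResult) -> pd.DataFrame:
    """Forest-style text table: per-study rows with IV weights, then the
    pooled row."""
    usable = [e for e in estimates if e.usable()]
    w = np.array([1.0 / e.se**2 for e in usable])
    w_pct = 100 * w / w.sum() if len(w) else w
    rows = [
        {
            "study": e.study_id,
            "beta": e.beta,
            "se": e.se,
            "ci_low": e.beta - Z95 * e.se,
            "ci_high": e.beta + Z95 * e.se,
            "weight_pct": round(float(pct), 2),
        }
        for e, pct in zip(usable, w_pct)
    ]
    rows.append(
        {
            "study": f"pooled ({pooled.model}, k={pooled.k_studies})",
            "beta": pooled.beta,
            "se": pooled.se,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
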
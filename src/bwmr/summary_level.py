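"""Two-sample MR estimators on harmonized per-SNP summary statistics.

Implements the estimator family used for the summary-level arm: per-SNP
Wald ratios, the inverse-variance-weighted (IVW) estimator, simple and
weighted median estimators with parametric-bootstrap standard errors, and
MR-Egger regression whose intercept tests for directional pleiotropy.

Reporting convention
--------------------
All estimators are computed on the per-allele scale as given (effect per
1-SD *increase* in birth weight) and, by default, negated on output so
results read "per 1-SD decrease in birth weight" — the convention of a
low-birth-weight risk analysis.  Pass ``orientation="increase"`` to skip
the negation (the exact algebraic identities are orientation-free either
way).  For binary outcomes the estimate is also exponentiated to an OR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .study_level import MrEstimate, Z95
from .summary_io import InstrumentVariant

__all__ = [
    "wald_ratios",
    "ivw",
    "median_estimators",
    "egger",
    "leave_loci_out",
    "all_methods",
    "LeaveOutResult",
]

#: Bonferroni-adjusted significance threshold for the four glycemic traits
GLYCEMIC_ALPHA = 0.05 / 4


def _usable(variants: Sequence[InstrumentVariant]) -> tuple[list[InstrumentVariant], list[tuple[str, str]]]:
    kept, excluded = [], []
    for v in variants:
        if v.flag == "monomorphic" or not np.isfinite(v.beta_exposure) or not np.isfinite(v.beta_outcome):
            excluded.append((v.rsid, "flagged/non-finite"))
        elif v.beta_exposure == 0:
            excluded.append((v.rsid, "zero exposure effect"))
        else:
            kept.append(v)
    return kept, excluded


def _arrays(variants: Sequence[InstrumentVariant]):
    bx = np.array([v.beta_exposure for v in variants])
    sx = np.array([v.se_exposure for v in variants])
    by = np.array([v.beta_outcome for v in variants])
    sy = np.array([v.se_outcome for v in variants])
    return bx, sx, by, sy


def _binary(variants: Sequence[InstrumentVariant]) -> bool:
    return all(v.outcome_type == "binary" for v in variants)


def _sign(orientation: str) -> float:
    if orientation == "decrease":
        return -1.0
    if orientation == "increase":
        return 1.0
    raise ValueError(f"unknown orientation {orientation!r}")


def _finish(
    method: str,
    beta_inc: float,
    se: float,
    p: float,
    n_snps: int,
    binary: bool,
    orientation: str,
    **extra,
) -> MrEstimate:
    beta = _sign(orientation) * beta_inc
    fields = dict(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        p=float(p), n_snps=n_snps,
    )
    if binary:
        fields.update(
            or_=math.exp(beta),
            or_ci_low=math.exp(beta - Z95 * se),
            or_ci_high=math.exp(beta + Z95 * se),
        )
    fields.update(extra)
    return MrEstimate(**fields)


def wald_ratios(
    variants: Sequence[InstrumentVariant],
) -> list[tuple[str, float, float]]:
    """Per-SNP ratio estimates βY/βX with first-order SE = seY/|βX|.

    Ratios are orientation-free (flipping both betas leaves them fixed).
    Variants with zero exposure effect are excluded, with the exclusion
    visible to callers via the shorter output list.
    """
    kept, _ = _usable(variants)
    return [
        (v.rsid, v.beta_outcome / v.beta_exposure, v.se_outcome / abs(v.beta_exposure))
        for v in kept
    ]


def ivw(
    variants: Sequence[InstrumentVariant],
    se_model: str = "multiplicative",
    orientation: str = "decrease",
) -> MrEstimate:
    """Inverse-variance-weighted estimate: WLS of βY on βX through the
    origin with weights 1/seY².

    ``se_model="multiplicative"`` (default) scales the fixed-effect SE by
    max(1, √(RSS/(k−1))), a conservative allowance for heterogeneity among
    ratios; ``"fixed"`` keeps the unscaled SE (used by the exact oracle
    identities).
    """
    kept, _ = _usable(variants)
    k = len(kept)
    if k == 0:
        raise ValueError("no usable variants")
    if se_model not in ("multiplicative", "fixed"):
        raise ValueError(f"unknown se_model {se_model!r}")
    if k == 1:
        # a single variant is directed to the Wald ratio (exact identity:
        # the origin-constrained WLS fit collapses to βY/βX)
        _, ratio, se = wald_ratios(kept)[0]
        p = 2 * stats.norm.sf(abs(ratio) / se)
        return _finish("wald_ratio", ratio, se, p, 1, _binary(kept), orientation)
    bx, _, by, sy = _arrays(kept)
    w = 1.0 / sy**2
    slope = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se_fixed = 1.0 / math.sqrt(float(np.sum(w * bx**2)))
    rss = float(np.sum(w * (by - slope * bx) ** 2))
    scale = max(1.0, math.sqrt(rss / (k - 1))) if se_model == "multiplicative" else 1.0
    se = se_fixed * scale
    p = 2 * stats.norm.sf(abs(slope) / se)
    return _finish("ivw", slope, se, p, k, _binary(kept), orientation)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """50th weighted percentile with linear interpolation.

    Order the ratios; with standardized weights w′ the cumulative position
    of the j-th ratio is sⱼ = Σ_{i≤j} w′ᵢ − w′ⱼ/2; the estimate
    interpolates between the ratios bracketing s = 0.5.  Symmetric in the
    sense median(−x) = −median(x); with equal weights it reproduces the
    ordinary median.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    wp = weights[order] / weights.sum()
    s = np.cumsum(wp) - wp / 2
    # np.interp clamps outside [s0, s_last] (a single dominant weight) and
    # averages across exact ties in the cumulative positions.
    return float(np.interp(0.5, s, r))


def median_estimators(
    variants: Sequence[InstrumentVariant],
    weighted: bool = True,
    n_boot: int = 10_000,
    seed: int | None = None,
    orientation: str = "decrease",
) -> MrEstimate:
    """Simple or weighted median of the per-SNP Wald ratios.

    Weighted uses inverse-variance weights 1/se(ratio)²; simple uses equal
    weights (and equals the ordinary median).  The SE is the standard
    deviation of the estimator over ``n_boot`` parametric-bootstrap draws
    in which each variant's exposure and outcome betas are resampled from
    Normal(β̂, se); ``seed`` makes the bootstrap reproducible and is
    required.  The median of ≥3 ratios is consistent when variants holding
    at least half the weight are valid instruments.
    """
    kept, _ = _usable(variants)
    k = len(kept)
    if k < 3:
        raise ValueError("median estimators require >= 3 usable variants")
    if seed is None:
        raise ValueError("median_estimators needs an explicit bootstrap seed")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is very low; SE will be noisy", stacklevel=2)
    bx, sx, by, sy = _arrays(kept)

    # inverse-variance weights of the observed ratios, held fixed across
    # bootstrap draws (the bootstrap measures the median's variability for
    # this weight profile, not the weights' own noise)
    if weighted:
        w = (bx / sy) ** 2  # 1/se(ratio)² to first order
    else:
        w = np.ones(k)

    point = _weighted_median(by / bx, w)
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, k))
    bys = rng.normal(by, sy, size=(n_boot, k))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median(bys[i] / bxs[i], w)
    se = float(np.std(boots, ddof=1))
    p = 2 * stats.norm.sf(abs(point) / se)
    method = "weighted_median" if weighted else "simple_median"
    return _finish(method, point, se, p, k, _binary(kept), orientation)


def egger(
    variants: Sequence[InstrumentVariant],
    se_model: str = "multiplicative",
    orientation: str = "decrease",
    constrain_intercept: bool = False,
) -> MrEstimate:
    """MR-Egger regression: WLS of βY on βX *with* a free intercept,
    weights 1/seY², after re-orienting every variant so βX ≥ 0.

    The slope is a pleiotropy-corrected causal estimate (under the InSIDE
    assumption); an intercept distinct from zero is evidence of
    directional pleiotropy.  Slope and intercept SEs share the
    multiplicative heterogeneity scaling max(1, √(RSS/(k−2))); p-values
    use t with k−2 degrees of freedom.  ``constrain_intercept=True`` drops
    the intercept column, which reduces the fit to the IVW regression
    (exactly, under the fixed-effect SE model).  The reported intercept keeps the
    βX ≥ 0 orientation (average direct effect per exposure-raising
    allele) regardless of the slope's reporting orientation.
    """
    kept, _ = _usable(variants)
    k = len(kept)
    if k < 3:
        raise ValueError("MR-Egger requires >= 3 usable variants")
    if se_model not in ("multiplicative", "fixed"):
        raise ValueError(f"unknown se_model {se_model!r}")
    bx, _, by, sy = _arrays(kept)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if not constrain_intercept and np.allclose(bx, bx[0]):
        raise ValueError("all exposure effects equal: Egger slope unidentifiable")
    w = 1.0 / sy**2
    if constrain_intercept:
        X = bx[:, None]
    else:
        X = np.column_stack([np.ones(k), bx])
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * by)
    coef = np.linalg.solve(XtWX, XtWy)
    slope = float(coef[-1])
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    cov = np.linalg.inv(XtWX)
    df = k - X.shape[1]
    scale = max(1.0, math.sqrt(rss / df)) if se_model == "multiplicative" else 1.0
    se_slope = math.sqrt(cov[-1, -1]) * scale
    p_slope = 2 * stats.t.sf(abs(slope) / se_slope, df)
    if constrain_intercept:
        return _finish("egger_constrained", slope, se_slope, p_slope, k,
                       _binary(kept), orientation)
    intercept = float(coef[0])
    se_int = math.sqrt(cov[0, 0]) * scale
    p_int = 2 * stats.t.sf(abs(intercept) / se_int, df)
    return _finish(
        "egger", slope, se_slope, p_slope, k, _binary(kept), orientation,
        intercept=intercept, intercept_se=se_int, intercept_p=float(p_int),
    )


@dataclass(frozen=True)
class LeaveOutResult:
    full: MrEstimate
    reduced: MrEstimate
    excluded: tuple[str, ...]


def leave_loci_out(
    variants: Sequence[InstrumentVariant],
    exclude_rsids: Sequence[str],
    se_model: str = "multiplicative",
    orientation: str = "decrease",
) -> LeaveOutResult:
    """Sensitivity analysis excluding named loci (e.g. known T2D genes):
    IVW on the full and the reduced SNP set, side by side."""
    exclude = set(exclude_rsids)
    reduced = [v for v in variants if v.rsid not in exclude]
    if len(reduced) == len(variants):
        hit: tuple[str, ...] = ()
    else:
        hit = tuple(v.rsid for v in variants if v.rsid in exclude)
    kept, _ = _usable(reduced)
    if len(kept) == 0:
        raise ValueError("exclusion removes all variants")
    if len(kept) == 1:
        rsid, ratio, se = wald_ratios(kept)[0]
        beta = _sign(orientation) * ratio
        p = 2 * stats.norm.sf(abs(beta) / se)
        red = MrEstimate(
            method="wald_ratio", beta=beta, se=se, ci_low=beta - Z95 * se,
            ci_high=beta + Z95 * se, p=float(p), n_snps=1,
            **({"or_": math.exp(beta), "or_ci_low": math.exp(beta - Z95 * se),
                "or_ci_high": math.exp(beta + Z95 * se)} if _binary(kept) else {}),
        )
    else:
        red = ivw(reduced, se_model=se_model, orientation=orientation)
    full = ivw(variants, se_model=se_model, orientation=orientation)
    return LeaveOutResult(full=full, reduced=red, excluded=hit)


def all_methods(
    variants: Sequence[InstrumentVariant],
    n_boot: int = 10_000,
    seed: int | None = None,
    se_model: str = "multiplicative",
    orientation: str = "decrease",
) -> dict[str, MrEstimate]:
    """Run the full estimator battery (simple median, weighted median,
    IVW, MR-Egger) in the order the results tables use."""
    return {
        "simple_median": median_estimators(
            variants, weighted=False, n_boot=n_boot, seed=seed, orientation=orientation
        ),
        "weighted_median": median_estimators(
            variants, weighted=True, n_boot=n_boot, seed=seed, orientation=orientation
        ),
        "ivw": ivw(variants, se_model=se_model, orientation=orientation),
        "egger": egger(variants, se_model=se_model, orientation=orientation),
    }
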
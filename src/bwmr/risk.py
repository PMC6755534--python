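"""Unit standardization and absolute-risk translation.

Birth-weight effects circulate in two unit systems: grams (individual-level
cohorts) and standard deviations (summary-level GWAS, with 1 SD = 543 g in
the pooled exposure GWAS).  All conversions between them live here, as does
the translation of an odds ratio into an absolute risk increase (ARI) per
1000 participant-years given a baseline incidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

__all__ = [
    "BIRTH_WEIGHT_SD_GRAMS",
    "FASTING_GLUCOSE_SD_MGDL",
    "RiskContext",
    "standardize_per_sd",
    "destandardize_per_sd",
    "ari_per_1000",
    "rare_disease_ari",
]

#: grams of birth weight per SD (pooled exposure-GWAS value)
BIRTH_WEIGHT_SD_GRAMS = 543.0
#: mg/dL of fasting glucose per SD (pooled value used for trait-side scaling)
FASTING_GLUCOSE_SD_MGDL = 13.1


@dataclass(frozen=True)
class RiskContext:
    """Baseline quantities needed to express relative effects absolutely."""

    sd_bw: float = BIRTH_WEIGHT_SD_GRAMS  # grams per SD of birth weight
    baseline_incidence: float | None = None  # events per 1000 participant-years
    outcome_label: str = "type 2 diabetes"

    def __post_init__(self) -> None:
        if self.sd_bw <= 0:
            raise ValueError("sd_bw must be positive")
        if self.baseline_incidence is not None and self.baseline_incidence < 0:
            raise ValueError("baseline_incidence must be >= 0")


def standardize_per_sd(beta_per_gram: float, sd_bw: float = BIRTH_WEIGHT_SD_GRAMS) -> float:
    """Convert an effect per gram of birth weight to an effect per SD.

    The same multiplication applies to a standard error.
    """
    if sd_bw <= 0:
        raise ValueError("sd_bw must be positive")
    return beta_per_gram * sd_bw


def destandardize_per_sd(beta_per_sd: float, sd_bw: float = BIRTH_WEIGHT_SD_GRAMS) -> float:
    """Inverse of :func:`standardize_per_sd`."""
    if sd_bw <= 0:
        raise ValueError("sd_bw must be positive")
    return beta_per_sd / sd_bw


def rare_disease_ari(or_: float, baseline_incidence: float) -> float:
    """ARI per 1000 participant-years under the rare-outcome approximation
    RR ≈ OR: ``baseline × (OR − 1)``."""
    return baseline_incidence * (or_ - 1.0)


def ari_per_1000(
    or_: float,
    context: RiskContext,
    formula: Callable[[float, float], float] = rare_disease_ari,
) -> float:
    """Absolute risk increase per 1000 participant-years for a given OR.

    The formula is pluggable (default: rare-outcome ``baseline × (OR − 1)``);
    pipeline reports always echo which formula and baseline were used.
    """
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    if context.baseline_incidence is None:
        raise ValueError(
            "baseline_incidence is not set; configure RiskContext.baseline_incidence "
            "(events per 1000 participant-years) before requesting an ARI"
        )
    return formula(or_, context.baseline_incidence)
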
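"""Weighted genetic risk score construction and instrument diagnostics.

The GRS is the single composite instrument of the study-level arm: a
weighted sum of allele counts, oriented so that (by default) a higher
score means a genetically *lower* birth weight, matching the "per 1-SD
decrease" reporting convention.  Weights may arrive in grams or SD of
birth weight; internally everything is carried in SD units (1 SD = 543 g
unless told otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .risk import BIRTH_WEIGHT_SD_GRAMS
from .simulate import CohortDataset

__all__ = [
    "WeightSet",
    "compute_grs",
    "instrument_strength",
    "confounder_screen",
    "read_weight_table",
]


@dataclass(frozen=True)
class WeightSet:
    """Published per-allele birth-weight effects for the score SNPs."""

    rsids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    weights: tuple[float, ...]  # per effect allele
    unit: str = "sd"  # "sd" | "grams"
    sd_bw: float = BIRTH_WEIGHT_SD_GRAMS

    def __post_init__(self) -> None:
        if len(set(self.rsids)) != len(self.rsids):
            raise ValueError("duplicate rsids in weight set")
        if not all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if len(self.rsids) != len(self.effect_alleles) or len(self.rsids) != len(self.weights):
            raise ValueError("rsids, effect_alleles and weights must align")
        if self.unit not in ("sd", "grams"):
            raise ValueError(f"unknown weight unit {self.unit!r}")

    def in_sd_units(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / self.sd_bw if self.unit == "grams" else w

    @classmethod
    def from_config_betas(cls, config) -> "WeightSet":
        """Weight set using a simulation's true per-allele effects (grams)."""
        beta, _ = config.scaled_betas()
        return cls(
            rsids=config.snp_ids,
            effect_alleles=tuple(a for a, _ in config.alleles),
            weights=tuple(float(b) for b in beta),
            unit="grams",
            sd_bw=config.sd_bw,
        )


def read_weight_table(path: str | Path) -> WeightSet:
    """Read a delimited weight file with columns rsid, effect_allele,
    weight and optionally unit (one value for the whole table)."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("rsid", "effect_allele", "weight"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    unit = "sd"
    if "unit" in df.columns:
        units = set(df["unit"].astype(str))
        if len(units) != 1:
            raise ValueError(f"{path}: mixed weight units {units}")
        unit = units.pop()
    return WeightSet(
        rsids=tuple(df["rsid"].astype(str)),
        effect_alleles=tuple(df["effect_allele"].astype(str)),
        weights=tuple(df["weight"].astype(float)),
        unit=unit,
    )


def compute_grs(
    cohort: CohortDataset,
    weights: WeightSet,
    orientation: str = "bw_lowering",
    max_missing_frac: float = 0.2,
) -> np.ndarray:
    """Weighted GRS per individual.

    The score counts, for each SNP, the allele on the requested orientation
    (``bw_lowering``: the allele that decreases birth weight) weighted by
    the absolute effect size, and is rescaled by ``m / Σ|w|`` so one score
    unit corresponds to roughly one average-effect allele.  Weight SNPs
    absent from the cohort are imputed at their expected count ``2·eaf``
    (a constant, so they do not add variance); if more than
    ``max_missing_frac`` of the SNPs are absent an error lists them.
    """
    if orientation not in ("bw_lowering", "bw_raising"):
        raise ValueError(f"unknown orientation {orientation!r}")
    w_sd = weights.in_sd_units()
    col = {rsid: j for j, rsid in enumerate(cohort.snp_ids)}
    missing = [r for r in weights.rsids if r not in col]
    if len(missing) > max_missing_frac * len(weights.rsids):
        raise ValueError(
            f"{len(missing)}/{len(weights.rsids)} weight SNPs absent from cohort "
            f"(> {max_missing_frac:.0%} allowed): {', '.join(missing)}"
        )
    n = cohort.n
    score = np.zeros(n)
    total_abs = float(np.sum(np.abs(w_sd)))
    if total_abs == 0:
        raise ValueError("all weights are zero")
    for k, rsid in enumerate(weights.rsids):
        w = w_sd[k]
        if rsid not in col:
            continue  # E[2·eaf]·w is a constant shift; skip (variance-free)
        j = col[rsid]
        g = cohort.genotypes[:, j].astype(float)
        if weights.effect_alleles[k] != cohort.effect_alleles[j]:
            if weights.effect_alleles[k] != cohort.other_alleles[j]:
                raise ValueError(
                    f"{rsid}: weight effect allele {weights.effect_alleles[k]} "
                    f"matches neither cohort allele "
                    f"{cohort.effect_alleles[j]}/{cohort.other_alleles[j]}"
                )
            g = 2.0 - g
            # g now counts the weight's effect allele
        # orient: count the allele moving BW in the requested direction
        lowering = w < 0
        if orientation == "bw_lowering":
            counted = g if lowering else 2.0 - g
        else:
            counted = 2.0 - g if lowering else g
        score += np.abs(w) * counted
    return score * (len(weights.rsids) / total_abs)


def instrument_strength(
    cohort: CohortDataset,
    grs: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> dict[str, float]:
    """Incremental R² of the GRS for birth weight, and the implied F.

    ``r2`` is the partial R² of the score added to a covariate-only linear
    model of birth weight; ``f_stat = ((n − k − 1)/k) · r2/(1 − r2)`` with
    k = 1 instrument.  F > 10 is the conventional strong-instrument bar.
    """
    grs = np.asarray(grs, dtype=float)
    if np.std(grs) == 0:
        raise ValueError("GRS is constant; instrument strength undefined")
    y = cohort.birth_weight
    n = len(y)
    k = 1
    if covariates is None:
        X0 = np.ones((n, 1))
    else:
        X0 = sm.add_constant(np.asarray(covariates, dtype=float))
    if n <= X0.shape[1] + k + 1:
        raise ValueError("too few observations for the requested model")
    fit0 = sm.OLS(y, X0).fit()
    fit1 = sm.OLS(y, np.column_stack([X0, grs])).fit()
    r2 = float((fit0.ssr - fit1.ssr) / fit0.ssr)  # partial R² of the GRS
    f_stat = (n - k - 1) / k * r2 / (1 - r2)
    return {"r2": r2, "f_stat": float(f_stat), "n": float(n)}


def confounder_screen(
    grs: np.ndarray, confounders: pd.DataFrame
) -> pd.DataFrame:
    """Univariate regressions of each putative confounder on the GRS.

    Returns one row per confounder with beta, SE and raw two-sided p
    (no multiplicity adjustment).  Zero-variance confounders are flagged
    rather than raised.
    """
    if confounders.shape[1] < 1:
        raise ValueError("at least one confounder column required")
    grs = np.asarray(grs, dtype=float)
    X = sm.add_constant(grs)
    rows = []
    for name in confounders.columns:
        y = confounders[name].to_numpy(dtype=float)
        if np.std(y) == 0:
            rows.append({"confounder": name, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "flag": "zero variance"})
            continue
        fit = sm.OLS(y, X).fit()
        rows.append({
            "confounder": name,
            "beta": float(fit.params[1]),
            "se": float(fit.bse[1]),
            "p": float(fit.pvalues[1]),
            "flag": None,
        })
    return pd.DataFrame(rows)


def pairwise_r2(cohort: CohortDataset) -> pd.DataFrame:
    """Pairwise genotype correlation r² between instrument SNPs.

    The real instruments were verified to have no pair with r² > 0.05;
    the diagnostics report applies the same check to simulated data.
    """
    g = cohort.genotypes.astype(float)
    keep = g.std(axis=0) > 0
    r = np.corrcoef(g[:, keep], rowvar=False)
    r2 = r**2
    ids = [s for s, k in zip(cohort.snp_ids, keep) if k]
    return pd.DataFrame(r2, index=ids, columns=ids)
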
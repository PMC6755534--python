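"""Reading, validation and harmonization of per-SNP summary statistics.

Two record types are used throughout the package:

* :class:`SummaryRecord` — one SNP's association with a single trait, as
  read from a GWAS summary table (rsid, alleles, EAF, beta, SE, n).
* :class:`InstrumentVariant` — one SNP's *harmonized* exposure and outcome
  statistics, the unit of input for every two-sample MR estimator.

Harmonization joins an exposure table with an outcome table on rsid and
re-expresses the outcome effect on the exposure's effect allele, flipping
signs for swapped alleles and attempting strand complements before
declaring a mismatch.  Palindromic SNPs (A/T or C/G) cannot be resolved by
allele labels alone and are kept only when the allele frequencies on both
sides identify the shared allele unambiguously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SummaryRecord",
    "InstrumentVariant",
    "StudyAssoc",
    "TableReadReport",
    "HarmonizationReport",
    "read_summary_table",
    "write_summary_table",
    "harmonize",
    "read_study_assocs",
    "write_study_assocs",
]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical header for single-trait summary tables
CANONICAL_COLUMNS = ["rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "n"]

#: default tolerance for resolving palindromic SNPs by allele frequency
DEFAULT_EAF_TOLERANCE = 0.08


@dataclass(frozen=True)
class SummaryRecord:
    """Single-trait GWAS association for one SNP."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    n: int | None = None
    flag: str | None = None

    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class InstrumentVariant:
    """Harmonized exposure + outcome summary statistics for one SNP.

    ``beta_exposure`` is in SD of birth weight per effect allele;
    ``beta_outcome`` is a log-OR (binary outcome) or SD of the trait
    (quantitative outcome) per the same allele.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    outcome_type: str = "binary"  # "binary" | "quantitative"
    flag: str | None = None

    def __post_init__(self) -> None:
        if self.outcome_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.rsid}: standard errors must be positive")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")


@dataclass(frozen=True)
class StudyAssoc:
    """One study's association estimate (GRS→exposure, GRS→outcome, or
    the observational exposure→outcome model)."""

    study_id: str
    assoc_kind: str  # grs_on_exposure | grs_on_outcome | exposure_on_outcome
    beta: float | None
    se: float | None
    n: int
    n_cases: int | None = None
    ancestry: str = "European"
    design: str = "cohort"  # cohort | case-control | cross-sectional
    flag: str | None = None
    meta: Mapping[str, object] = field(default_factory=dict)

    def usable(self) -> bool:
        return (
            self.flag is None
            and self.beta is not None
            and self.se is not None
            and self.se > 0
        )


@dataclass
class TableReadReport:
    """Result of reading a summary table: valid records plus per-row
    rejections (1-based data line number, reason)."""

    records: list[SummaryRecord]
    rejected: list[tuple[int, str]]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HarmonizationReport:
    variants: list[InstrumentVariant]
    dropped: list[tuple[str, str]]  # (rsid, reason)

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> TableReadReport:
    """Read a delimited summary-statistics table into :class:`SummaryRecord`s.

    ``column_map`` maps canonical names (``rsid``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``n``) to the file's column
    names; omitted keys default to the canonical name itself.  Rows that
    violate record invariants (non-positive SE, invalid alleles, EAF outside
    (0,1)) are reported with their line number rather than raised.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    cmap = dict(column_map or {})
    resolve = {c: cmap.get(c, c) for c in CANONICAL_COLUMNS}
    for canon in ("rsid", "effect_allele", "other_allele", "beta", "se"):
        if resolve[canon] not in df.columns:
            raise ValueError(
                f"{path}: required column {resolve[canon]!r} (for {canon!r}) not found"
            )

    records: list[SummaryRecord] = []
    rejected: list[tuple[int, str]] = []
    has_eaf = resolve["eaf"] in df.columns
    has_n = resolve["n"] in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        rsid = str(row[resolve["rsid"]])
        ea = str(row[resolve["effect_allele"]]).upper()
        oa = str(row[resolve["other_allele"]]).upper()
        try:
            beta = float(row[resolve["beta"]])
            se = float(row[resolve["se"]])
        except (TypeError, ValueError):
            rejected.append((i, f"{rsid}: non-numeric beta/se"))
            continue
        eaf = float(row[resolve["eaf"]]) if has_eaf else math.nan
        eaf_val = None if math.isnan(eaf) else eaf
        n_val = None
        if has_n and not pd.isna(row[resolve["n"]]):
            n_val = int(row[resolve["n"]])
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            rejected.append((i, f"{rsid}: invalid allele {ea}/{oa}"))
            continue
        if ea == oa:
            rejected.append((i, f"{rsid}: effect and other allele identical"))
            continue
        if not (se > 0) or math.isnan(beta):
            rejected.append((i, f"{rsid}: SE must be > 0 and beta finite"))
            continue
        if eaf_val is not None and not (0.0 < eaf_val < 1.0):
            rejected.append((i, f"{rsid}: EAF {eaf_val} outside (0,1)"))
            continue
        rec = SummaryRecord(rsid, ea, oa, eaf_val, beta, se, n_val)
        if rec.is_palindromic():
            rec = replace(rec, flag="palindromic")
        records.append(rec)
    return TableReadReport(records, rejected)


def write_summary_table(records: Iterable[SummaryRecord], path: str | Path) -> None:
    """Write records with the canonical header (TSV)."""
    rows = [
        {
            "rsid": r.rsid,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": r.eaf,
            "beta": r.beta,
            "se": r.se,
            "n": r.n,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def _orient_outcome(
    exp: SummaryRecord, out: SummaryRecord, eaf_tolerance: float
) -> tuple[float, float | None] | str:
    """Re-express the outcome effect on the exposure's effect allele.

    Returns ``(sign, outcome_eaf_aligned)`` or a string reason for dropping.
    ``sign`` multiplies the outcome beta; the aligned outcome EAF refers to
    the exposure effect allele.
    """
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele

    if exp.is_palindromic() or out.is_palindromic():
        # Allele labels cannot distinguish strands; use EAF on both sides.
        if {e_ea, e_oa} != {o_ea, o_oa}:
            return "palindromic allele-set mismatch"
        if exp.eaf is None or out.eaf is None:
            return "palindromic SNP without EAF on both sides"
        de, do = exp.eaf - 0.5, out.eaf - 0.5
        if abs(de) <= eaf_tolerance or abs(do) <= eaf_tolerance:
            return "palindromic SNP with EAF too close to 0.5"
        if de * do > 0:  # same side: effect alleles agree
            return (1.0, out.eaf)
        return (-1.0, 1.0 - out.eaf)

    if (o_ea, o_oa) == (e_ea, e_oa):
        return (1.0, out.eaf)
    if (o_ea, o_oa) == (e_oa, e_ea):
        return (-1.0, None if out.eaf is None else 1.0 - out.eaf)
    # try strand complement
    c_ea, c_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (e_ea, e_oa):
        return (1.0, out.eaf)
    if (c_ea, c_oa) == (e_oa, e_ea):
        return (-1.0, None if out.eaf is None else 1.0 - out.eaf)
    return f"allele mismatch {e_ea}/{e_oa} vs {o_ea}/{o_oa}"


def harmonize(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    eaf_tolerance: float = DEFAULT_EAF_TOLERANCE,
    outcome_type: str = "binary",
) -> HarmonizationReport:
    """Inner-join exposure and outcome records on rsid and align alleles.

    Swapped outcome alleles negate the outcome beta; strand complements are
    attempted before a mismatch is declared; palindromic SNPs are kept only
    when both EAFs are at least ``eaf_tolerance`` away from 0.5 (and then
    matched by frequency side).  Dropped SNPs are listed with reasons —
    nothing is discarded silently.
    """
    out_by_rsid = {r.rsid: r for r in outcome}
    variants: list[InstrumentVariant] = []
    dropped: list[tuple[str, str]] = []
    for exp in exposure:
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            dropped.append((exp.rsid, "absent from outcome table"))
            continue
        result = _orient_outcome(exp, out, eaf_tolerance)
        if isinstance(result, str):
            dropped.append((exp.rsid, result))
            continue
        sign, _ = result
        variants.append(
            InstrumentVariant(
                rsid=exp.rsid,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                eaf=exp.eaf,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=sign * out.beta,
                se_outcome=out.se,
                outcome_type=outcome_type,
                flag=exp.flag,
            )
        )
    return HarmonizationReport(variants, dropped)


# -- per-study association tables -------------------------------------------

STUDY_COLUMNS = [
    "study_id",
    "assoc_kind",
    "beta",
    "se",
    "n",
    "n_cases",
    "ancestry",
    "design",
]


def write_study_assocs(assocs: Iterable[StudyAssoc], path: str | Path) -> None:
    rows = []
    for a in assocs:
        row = {c: getattr(a, c) for c in STUDY_COLUMNS}
        row.update(a.meta)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_study_assocs(path: str | Path) -> list[StudyAssoc]:
    df = pd.read_csv(path, sep=_sniff_sep(Path(path)))
    missing = [c for c in ("study_id", "assoc_kind", "beta", "se", "n") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for _, row in df.iterrows():
        meta = {
            k: row[k]
            for k in df.columns
            if k not in STUDY_COLUMNS and not pd.isna(row[k])
        }
        out.append(
            StudyAssoc(
                study_id=str(row["study_id"]),
                assoc_kind=str(row["assoc_kind"]),
                beta=None if pd.isna(row["beta"]) else float(row["beta"]),
                se=None if pd.isna(row["se"]) else float(row["se"]),
                n=int(row["n"]),
                n_cases=None
                if "n_cases" not in df.columns or pd.isna(row.get("n_cases"))
                else int(row["n_cases"]),
                ancestry=str(row.get("ancestry", "European")),
                design=str(row.get("design", "cohort")),
                meta=meta,
            )
        )
    return out
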
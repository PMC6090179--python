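"""Disproportionality signals from spontaneous adverse-event reports.

A spontaneous report links one patient episode to a set of suspected drugs,
a set of coded reactions, and the indications the drugs were given for.
For a (drug, outcome) pair the reports are partitioned into a 2x2 table —
a: drug and outcome, b: drug without outcome, c: other drugs with outcome,
d: other drugs without outcome — and scored with the reporting odds ratio
ROR = (a*d)/(b*c).  A pair is flagged as a signal when the lower bound of
the 95% Woolf confidence interval of the ROR exceeds 1.

The canonical in-memory container is a pandas DataFrame with one row per
report and set-valued columns for drugs, reactions and indications
(see :func:`read_reports_tsv`); the multi-valued TSV columns use ';' as the
within-cell separator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .core import (
    DEFAULT_Z,
    ContingencyTable,
    SignalScore,
    SignalSet,
    Source,
    TableContext,
    odds_ratio_woolf,
)

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["report_id", "drug_ids", "reaction_cuis", "indication_cuis", "gender", "age"]

SIGNAL_TSV_COLUMNS = ["outcome_cui", "a", "b", "c", "d", "ror", "ci_low", "ci_high", "is_signal"]


@dataclass(frozen=True)
class SpontaneousReport:
    """One voluntary report: drugs, coded reactions, indications, demographics."""

    report_id: str
    drug_ids: frozenset[str]
    reaction_cuis: frozenset[str] = frozenset()
    indication_cuis: frozenset[str] = frozenset()
    gender: str = "U"
    age_years: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.drug_ids:
            raise ValueError("drug_ids must be non-empty")
        if self.gender not in {"F", "M", "U"}:
            raise ValueError(f"gender must be F, M or U, got {self.gender!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")


def _split_set(value: str) -> frozenset[str]:
    if not value or pd.isna(value):
        return frozenset()
    return frozenset(v for v in str(value).split(";") if v)


def reports_to_frame(reports: Iterable[SpontaneousReport]) -> pd.DataFrame:
    rows = [
        (r.report_id, r.drug_ids, r.reaction_cuis, r.indication_cuis, r.gender, r.age_years)
        for r in reports
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def read_reports_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a report table: ';'-separated multi-valued cells become frozensets."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"report file missing columns: {sorted(missing)}")
    if df["report_id"].duplicated().any():
        dupes = df.loc[df["report_id"].duplicated(), "report_id"].head(3).tolist()
        raise ValueError(f"duplicate report_id values, e.g. {dupes}")
    out = pd.DataFrame(
        {
            "report_id": df["report_id"],
            "drug_ids": df["drug_ids"].map(_split_set),
            "reaction_cuis": df["reaction_cuis"].map(_split_set),
            "indication_cuis": df["indication_cuis"].map(_split_set),
            "gender": df["gender"].where(df["gender"].isin(["F", "M", "U"]), "U"),
            "age": pd.to_numeric(df["age"], errors="coerce"),
        }
    )
    if (out["drug_ids"].map(len) == 0).any():
        raise ValueError("every report must list at least one drug")
    return out


def write_reports_tsv(reports: pd.DataFrame, path: Union[str, Path]) -> None:
    df = reports.copy()
    for col in ["drug_ids", "reaction_cuis", "indication_cuis"]:
        df[col] = df[col].map(lambda s: ";".join(sorted(s)))
    df["age"] = df["age"].map(lambda v: "" if pd.isna(v) else f"{v:g}")
    df.to_csv(path, sep="\t", index=False)


def filter_reports_by_indication(
    reports: pd.DataFrame, drug: str, indication: str
) -> pd.DataFrame:
    """Reports naming both the drug and the indication of interest.

    This is the exposure stratum of the analysis; the comparator population
    (all remaining reports, or the indication-restricted remainder) is chosen
    downstream when the 2x2 table is assembled.
    """
    mask = reports["drug_ids"].map(lambda s: drug in s) & reports["indication_cuis"].map(
        lambda s: indication in s
    )
    subset = reports[mask]
    logger.info(
        "(%s, %s): %d of %d reports in the exposure stratum", drug, indication, len(subset), len(reports)
    )
    if subset.empty:
        logger.warning("no reports for drug %s with indication %s", drug, indication)
    return subset


def build_contingency_reports(
    reports: pd.DataFrame, drug: str, ade_cui: str
) -> ContingencyTable:
    """Partition reports into the drug/outcome 2x2 table.

    Cells always sum to the number of input reports; restricting the input
    population (e.g. to an indication) is the caller's choice.
    """
    has_drug = reports["drug_ids"].map(lambda s: drug in s)
    has_ade = reports["reaction_cuis"].map(lambda s: ade_cui in s)
    a = int((has_drug & has_ade).sum())
    b = int((has_drug & ~has_ade).sum())
    c = int((~has_drug & has_ade).sum())
    d = int((~has_drug & ~has_ade).sum())
    return ContingencyTable(a, b, c, d, context=TableContext.REPORTS)


def ror_score(table: ContingencyTable, z: float = DEFAULT_Z) -> SignalScore:
    """Reporting odds ratio with Woolf interval; signal when ci_low > 1."""
    if table.context is not TableContext.REPORTS:
        raise ValueError("ror_score expects a REPORTS-context table")
    est, lo, hi, corrected = odds_ratio_woolf(table, z=z)
    if corrected:
        logger.info("zero cell in %s; Haldane-Anscombe correction applied", table.cells)
    return SignalScore(
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        is_signal=lo > 1.0,
        table=table,
        zero_corrected=corrected,
    )


def detect_signals_faers(
    reports: pd.DataFrame,
    drug: str,
    indication: str,
    min_a: int = 1,
    z: float = DEFAULT_Z,
    comparator: str = "all",
) -> SignalSet:
    """Score every candidate reaction of a (drug, indication) pair.

    Candidate outcomes are the reaction CUIs occurring on reports that name
    both the drug and the indication, with at least ``min_a`` drug-and-outcome
    reports.  ``comparator`` selects the population the 2x2 table is built
    over: ``"all"`` (every loaded report; the standard disproportionality
    background) or ``"indication_restricted"`` (only reports carrying the
    indication).
    """
    if comparator not in {"all", "indication_restricted"}:
        raise ValueError(f"unknown comparator {comparator!r}")
    subset = filter_reports_by_indication(reports, drug, indication)
    result = SignalSet(drug=drug, indication=indication, source=Source.FAERS)
    if subset.empty:
        logger.warning("empty candidate set for (%s, %s)", drug, indication)
        return result

    if comparator == "all":
        population = reports
    else:
        population = reports[reports["indication_cuis"].map(lambda s: indication in s)]

    candidates = sorted(set().union(*subset["reaction_cuis"]))
    has_drug = population["drug_ids"].map(lambda s: drug in s)
    n_total = len(population)
    n_drug = int(has_drug.sum())

    # One exploded pass over the reactions gives every candidate's a and c.
    exploded = population[["reaction_cuis"]].copy()
    exploded["has_drug"] = has_drug
    exploded = exploded.explode("reaction_cuis").dropna(subset=["reaction_cuis"])
    grouped = exploded.groupby("reaction_cuis")["has_drug"].agg(["sum", "count"])

    for cui in candidates:
        if cui in grouped.index:
            a = int(grouped.loc[cui, "sum"])
            with_ade = int(grouped.loc[cui, "count"])
        else:  # pragma: no cover - candidates come from the population
            a, with_ade = 0, 0
        if a < min_a:
            continue
        c = with_ade - a
        table = ContingencyTable(a, n_drug - a, c, n_total - n_drug - c, context=TableContext.REPORTS)
        result.entries[cui] = ror_score(table, z=z)
    if not result.entries:
        logger.warning("no candidate reached min_a=%d for (%s, %s)", min_a, drug, indication)
    return result


def signals_to_frame(signals: SignalSet) -> pd.DataFrame:
    """Tabular form of a report-based signal set (one row per outcome)."""
    rows = []
    for cui, s in signals.entries.items():
        t = s.table
        rows.append((cui, t.a, t.b, t.c, t.d, s.estimate, s.ci_low, s.ci_high, s.is_signal))
    return pd.DataFrame(rows, columns=SIGNAL_TSV_COLUMNS)


def write_signals_tsv(signals: SignalSet, path: Union[str, Path]) -> None:
    signals_to_frame(signals).to_csv(path, sep="\t", index=False, float_format="%.6g")
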
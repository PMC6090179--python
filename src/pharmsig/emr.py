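"""Case-crossover signal detection from longitudinal patient timelines.

Each patient acts as their own control, which cancels time-invariant
confounders such as genetics and sex.  For a patient treated with drug D
for indication IND, the interval from the first IND diagnosis up to (but
excluding) the first D exposure is the *control* window, and the interval
from first through last exposure (inclusive) is the *case* window.  For
each candidate outcome the cohort is counted into a 2x2 table — a: patients
with the outcome mentioned in the case window, b: the rest of the cohort,
c: patients with a control-window mention, d: the rest — so a+b = c+d = the
cohort size.  The analysis is unconditional: the pooled odds ratio
OR = (a*d)/(b*c) is scored with a Woolf interval, and a pair is a signal
when the interval's lower bound exceeds 1 *and* the two-sided p-value is
below 0.05.

Events arrive as a DataFrame (``patient_id  date  kind  code
semantic_type``) standing in for concept mentions extracted from clinical
notes and normalised to UMLS CUIs; dates may be integer day indices or ISO
dates (converted to day ordinals on read).
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
    bonferroni,
    odds_ratio_woolf,
    two_sided_p,
)
from .vocab import Hierarchy

__all__ = [
    "DEFAULT_SEMANTIC_TYPES",
    "ClinicalEvent",
    "PatientTimeline",
    "CaseCrossoverWindows",
    "CohortError",
    "read_events_tsv",
    "read_demographics_tsv",
    "filter_concepts_semantic",
    "extract_cohort",
    "build_windows",
    "count_outcome",
    "or_score",
    "outcome_pvalue",
    "bonferroni",
    "detect_signals_emr",
    "signals_to_frame",
    "write_signals_tsv",
]

logger = logging.getLogger(__name__)

#: UMLS semantic types retained for outcome mentions: Finding, Laboratory or
#: Test Result, Sign or Symptom, Disease or Syndrome, Mental or Behavioral
#: Dysfunction, Neoplastic Process, Cell or Molecular Dysfunction.
DEFAULT_SEMANTIC_TYPES = frozenset({"T033", "T034", "T184", "T047", "T048", "T191", "T049"})

EVENT_KINDS = {"DRUG_EXPOSURE", "CONCEPT_MENTION", "DIAGNOSIS"}
EVENT_COLUMNS = ["patient_id", "date", "kind", "code", "semantic_type"]
DEMOGRAPHICS_COLUMNS = ["patient_id", "gender", "race"]

SIGNAL_TSV_COLUMNS = [
    "outcome_cui",
    "a",
    "b",
    "c",
    "d",
    "or",
    "ci_low",
    "ci_high",
    "p",
    "p_bonferroni",
    "is_signal",
    "possible_indication_confounder",
]


class CohortError(ValueError):
    """No patient satisfies the cohort definition."""


@dataclass(frozen=True)
class ClinicalEvent:
    """One dated fact on a patient timeline."""

    patient_id: str
    date: int
    kind: str
    code: str
    semantic_type: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.code:
            raise ValueError("code must be non-empty")


@dataclass
class PatientTimeline:
    """Date-ordered event stream for a single patient."""

    patient_id: str
    events: list[ClinicalEvent]
    gender: str = "U"
    race: str = ""

    def __post_init__(self) -> None:
        if any(e.patient_id != self.patient_id for e in self.events):
            raise ValueError("all events must belong to the timeline's patient")
        self.events = sorted(self.events, key=lambda e: e.date)

    def to_frame(self) -> pd.DataFrame:
        rows = [(e.patient_id, e.date, e.kind, e.code, e.semantic_type) for e in self.events]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@dataclass(frozen=True)
class CaseCrossoverWindows:
    """Control ``[t_dx, t_first)`` and case ``[t_first, t_last]`` windows.

    A mention on the first-exposure day itself is a case-window event: an
    on-treatment day belongs to the exposure period.
    """

    patient_id: str
    t_dx: int
    t_first: int
    t_last: int

    def __post_init__(self) -> None:
        if not self.t_dx <= self.t_first <= self.t_last:
            raise ValueError(
                f"windows out of order for {self.patient_id}: "
                f"dx={self.t_dx}, first={self.t_first}, last={self.t_last}"
            )
        if self.t_first == self.t_dx:
            raise ValueError(f"control window empty for {self.patient_id}")

    def in_control(self, date: int) -> bool:
        return self.t_dx <= date < self.t_first

    def in_case(self, date: int) -> bool:
        return self.t_first <= date <= self.t_last


def _coerce_dates(series: pd.Series) -> pd.Series:
    numeric = pd.to_numeric(series, errors="coerce")
    if numeric.notna().all():
        return numeric.astype("int64")
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        bad = series[parsed.isna() & numeric.isna()].head(3).tolist()
        raise ValueError(f"unparseable dates, e.g. {bad}")
    return (parsed - pd.Timestamp("1970-01-01")).dt.days.astype("int64")


def read_events_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event file missing columns: {sorted(missing)}")
    unknown = set(df["kind"]) - EVENT_KINDS
    if unknown:
        raise ValueError(f"unknown event kinds: {sorted(unknown)}")
    out = df[EVENT_COLUMNS].copy()
    out["date"] = _coerce_dates(out["date"])
    return out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def read_demographics_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(DEMOGRAPHICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"demographics file missing columns: {sorted(missing)}")
    return df[DEMOGRAPHICS_COLUMNS]


def filter_concepts_semantic(
    events: pd.DataFrame, allowed_types: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Restrict concept mentions to outcome-relevant semantic types.

    Only ``CONCEPT_MENTION`` rows are filtered; drug exposures and diagnoses
    pass through untouched.
    """
    allowed = frozenset(allowed_types) if allowed_types is not None else DEFAULT_SEMANTIC_TYPES
    keep = (events["kind"] != "CONCEPT_MENTION") | events["semantic_type"].isin(allowed)
    return events[keep]


def extract_cohort(events: pd.DataFrame, drug: str, indication: str) -> pd.DataFrame:
    """Patients treated with ``drug`` for ``indication``, with their windows.

    A patient qualifies with at least one diagnosis of the indication, at
    least one exposure to the drug, and the earliest diagnosis strictly
    before the first exposure (so the control window is non-empty).  Returns
    one row per qualifying patient: ``patient_id  t_dx  t_first  t_last``.
    """
    dx = events[(events["kind"] == "DIAGNOSIS") & (events["code"] == indication)]
    rx = events[(events["kind"] == "DRUG_EXPOSURE") & (events["code"] == drug)]
    t_dx = dx.groupby("patient_id")["date"].min()
    t_rx = rx.groupby("patient_id")["date"].agg(t_first="min", t_last="max")
    windows = t_rx.join(t_dx.rename("t_dx"), how="inner")
    eligible = windows[windows["t_dx"] < windows["t_first"]]
    if eligible.empty:
        raise CohortError(
            f"empty cohort for ({drug}, {indication}): "
            f"{t_dx.size} diagnosed, {t_rx.shape[0]} exposed, "
            f"{len(windows)} with both, 0 with a non-empty control window"
        )
    logger.info(
        "cohort (%s, %s): %d patients (%d diagnosed, %d exposed)",
        drug,
        indication,
        len(eligible),
        t_dx.size,
        t_rx.shape[0],
    )
    return (
        eligible.reset_index()[["patient_id", "t_dx", "t_first", "t_last"]]
        .sort_values("patient_id", kind="stable")
        .reset_index(drop=True)
    )


def build_windows(
    timeline: Union[PatientTimeline, pd.DataFrame], drug: str, indication: str
) -> CaseCrossoverWindows:
    """Case-crossover windows for one patient who passed the cohort filter."""
    events = timeline.to_frame() if isinstance(timeline, PatientTimeline) else timeline
    patients = events["patient_id"].unique()
    if len(patients) != 1:
        raise ValueError(f"expected a single patient, got {len(patients)}")
    row = extract_cohort(events, drug, indication).iloc[0]
    return CaseCrossoverWindows(
        patient_id=str(row["patient_id"]),
        t_dx=int(row["t_dx"]),
        t_first=int(row["t_first"]),
        t_last=int(row["t_last"]),
    )


def count_outcome(
    cohort_windows: pd.DataFrame, outcome_cui: str, events: pd.DataFrame
) -> ContingencyTable:
    """Count per-window occurrence of one outcome over the cohort.

    Occurrence is binary per window (at least one mention); a patient with
    mentions in both windows contributes to both a and c, which is why both
    rows of the table cover the full cohort.
    """
    if cohort_windows.empty:
        raise CohortError("cohort_windows is empty")
    n = len(cohort_windows)
    mentions = events[(events["kind"] == "CONCEPT_MENTION") & (events["code"] == outcome_cui)]
    merged = mentions.merge(cohort_windows, on="patient_id", how="inner")
    in_case = (merged["date"] >= merged["t_first"]) & (merged["date"] <= merged["t_last"])
    in_control = (merged["date"] >= merged["t_dx"]) & (merged["date"] < merged["t_first"])
    a = merged.loc[in_case, "patient_id"].nunique()
    c = merged.loc[in_control, "patient_id"].nunique()
    return ContingencyTable(int(a), n - int(a), int(c), n - int(c), context=TableContext.CASE_CROSSOVER)


def outcome_pvalue(table: ContingencyTable, method: str = "auto") -> float:
    """Two-sided p-value for the 2x2; Pearson chi-square by default, Fisher
    exact when any expected cell is below 5 (``method="auto"``)."""
    p, used = two_sided_p(table, method=method)
    logger.debug("p=%.3g via %s for %s", p, used, table.cells)
    return p


def or_score(
    table: ContingencyTable,
    z: float = DEFAULT_Z,
    p_method: str = "auto",
) -> SignalScore:
    """Case-crossover odds ratio; signal when ci_low > 1 and p < 0.05."""
    if table.context is not TableContext.CASE_CROSSOVER:
        raise ValueError("or_score expects a CASE_CROSSOVER-context table")
    est, lo, hi, corrected = odds_ratio_woolf(table, z=z)
    p, used = two_sided_p(table, method=p_method)
    return SignalScore(
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        is_signal=(lo > 1.0) and (p < 0.05),
        table=table,
        p_value=p,
        p_method=used,
        zero_corrected=corrected,
    )


def detect_signals_emr(
    events: pd.DataFrame,
    drug: str,
    indication: str,
    min_patients: int = 1,
    z: float = DEFAULT_Z,
    p_method: str = "auto",
    bonferroni_m: Optional[int] = None,
    semantic_types: Optional[Iterable[str]] = None,
    hierarchy: Optional[Hierarchy] = None,
) -> SignalSet:
    """Run the full case-crossover screen for one (drug, indication) pair.

    Candidate outcomes are all semantic-type-filtered concept CUIs mentioned
    in at least ``min_patients`` case windows.  Each candidate is scored,
    Bonferroni-corrected over ``bonferroni_m`` comparisons (default: the
    number of candidates), and the result is ranked by descending OR with
    ties broken by ascending p then CUI.  When a hierarchy is supplied,
    outcomes that are the indication itself or one of its hierarchy
    descendants are flagged as possible indication confounders (they are
    kept, not excluded).
    """
    filtered = filter_concepts_semantic(events, semantic_types)
    windows = extract_cohort(filtered, drug, indication)
    n = len(windows)

    mentions = filtered[filtered["kind"] == "CONCEPT_MENTION"]
    merged = mentions.merge(windows, on="patient_id", how="inner")
    in_case = (merged["date"] >= merged["t_first"]) & (merged["date"] <= merged["t_last"])
    in_control = (merged["date"] >= merged["t_dx"]) & (merged["date"] < merged["t_first"])
    case_counts = merged.loc[in_case].groupby("code")["patient_id"].nunique()
    control_counts = merged.loc[in_control].groupby("code")["patient_id"].nunique()

    candidates = sorted(case_counts[case_counts >= min_patients].index)
    result = SignalSet(drug=drug, indication=indication, source=Source.EMR)
    if not candidates:
        logger.warning("no candidate outcome reached min_patients=%d", min_patients)
        return result

    m = bonferroni_m if bonferroni_m is not None else len(candidates)
    indication_family: set[str] = set()
    if hierarchy is not None:
        code = (
            indication if indication in hierarchy else hierarchy.code_for_cui(indication)
        )
        if code is not None:
            indication_family = {hierarchy.terms[code].cui} | hierarchy.descendant_cuis(code)

    scored: list[tuple[str, SignalScore]] = []
    for cui in candidates:
        a = int(case_counts.get(cui, 0))
        c = int(control_counts.get(cui, 0))
        table = ContingencyTable(a, n - a, c, n - c, context=TableContext.CASE_CROSSOVER)
        score = or_score(table, z=z, p_method=p_method)
        score.p_bonferroni = bonferroni(score.p_value, m)
        score.possible_indication_confounder = cui in indication_family
        scored.append((cui, score))

    scored.sort(key=lambda item: (-item[1].estimate, item[1].p_value, item[0]))
    result.entries = dict(scored)
    return result


def signals_to_frame(signals: SignalSet) -> pd.DataFrame:
    rows = []
    for cui, s in signals.entries.items():
        t = s.table
        rows.append(
            (
                cui,
                t.a,
                t.b,
                t.c,
                t.d,
                s.estimate,
                s.ci_low,
                s.ci_high,
                s.p_value,
                s.p_bonferroni,
                s.is_signal,
                s.possible_indication_confounder,
            )
        )
    return pd.DataFrame(rows, columns=SIGNAL_TSV_COLUMNS)


def write_signals_tsv(signals: SignalSet, path: Union[str, Path]) -> None:
    signals_to_frame(signals).to_csv(path, sep="\t", index=False, float_format="%.6g")
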
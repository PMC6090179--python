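"""Evaluate detected signal sets against adverse-event knowledge bases.

Two mapping strategies relate signals to a knowledge base over the shared
CUI key.  *Exact* mapping intersects the discovered CUIs with the
knowledge base's own CUIs.  *Flexible* mapping first expands every
knowledge-base term downward through the terminology hierarchy to all its
sub-level terms, so a specific discovered term (e.g. a particular
vasculitis) can match a broader recorded one (vasculitides).  Precision,
recall and F1 follow the usual definitions; the recall denominator is the
*un-expanded* confirmed set, so exact and flexible recall stay comparable
(expansion widens matching, not the gold standard's size).

The module also combines the two signal sources, partitions the three-way
Venn regions over CUIs, and ranks the flagged outcomes absent from the
knowledge base as novel-ADE hypotheses.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd

from .core import SignalSet, Source
from .vocab import Hierarchy, KnowledgeBase, expand_kb_flexible

logger = logging.getLogger(__name__)

VENN_REGIONS = ["faers_only", "emr_only", "kb_only", "faers_emr", "faers_kb", "emr_kb", "all"]

NOVEL_TSV_COLUMNS = ["outcome_cui", "sources", "odds_ratio", "ci_low", "ci_high", "p", "p_bonferroni"]


class MatchStrategy(enum.Enum):
    EXACT = "exact"
    FLEXIBLE = "flexible"


@dataclass
class MatchResult:
    """Signals mapped against a knowledge base under one strategy."""

    strategy: MatchStrategy
    discovered: set[str]
    confirmed: set[str]
    matched: set[str]
    confirmed_exact: set[str]

    def __post_init__(self) -> None:
        if not self.matched <= self.discovered:
            raise ValueError("matched must be a subset of discovered")
        if not self.matched <= self.confirmed:
            raise ValueError("matched must be a subset of confirmed")


@dataclass(frozen=True)
class EvaluationResult:
    precision: float
    recall: float
    f1: float
    n_discovered: int
    n_confirmed: int
    n_matched: int

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_discovered": self.n_discovered,
            "n_confirmed": self.n_confirmed,
            "n_matched": self.n_matched,
        }


@dataclass(frozen=True)
class VennPartition:
    """Cardinalities of the 7 regions of (FAERS, EMR, knowledge base)."""

    faers_only: int
    emr_only: int
    kb_only: int
    faers_emr: int
    faers_kb: int
    emr_kb: int
    all: int

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in VENN_REGIONS}

    def set_total(self, which: str) -> int:
        """Reconstruct one input set's cardinality from its 4 regions."""
        if which == "faers":
            return self.faers_only + self.faers_emr + self.faers_kb + self.all
        if which == "emr":
            return self.emr_only + self.faers_emr + self.emr_kb + self.all
        if which == "kb":
            return self.kb_only + self.faers_kb + self.emr_kb + self.all
        raise ValueError(f"unknown set {which!r}")


def _as_cui_set(obj: Union[SignalSet, set[str], frozenset[str]]) -> set[str]:
    if isinstance(obj, SignalSet):
        return obj.flagged()
    return set(obj)


def match_signals(
    signals: Union[SignalSet, set[str]],
    kb: KnowledgeBase,
    hierarchy: Optional[Hierarchy],
    strategy: Union[MatchStrategy, str] = MatchStrategy.EXACT,
) -> MatchResult:
    """Map flagged signal CUIs onto a knowledge base.

    Under ``FLEXIBLE`` the confirmed side is expanded downward through the
    hierarchy before intersecting; the discovered side is never expanded.
    Each discovered CUI counts at most once however many knowledge-base
    parents cover it.
    """
    strategy = MatchStrategy(strategy) if isinstance(strategy, str) else strategy
    discovered = _as_cui_set(signals)
    exact_cuis = kb.cuis()
    if strategy is MatchStrategy.FLEXIBLE:
        if hierarchy is None:
            raise ValueError("flexible matching requires a hierarchy")
        confirmed = expand_kb_flexible(kb, hierarchy)
    else:
        confirmed = set(exact_cuis)
    return MatchResult(
        strategy=strategy,
        discovered=discovered,
        confirmed=confirmed,
        matched=discovered & confirmed,
        confirmed_exact=set(exact_cuis),
    )


def compute_metrics(match: MatchResult) -> EvaluationResult:
    """Precision, recall and F1 of a match result.

    precision = |matched| / |discovered|; recall = |matched| / |confirmed|
    with the un-expanded confirmed set as denominator (capped at 1 in the
    rare case flexible matching matches more discovered terms than the
    knowledge base has entries); F1 is the harmonic mean of the two.  Empty
    denominators yield zeros with a warning rather than an error.
    """
    n_disc = len(match.discovered)
    n_conf = len(match.confirmed_exact)
    n_match = len(match.matched)
    if n_disc == 0 and n_conf == 0:
        logger.warning("nothing discovered and nothing confirmed; metrics all zero")
        return EvaluationResult(0.0, 0.0, 0.0, 0, 0, 0)
    precision = n_match / n_disc if n_disc else 0.0
    recall = min(1.0, n_match / n_conf) if n_conf else 0.0
    if precision + recall == 0.0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return EvaluationResult(precision, recall, f1, n_disc, n_conf, n_match)


def combine_sources(s_faers: SignalSet, s_emr: SignalSet) -> SignalSet:
    """Union of the flagged outcomes of the two sources.

    Per-outcome provenance is retained in ``per_source``; when both sources
    flag an outcome both scores are kept and the patient-record score is the
    representative entry (it carries a p-value and drives downstream
    ranking).
    """
    if (s_faers.drug, s_faers.indication) != (s_emr.drug, s_emr.indication):
        raise ValueError(
            "cannot combine signal sets for different (drug, indication) pairs: "
            f"({s_faers.drug}, {s_faers.indication}) vs ({s_emr.drug}, {s_emr.indication})"
        )
    combined = SignalSet(
        drug=s_faers.drug, indication=s_faers.indication, source=Source.COMBINED
    )
    for cui in sorted(s_faers.flagged() | s_emr.flagged()):
        per_source: dict[str, object] = {}
        if cui in s_emr.flagged():
            per_source[Source.EMR.value] = s_emr.entries[cui]
        if cui in s_faers.flagged():
            per_source[Source.FAERS.value] = s_faers.entries[cui]
        combined.per_source[cui] = per_source  # type: ignore[assignment]
        combined.entries[cui] = (
            per_source.get(Source.EMR.value) or per_source[Source.FAERS.value]
        )  # type: ignore[assignment]
    return combined


def venn_partition(
    s_faers: Union[SignalSet, set[str]],
    s_emr: Union[SignalSet, set[str]],
    kb_cuis: Union[KnowledgeBase, set[str]],
) -> VennPartition:
    """Cardinalities of the 7 regions of the three CUI sets."""
    f = _as_cui_set(s_faers)
    e = _as_cui_set(s_emr)
    k = kb_cuis.cuis() if isinstance(kb_cuis, KnowledgeBase) else set(kb_cuis)
    return VennPartition(
        faers_only=len(f - e - k),
        emr_only=len(e - f - k),
        kb_only=len(k - f - e),
        faers_emr=len((f & e) - k),
        faers_kb=len((f & k) - e),
        emr_kb=len((e & k) - f),
        all=len(f & e & k),
    )


def novel_candidates(
    s_combined: SignalSet,
    kb_cuis_flexible: set[str],
    top_k: Optional[int] = 10,
) -> pd.DataFrame:
    """Rank flagged outcomes absent from the (expanded) knowledge base.

    These are the novel-ADE hypotheses: possibly false positives, possibly
    real adverse events not yet recorded.  Sorted by descending odds ratio
    (the patient-record OR when present, else the report ROR), ties by
    ascending p then CUI; ``top_k=None`` returns the full table.
    """
    rows = []
    for cui in s_combined.flagged():
        if cui in kb_cuis_flexible:
            continue
        score = s_combined.entries[cui]
        sources = sorted(s_combined.per_source.get(cui, {Source.COMBINED.value: score}))
        p = score.p_value if score.p_value is not None else math.inf
        rows.append(
            (
                cui,
                "+".join(sources),
                score.estimate,
                score.ci_low,
                score.ci_high,
                score.p_value,
                score.p_bonferroni,
                p,
            )
        )
    rows.sort(key=lambda r: (-r[2], r[7], r[0]))
    df = pd.DataFrame([r[:7] for r in rows], columns=NOVEL_TSV_COLUMNS)
    if top_k is not None:
        df = df.head(top_k)
    return df.reset_index(drop=True)


def evaluate_all(
    s_faers: SignalSet,
    s_emr: SignalSet,
    kb: KnowledgeBase,
    hierarchy: Optional[Hierarchy],
) -> dict[str, dict[str, dict[str, float]]]:
    """Exact and flexible metrics for each source and their combination."""
    combined = combine_sources(s_faers, s_emr)
    out: dict[str, dict[str, dict[str, float]]] = {}
    for strategy in MatchStrategy:
        per_source = {}
        for name, signals in [
            ("faers", s_faers),
            ("emr", s_emr),
            ("combined", combined),
        ]:
            match = match_signals(signals, kb, hierarchy, strategy)
            per_source[name] = compute_metrics(match).as_dict()
        out[strategy.value] = per_source
    return out
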
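"""Synthetic pharmacovigilance data with planted drug-ADE effects.

Everything the pipeline consumes can be generated here: a 5-level term
hierarchy, SIDER- and ADReCS-dialect knowledge-base files, spontaneous
report tables, and longitudinal patient timelines.  Effects are *planted*
with known analytic strength so that detection, mapping and evaluation can
be tested end to end against ground truth:

* In report tables, a planted (drug, outcome, target ROR) triple sets the
  outcome's conditional probability on exposed reports so that the odds
  ratio of the implied cell probabilities equals the target exactly.
* In timelines, a planted (drug, outcome, p_case, p_control) triple draws
  one Bernoulli occurrence per window, giving the closed-form truth
  OR = (p_case * (1 - p_control)) / ((1 - p_case) * p_control).
  Non-planted outcomes use one background probability in both windows, so
  their truth OR is exactly 1.

A single master seed derives independent per-stream generators, so
regenerating one table never perturbs the others, and equal seeds give
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import emr, faers
from .vocab import (
    ADRECS_COLUMNS,
    SIDER_COLUMNS,
    Hierarchy,
    Level,
    Term,
    _build_hierarchy,
)

RACE_CATEGORIES = [
    "American Indian/Alaskan Native",
    "Asian",
    "Black or African American",
    "White",
    "Other",
    "Unknown",
    "Choose not to disclose",
]
RACE_PROBS = [0.008, 0.010, 0.009, 0.870, 0.016, 0.082, 0.005]

SCENARIO_FILES = [
    "hierarchy.tsv",
    "kb_sider_indications.tsv",
    "kb_sider_se.tsv",
    "kb_adrecs.tsv",
    "reports.tsv",
    "events.tsv",
    "demographics.tsv",
    "truth.json",
]


class ConfigError(ValueError):
    """Infeasible synthetic-data configuration (an implied probability
    outside (0, 1), or a non-positive target odds ratio)."""


@dataclass(frozen=True)
class PlantedReportEffect:
    """Planted disproportionality: the outcome's odds on exposed reports are
    ``target_ror`` times its background odds."""

    drug: str
    outcome_cui: str
    target_ror: float

    def exposed_probability(self, background_prob: float) -> float:
        """P(outcome | exposed) implied by the target ROR."""
        odds = self.target_ror * background_prob / (1.0 - background_prob)
        return odds / (1.0 + odds)


@dataclass(frozen=True)
class PlantedTimelineEffect:
    """Planted per-window occurrence probabilities for one outcome."""

    drug: str
    outcome_cui: str
    p_case: float
    p_control: float

    @property
    def truth_or(self) -> float:
        return (self.p_case * (1.0 - self.p_control)) / ((1.0 - self.p_case) * self.p_control)


@dataclass
class SyntheticConfig:
    """All knobs of one synthetic scenario.

    The defaults define the bundled study conditions: 5,000 reports and
    2,000 patients observed over 20 years, a (2,3,3,3)-branching hierarchy,
    five planted adverse events (report ROR 8, per-window probabilities
    0.3 vs 0.1), three of them recorded in the knowledge bases — one only at
    its parent preferred term, so flexible mapping is exercised — and two
    left novel.
    """

    seed: int = 0
    hierarchy_shape: tuple[int, ...] = (2, 3, 3, 3)
    n_reports: int = 5000
    n_patients: int = 2000
    n_outcomes: int = 20

    drug: str = "RX001"
    other_drugs: tuple[str, ...] = ("RX101", "RX102", "RX103")
    stitch_id: str = "CID100000001"
    indication_name: str = "Rheumatoid arthritis"
    decoy_indication_name: str = "Psoriasis"

    # Report generation.
    p_exposed: float = 0.10
    indication_rate_exposed: float = 0.90
    indication_rate_background: float = 0.20
    background_reaction_prob: float = 0.02
    report_effects: tuple[PlantedReportEffect, ...] = ()

    # Timeline generation.
    observation_span_days: int = 7300  # 20 years of records
    dx_latest_day: int = 2000
    exposure_gap_days: tuple[int, int] = (30, 1460)
    exposure_span_days: tuple[int, int] = (180, 2500)
    background_mention_rate: float = 0.05  # expected mentions per patient-year
    noncohort_fraction: float = 0.10
    noise_mention_prob: float = 0.02  # off-semantic-type mentions, dropped by the filter
    timeline_effects: tuple[PlantedTimelineEffect, ...] = ()

    # Knowledge-base composition (indices into the outcome CUI pool).
    kb_exact_outcomes: tuple[int, ...] = (0, 3)
    kb_parent_outcomes: tuple[int, ...] = (6,)
    n_kb_extra: int = 3
    n_decoy_terms: int = 2

    def validate(self) -> None:
        if not 0.0 < self.background_reaction_prob < 1.0:
            raise ConfigError(
                f"background reaction probability {self.background_reaction_prob} outside (0, 1)"
            )
        if not 0.0 < self.p_exposed < 1.0:
            raise ConfigError(f"exposure probability {self.p_exposed} outside (0, 1)")
        for eff in self.report_effects:
            if eff.target_ror <= 0:
                raise ConfigError(f"target ROR must be positive, got {eff.target_ror}")
            p1 = eff.exposed_probability(self.background_reaction_prob)
            if not 0.0 < p1 < 1.0:
                raise ConfigError(
                    f"implied exposed probability {p1} outside (0, 1) for {eff.outcome_cui}"
                )
        for eff in self.timeline_effects:
            for p in (eff.p_case, eff.p_control):
                if not 0.0 < p < 1.0:
                    raise ConfigError(
                        f"window probability {p} outside (0, 1) for {eff.outcome_cui}"
                    )
        if any(b < 1 for b in self.hierarchy_shape) or len(self.hierarchy_shape) != 4:
            raise ConfigError("hierarchy_shape must be four branching factors >= 1")


def _streams(cfg: SyntheticConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(3)
    names = ["reports", "timelines", "kb"]
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# Hierarchy


def gen_hierarchy(cfg: SyntheticConfig) -> Hierarchy:
    """Perfect multi-way tree over SOC -> HLGT -> HLT -> PT -> LLT.

    Codes and CUIs are assigned breadth-first and depend only on the shape,
    so the hierarchy is fully deterministic.
    """
    cfg.validate()
    levels = [Level.SOC, Level.HLGT, Level.HLT, Level.PT, Level.LLT]
    rows: list[tuple[str, str, str, str, str]] = []
    counter = 0

    def code_of(i: int) -> str:
        return f"MD{i:06d}"

    def cui_of(i: int) -> str:
        return f"C{i:07d}"

    current = [(code_of(0), cui_of(0))]
    rows.append((code_of(0), cui_of(0), Level.SOC.name, "SOC term 0", ""))
    counter = 1
    for depth, branching in enumerate(cfg.hierarchy_shape):
        level = levels[depth + 1]
        nxt = []
        for parent_code, _ in current:
            for _ in range(branching):
                code, cui = code_of(counter), cui_of(counter)
                rows.append((code, cui, level.name, f"{level.name} term {counter}", parent_code))
                nxt.append((code, cui))
                counter += 1
        current = nxt
    df = pd.DataFrame(
        rows, columns=["meddra_code", "cui", "level", "name", "parent_code"]
    )
    return _build_hierarchy(df)


@dataclass
class ScenarioVocab:
    """The concept roles a scenario assigns within its hierarchy."""

    indication_cui: str
    indication_code: str
    outcome_cuis: list[str]
    kb_extra_cuis: list[str]
    decoy_cuis: list[str]


def scenario_vocab(cfg: SyntheticConfig, hierarchy: Hierarchy) -> ScenarioVocab:
    """Assign hierarchy leaves to roles: indication, outcome pool, extras."""
    leaves = sorted(
        code for code, term in hierarchy.terms.items() if term.level is Level.LLT
    )
    needed = 1 + cfg.n_outcomes + cfg.n_kb_extra + cfg.n_decoy_terms
    if len(leaves) < needed:
        raise ConfigError(
            f"hierarchy has {len(leaves)} leaves but the scenario needs {needed}"
        )
    cui = lambda code: hierarchy.terms[code].cui  # noqa: E731
    k = 1 + cfg.n_outcomes
    return ScenarioVocab(
        indication_cui=cui(leaves[0]),
        indication_code=leaves[0],
        outcome_cuis=[cui(c) for c in leaves[1:k]],
        kb_extra_cuis=[cui(c) for c in leaves[k : k + cfg.n_kb_extra]],
        decoy_cuis=[cui(c) for c in leaves[k + cfg.n_kb_extra : k + cfg.n_kb_extra + cfg.n_decoy_terms]],
    )


def default_config(
    seed: int = 0, n_reports: int = 5000, n_patients: int = 2000
) -> SyntheticConfig:
    """The bundled scenario: five planted adverse events, three in the KB.

    Planted strengths are the scenario's study conditions: report ROR 8 and
    per-window probabilities 0.3 (case) vs 0.1 (control), i.e. truth OR
    27/7.
    """
    cfg = SyntheticConfig(seed=seed, n_reports=n_reports, n_patients=n_patients)
    hierarchy = gen_hierarchy(cfg)
    vocab = scenario_vocab(cfg, hierarchy)
    # Planted outcomes sit under five different preferred terms so that the
    # parent-level knowledge-base entry expands over exactly one of them and
    # the two novel outcomes stay outside every expansion.
    planted = [vocab.outcome_cuis[i] for i in (0, 3, 6, 9, 12)]
    cfg.report_effects = tuple(
        PlantedReportEffect(cfg.drug, cui, target_ror=8.0) for cui in planted
    )
    cfg.timeline_effects = tuple(
        PlantedTimelineEffect(cfg.drug, cui, p_case=0.30, p_control=0.10) for cui in planted
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Spontaneous reports


def gen_reports(
    cfg: SyntheticConfig,
    vocab: ScenarioVocab,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw a spontaneous-report table with the configured planted effects.

    Returns the report DataFrame (same in-memory dialect as
    :func:`pharmsig.faers.read_reports_tsv`) and a truth record holding each
    planted pair's analytic cell probabilities and target ROR.
    """
    cfg.validate()
    rng = rng if rng is not None else _streams(cfg)["reports"]
    n = cfg.n_reports
    q = cfg.background_reaction_prob
    effects = {e.outcome_cui: e for e in cfg.report_effects if e.drug == cfg.drug}

    exposed = rng.random(n) < cfg.p_exposed
    extra_drug = rng.integers(0, len(cfg.other_drugs), size=n)
    with_extra = rng.random(n) < 0.3
    has_ind = np.where(
        exposed,
        rng.random(n) < cfg.indication_rate_exposed,
        rng.random(n) < cfg.indication_rate_background,
    )

    reaction_sets: list[set[str]] = [set() for _ in range(n)]
    truth_effects = []
    for cui in vocab.outcome_cuis:
        eff = effects.get(cui)
        if eff is None:
            hit = rng.random(n) < q
        else:
            p1 = eff.exposed_probability(q)
            hit = rng.random(n) < np.where(exposed, p1, q)
            truth_effects.append(
                {
                    "drug": eff.drug,
                    "outcome_cui": cui,
                    "target_ror": eff.target_ror,
                    "cell_probabilities": {
                        "p_a": cfg.p_exposed * p1,
                        "p_b": cfg.p_exposed * (1.0 - p1),
                        "p_c": (1.0 - cfg.p_exposed) * q,
                        "p_d": (1.0 - cfg.p_exposed) * (1.0 - q),
                    },
                }
            )
        for i in np.flatnonzero(hit):
            reaction_sets[i].add(cui)

    gender = rng.choice(["F", "M", "U"], size=n, p=[0.70, 0.25, 0.05])
    age = np.clip(rng.normal(55.0, 15.0, size=n).round(0), 0, 100)
    age_missing = rng.random(n) < 0.05

    rows = []
    for i in range(n):
        if exposed[i]:
            drugs = {cfg.drug}
            if with_extra[i]:
                drugs.add(cfg.other_drugs[extra_drug[i]])
        else:
            drugs = {cfg.other_drugs[extra_drug[i]]}
        rows.append(
            (
                f"R{i:06d}",
                frozenset(drugs),
                frozenset(reaction_sets[i]),
                frozenset({vocab.indication_cui}) if has_ind[i] else frozenset(),
                gender[i],
                np.nan if age_missing[i] else float(age[i]),
            )
        )
    reports = pd.DataFrame(rows, columns=faers.REPORT_COLUMNS)
    truth = {"report_effects": truth_effects}
    return reports, truth


# ---------------------------------------------------------------------------
# Patient timelines


def gen_timelines(
    cfg: SyntheticConfig,
    vocab: ScenarioVocab,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw event and demographics tables with planted per-window effects.

    Cohort patients get a diagnosis day, a first and a last exposure day
    (diagnosis strictly first), and one Bernoulli occurrence draw per
    (outcome, window).  The background occurrence probability is identical
    in both windows by design — ``1 - exp(-background_mention_rate)`` over a
    nominal patient-year — so every non-planted outcome has truth OR 1.  A
    configurable fraction of patients violate the cohort definition (no
    exposure, or exposure before diagnosis) and must be excluded upstream.
    """
    cfg.validate()
    rng = rng if rng is not None else _streams(cfg)["timelines"]
    n = cfg.n_patients
    pids = np.array([f"P{i:05d}" for i in range(n)])
    effects = {e.outcome_cui: e for e in cfg.timeline_effects if e.drug == cfg.drug}
    p_bg = 1.0 - math.exp(-cfg.background_mention_rate)
    allowed = sorted(emr.DEFAULT_SEMANTIC_TYPES)

    u = rng.random(n)
    kind = np.where(
        u < 1.0 - cfg.noncohort_fraction,
        0,  # cohort
        np.where(u < 1.0 - cfg.noncohort_fraction / 2.0, 1, 2),  # no-exposure / reversed
    )
    dx = rng.integers(0, cfg.dx_latest_day, size=n)
    gap = rng.integers(*cfg.exposure_gap_days, size=n)
    span = rng.integers(*cfg.exposure_span_days, size=n)
    t_first = dx + gap
    t_last = np.minimum(t_first + span, cfg.observation_span_days - 1)
    # Reversed patients: exposure precedes diagnosis, so no control window.
    t_first = np.where(kind == 2, np.maximum(dx - gap, 0), t_first)
    t_last = np.where(kind == 2, np.maximum(dx - 1, t_first), t_last)

    frames: list[pd.DataFrame] = []

    def add(pid_arr, date_arr, kind_name, code_arr, sem_arr) -> None:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid_arr,
                    "date": np.asarray(date_arr, dtype="int64"),
                    "kind": kind_name,
                    "code": code_arr,
                    "semantic_type": sem_arr,
                }
            )
        )

    add(pids, dx, "DIAGNOSIS", vocab.indication_cui, "T047")
    exposed_mask = kind != 1
    add(pids[exposed_mask], t_first[exposed_mask], "DRUG_EXPOSURE", cfg.drug, "")
    multi = exposed_mask & (t_last > t_first)
    add(pids[multi], t_last[multi], "DRUG_EXPOSURE", cfg.drug, "")

    cohort = kind == 0
    truth_effects = []
    for cui in vocab.outcome_cuis:
        eff = effects.get(cui)
        pc, pk = (eff.p_case, eff.p_control) if eff else (p_bg, p_bg)
        if eff is not None:
            truth_effects.append(
                {
                    "drug": eff.drug,
                    "outcome_cui": cui,
                    "p_case": eff.p_case,
                    "p_control": eff.p_control,
                    "truth_or": eff.truth_or,
                }
            )
        case_hit = cohort & (rng.random(n) < pc)
        ctrl_hit = cohort & (rng.random(n) < pk)
        case_day = rng.integers(t_first, t_last + 1)
        ctrl_day = rng.integers(dx, np.maximum(t_first, dx + 1))
        sem = rng.choice(allowed, size=n)
        add(pids[case_hit], case_day[case_hit], "CONCEPT_MENTION", cui, sem[case_hit])
        add(pids[ctrl_hit], ctrl_day[ctrl_hit], "CONCEPT_MENTION", cui, sem[ctrl_hit])

    # Off-type noise mentions that the semantic filter must drop.
    noise = rng.random(n) < cfg.noise_mention_prob
    noise_cui = rng.choice(vocab.outcome_cuis, size=n)
    noise_day = rng.integers(0, cfg.observation_span_days, size=n)
    add(pids[noise], noise_day[noise], "CONCEPT_MENTION", noise_cui[noise], "T121")

    events = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["patient_id", "date", "kind", "code"], kind="stable")
        .reset_index(drop=True)
    )

    demographics = pd.DataFrame(
        {
            "patient_id": pids,
            "gender": rng.choice(["F", "M", "U"], size=n, p=[0.69, 0.30, 0.01]),
            "race": rng.choice(
                RACE_CATEGORIES, size=n, p=np.array(RACE_PROBS) / sum(RACE_PROBS)
            ),
        }
    )
    truth = {
        "timeline_effects": truth_effects,
        "background_window_probability": p_bg,
        "n_cohort": int(cohort.sum()),
    }
    return events, demographics, truth


# ---------------------------------------------------------------------------
# Knowledge bases


def gen_kb(
    cfg: SyntheticConfig, hierarchy: Hierarchy, vocab: ScenarioVocab
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """SIDER- and ADReCS-dialect knowledge-base files for the scenario drug.

    The indication-matched label carries the configured mixture of exact
    LLT terms and parent-level PT terms (so flexible mapping has work to
    do) plus a few confirmed ADEs outside the outcome pool; a decoy label
    with a different indication carries terms that must never leak into the
    indication-restricted extraction.
    """
    term_of = {t.cui: t for t in hierarchy.terms.values()}

    def parent_pt(cui: str) -> Term:
        code = hierarchy.code_for_cui(cui)
        parents = list(hierarchy.graph.predecessors(code))
        return hierarchy.terms[sorted(parents)[0]]

    exact_terms = [term_of[vocab.outcome_cuis[i]] for i in cfg.kb_exact_outcomes]
    parent_terms = [parent_pt(vocab.outcome_cuis[i]) for i in cfg.kb_parent_outcomes]
    extra_terms = [term_of[c] for c in vocab.kb_extra_cuis]
    kb_terms = exact_terms + parent_terms + extra_terms
    decoy_terms = [term_of[c] for c in vocab.decoy_cuis]

    ind_term = term_of[vocab.indication_cui]
    decoy_ind = Term(
        cui="C9000001", meddra_code="MD900001", level=Level.LLT, name=cfg.decoy_indication_name
    )

    def sider_row(label: str, term: Term, name: str) -> tuple:
        return (label, cfg.stitch_id, cfg.stitch_id.replace("CID1", "CID0"), term.cui,
                term.level.name, term.meddra_code, name)

    indications = pd.DataFrame(
        [
            sider_row("L001", ind_term, cfg.indication_name),
            sider_row("L002", decoy_ind, cfg.decoy_indication_name),
        ],
        columns=SIDER_COLUMNS,
    )
    se_rows = [sider_row("L001", t, t.name) for t in kb_terms]
    se_rows += [sider_row("L002", t, t.name) for t in decoy_terms]
    side_effects = pd.DataFrame(se_rows, columns=SIDER_COLUMNS)

    adrecs = pd.DataFrame(
        [(cfg.drug, t.name, t.meddra_code, t.cui) for t in kb_terms],
        columns=ADRECS_COLUMNS,
    )

    covered = [vocab.outcome_cuis[i] for i in cfg.kb_exact_outcomes + cfg.kb_parent_outcomes]
    planted = sorted({e.outcome_cui for e in cfg.report_effects}
                     | {e.outcome_cui for e in cfg.timeline_effects})
    truth = {
        "kb_cuis": sorted(t.cui for t in kb_terms),
        "kb_covered_planted_cuis": sorted(set(covered) & set(planted)),
        "novel_planted_cuis": sorted(set(planted) - set(covered)),
        "decoy_cuis": sorted(t.cui for t in decoy_terms),
    }
    return indications, side_effects, adrecs, truth


# ---------------------------------------------------------------------------
# Whole scenario


@dataclass
class Scenario:
    """All in-memory artifacts of one generated scenario."""

    config: SyntheticConfig
    hierarchy: Hierarchy
    vocab: ScenarioVocab
    reports: pd.DataFrame
    events: pd.DataFrame
    demographics: pd.DataFrame
    kb_sider_indications: pd.DataFrame
    kb_sider_se: pd.DataFrame
    kb_adrecs: pd.DataFrame
    truth: dict = field(default_factory=dict)


def generate_scenario(
    cfg: SyntheticConfig, out_dir: Optional[Union[str, Path]] = None
) -> Scenario:
    """Generate every scenario artifact, optionally writing the file set."""
    cfg.validate()
    streams = _streams(cfg)
    hierarchy = gen_hierarchy(cfg)
    vocab = scenario_vocab(cfg, hierarchy)
    reports, truth_r = gen_reports(cfg, vocab, streams["reports"])
    events, demographics, truth_t = gen_timelines(cfg, vocab, streams["timelines"])
    kb_ind, kb_se, kb_adrecs, truth_k = gen_kb(cfg, hierarchy, vocab)
    truth = {
        "seed": cfg.seed,
        "drug": cfg.drug,
        "indication_cui": vocab.indication_cui,
        "indication_name": cfg.indication_name,
        "outcome_cuis": vocab.outcome_cuis,
        **truth_r,
        **truth_t,
        **truth_k,
    }
    scenario = Scenario(
        config=cfg,
        hierarchy=hierarchy,
        vocab=vocab,
        reports=reports,
        events=events,
        demographics=demographics,
        kb_sider_indications=kb_ind,
        kb_sider_se=kb_se,
        kb_adrecs=kb_adrecs,
        truth=truth,
    )
    if out_dir is not None:
        write_scenario(scenario, out_dir)
    return scenario


def write_scenario(scenario: Scenario, out_dir: Union[str, Path]) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for name in SCENARIO_FILES}
    scenario.hierarchy.to_tsv(paths["hierarchy.tsv"])
    scenario.kb_sider_indications.to_csv(paths["kb_sider_indications.tsv"], sep="\t", index=False)
    scenario.kb_sider_se.to_csv(paths["kb_sider_se.tsv"], sep="\t", index=False)
    scenario.kb_adrecs.to_csv(paths["kb_adrecs.tsv"], sep="\t", index=False)
    faers.write_reports_tsv(scenario.reports, paths["reports.tsv"])
    scenario.events.to_csv(paths["events.tsv"], sep="\t", index=False)
    scenario.demographics.to_csv(paths["demographics.tsv"], sep="\t", index=False)
    with open(paths["truth.json"], "w") as fh:
        json.dump(scenario.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def config_to_dict(cfg: SyntheticConfig) -> dict:
    return asdict(cfg)
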
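"""End-to-end orchestration: synth -> detect (x2) -> evaluate -> report.

A single declarative run configuration drives every stage for each drug in
the drug list and writes per-drug artifacts: signal tables for both
sources, exact and flexible evaluation metrics per source and combined,
the three-way Venn partition, the ranked novel-ADE hypotheses, and a
demographics summary.  Every default a run resolves
(z quantile, p-value method, minimum counts, mapping strategy, top-k) is
echoed into the run log so results are reproducible from the log alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import emr, evaluate, faers, synth, vocab

logger = logging.getLogger(__name__)

ARTIFACT_NAMES = [
    "signals_faers.tsv",
    "signals_emr.tsv",
    "metrics.json",
    "venn.json",
    "novel.tsv",
    "demographics.json",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def fm_ratio(n_female: int, n_male: int) -> Optional[float]:
    """Female:male ratio rounded half-up to one decimal; None when no males."""
    if n_male == 0:
        return None
    return _round_half_up(n_female / n_male, 1)


def pct(numerator: int, denominator: int) -> Optional[float]:
    """Percentage rounded half-up to one decimal; None for a zero denominator."""
    if denominator == 0:
        return None
    return _round_half_up(100.0 * numerator / denominator, 1)


def demographics_summary(
    table: pd.DataFrame, drug: Optional[str] = None, source: str = "faers"
) -> dict:
    """Table-1-style gender/race breakdown for one drug and source.

    For report data (``source="faers"``) the percentage denominator is the
    full report count including unknown gender, so the two gender
    percentages need not sum to 100.  For patient data (``source="emr"``)
    percentages are taken over the female+male sum, and race categories are
    also tallied.  The F:M ratio is rounded half-up to one decimal and is
    None when there are no males.
    """
    if source == "faers":
        rows = table
        if drug is not None:
            rows = table[table["drug_ids"].map(lambda s: drug in s)]
        gender = rows["gender"].value_counts()
        n_f, n_m = int(gender.get("F", 0)), int(gender.get("M", 0))
        total = len(rows)
        denom = total
        race_counts = None
    elif source == "emr":
        rows = table
        gender = rows["gender"].value_counts()
        n_f, n_m = int(gender.get("F", 0)), int(gender.get("M", 0))
        total = len(rows)
        denom = n_f + n_m
        race_counts = {cat: int((rows["race"] == cat).sum()) for cat in sorted(rows["race"].unique())}
    else:
        raise ValueError(f"unknown source {source!r}")

    summary = {
        "source": source,
        "drug": drug,
        "n_female": n_f,
        "n_male": n_m,
        "pct_female": pct(n_f, denom),
        "pct_male": pct(n_m, denom),
        "fm_ratio": fm_ratio(n_f, n_m),
        "total": total,
    }
    if race_counts is not None:
        summary["race"] = race_counts
        if sum(race_counts.values()) != total:
            raise ValueError("race categories do not sum to the patient total")
    return summary


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Either ``synthetic: true`` (the bundled generator supplies all inputs)
    or explicit input paths.  Thresholds default to the package-wide
    defaults and are echoed into the run log.
    """

    out_dir: Path
    drugs: list[str]
    indication: str
    indication_name: str = ""
    synthetic: bool = True
    seed: int = 0
    n_reports: int = 5000
    n_patients: int = 2000
    reports_path: Optional[Path] = None
    events_path: Optional[Path] = None
    demographics_path: Optional[Path] = None
    hierarchy_path: Optional[Path] = None
    sider_indications_path: Optional[Path] = None
    sider_se_path: Optional[Path] = None
    adrecs_path: Optional[Path] = None
    kb_source: str = "sider"
    kb_drug_id: str = ""
    min_a: int = 1
    min_patients: int = 1
    z: float = 1.96
    p_method: str = "auto"
    bonferroni_m: Optional[int] = None
    comparator: str = "all"
    strategy: str = "both"
    top_k: int = 10
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["out_dir"] = Path(raw["out_dir"])
        for key in list(raw):
            if key.endswith("_path") and raw[key] is not None:
                raw[key] = Path(raw[key])
        cfg = cls(**raw)
        if not cfg.drugs:
            raise ValueError("drug list must be non-empty")
        if not cfg.synthetic:
            for key in ("reports_path", "events_path", "hierarchy_path"):
                p = getattr(cfg, key)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{key} missing or does not exist: {p}")
        return cfg

    def resolved_defaults(self) -> dict:
        return {
            "min_a": self.min_a,
            "min_patients": self.min_patients,
            "z": self.z,
            "p_method": self.p_method,
            "bonferroni_m": self.bonferroni_m,
            "comparator": self.comparator,
            "strategy": self.strategy,
            "top_k": self.top_k,
            "seed": self.seed,
        }


def _versions() -> dict[str, str]:
    import numpy
    import scipy

    from . import __version__

    return {
        "pharmsig": __version__,
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic:
        scn = synth.generate_scenario(
            synth.default_config(
                seed=cfg.seed, n_reports=cfg.n_reports, n_patients=cfg.n_patients
            )
        )
        kb = vocab.KnowledgeBase(
            drug_id=scn.config.drug,
            indication=scn.config.indication_name,
            ade_terms=vocab.kb_terms_from_cuis(
                scn.truth["kb_cuis"], scn.hierarchy
            ).ade_terms,
            provenance=vocab.Provenance.SYNTHETIC,
        )
        return scn.reports, scn.events, scn.demographics, scn.hierarchy, kb
    reports = faers.read_reports_tsv(cfg.reports_path)
    events = emr.read_events_tsv(cfg.events_path)
    demographics = (
        emr.read_demographics_tsv(cfg.demographics_path)
        if cfg.demographics_path
        else None
    )
    hierarchy = vocab.load_hierarchy(cfg.hierarchy_path)
    if cfg.kb_source == "sider":
        kb = vocab.load_sider_kb(
            cfg.sider_indications_path,
            cfg.sider_se_path,
            cfg.kb_drug_id,
            cfg.indication_name,
        )
    else:
        kb = vocab.load_adrecs_kb(cfg.adrecs_path, cfg.kb_drug_id, hierarchy)
    return reports, events, demographics, hierarchy, kb


def run_pipeline(cfg: RunConfig) -> dict[str, dict[str, Path]]:
    """Run every stage for every drug; abort cleanly on stage failure.

    Returns ``{drug: {artifact name: path}}``.  On failure the partially
    written outputs of the failing run are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load inputs"
    try:
        reports, events, demographics, hierarchy, kb = _load_inputs(cfg)
        artifacts: dict[str, dict[str, Path]] = {}
        for drug in cfg.drugs:
            drug_dir = out_root / drug
            drug_dir.mkdir(parents=True, exist_ok=True)
            paths = {name: drug_dir / name for name in ARTIFACT_NAMES}

            stage = f"FAERS detection ({drug})"
            s_faers = faers.detect_signals_faers(
                reports,
                drug,
                cfg.indication,
                min_a=cfg.min_a,
                z=cfg.z,
                comparator=cfg.comparator,
            )
            faers.write_signals_tsv(s_faers, paths["signals_faers.tsv"])
            written.append(paths["signals_faers.tsv"])

            stage = f"EMR detection ({drug})"
            s_emr = emr.detect_signals_emr(
                events,
                drug,
                cfg.indication,
                min_patients=cfg.min_patients,
                z=cfg.z,
                p_method=cfg.p_method,
                bonferroni_m=cfg.bonferroni_m,
                hierarchy=hierarchy,
            )
            emr.write_signals_tsv(s_emr, paths["signals_emr.tsv"])
            written.append(paths["signals_emr.tsv"])

            stage = f"evaluation ({drug})"
            metrics = evaluate.evaluate_all(s_faers, s_emr, kb, hierarchy)
            if cfg.strategy in ("exact", "flexible"):
                metrics = {cfg.strategy: metrics[cfg.strategy]}
            _dump_json(metrics, paths["metrics.json"])
            written.append(paths["metrics.json"])

            venn = evaluate.venn_partition(s_faers, s_emr, kb.cuis())
            _dump_json(venn.as_dict(), paths["venn.json"])
            written.append(paths["venn.json"])

            combined = evaluate.combine_sources(s_faers, s_emr)
            expanded = vocab.expand_kb_flexible(kb, hierarchy)
            novel = evaluate.novel_candidates(combined, expanded, top_k=cfg.top_k)
            novel.to_csv(paths["novel.tsv"], sep="\t", index=False, float_format="%.6g")
            written.append(paths["novel.tsv"])

            stage = f"demographics ({drug})"
            demo = {"faers": demographics_summary(reports, drug, source="faers")}
            if demographics is not None:
                cohort = emr.extract_cohort(events, drug, cfg.indication)
                cohort_demo = demographics[
                    demographics["patient_id"].isin(cohort["patient_id"])
                ]
                demo["emr"] = demographics_summary(cohort_demo, drug, source="emr")
            _dump_json(demo, paths["demographics.json"])
            written.append(paths["demographics.json"])
            artifacts[drug] = paths

        stage = "run log"
        log_path = out_root / "run_log.json"
        _dump_json(
            {
                "versions": _versions(),
                "resolved_defaults": cfg.resolved_defaults(),
                "drugs": cfg.drugs,
                "indication": cfg.indication,
                "synthetic": cfg.synthetic,
            },
            log_path,
        )
        artifacts["_run"] = {"run_log.json": log_path}
        return artifacts
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"pipeline failed at stage: {stage}: {exc}") from exc


def _dump_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def default_synthetic_runconfig(
    out_dir: Union[str, Path], seed: int = 0, **overrides
) -> RunConfig:
    """Run configuration for the bundled synthetic scenario."""
    scfg = synth.default_config(seed=seed)
    hierarchy = synth.gen_hierarchy(scfg)
    scenario_vocab = synth.scenario_vocab(scfg, hierarchy)
    return RunConfig(
        out_dir=Path(out_dir),
        drugs=[scfg.drug],
        indication=scenario_vocab.indication_cui,
        indication_name=scfg.indication_name,
        seed=seed,
        **overrides,
    )
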
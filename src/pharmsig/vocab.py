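"""MedDRA-style 5-level hierarchy and adverse-event knowledge bases.

The regulatory terminology for adverse events is organised in five levels,
from most specific to most general: LLT (lowest level term) < PT (preferred
term) < HLT (high level term) < HLGT (high level group term) < SOC (system
organ class).  A term may have multiple parents, so the structure is a DAG,
not a tree.  Concepts are cross-referenced to UMLS-style concept unique
identifiers (CUIs), which this package uses as the join key across every
data source.

Knowledge bases (SIDER-dialect label files restricted to an indication, or
an ADReCS-like flat file) supply the "confirmed" adverse events of a drug.
For flexible mapping, high-level knowledge-base terms are expanded downward
through the hierarchy to all their sub-level terms.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

HIERARCHY_COLUMNS = ["meddra_code", "cui", "level", "name", "parent_code"]
SIDER_COLUMNS = [
    "label_id",
    "stitch_id_flat",
    "stitch_id_stereo",
    "cui",
    "meddra_type",
    "meddra_code",
    "name",
]
ADRECS_COLUMNS = ["drug_name", "ade_name", "meddra_code", "cui"]


class Level(enum.Enum):
    """Hierarchy level, ordered from most specific (LLT) to broadest (SOC)."""

    LLT = 0
    PT = 1
    HLT = 2
    HLGT = 3
    SOC = 4

    @classmethod
    def parse(cls, value: str) -> "Level":
        try:
            return cls[value.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown hierarchy level {value!r}") from None


class HierarchyError(ValueError):
    """Structural problem in a hierarchy file (bad edge, cycle, duplicate)."""


class Provenance(enum.Enum):
    SIDER = "SIDER"
    ADRECS = "ADRECS"
    SYNTHETIC = "SYNTHETIC"


@dataclass(frozen=True)
class Term:
    """One terminology entry: a hierarchy code, its CUI, level and label."""

    cui: str
    meddra_code: str
    level: Level
    name: str

    def __post_init__(self) -> None:
        if not self.cui:
            raise ValueError("cui must be non-empty")
        if not self.meddra_code:
            raise ValueError("meddra_code must be non-empty")
        if not isinstance(self.level, Level):
            raise TypeError(f"level must be a Level, got {self.level!r}")


@dataclass
class Hierarchy:
    """The 5-level term DAG, keyed by hierarchy code.

    Edges run parent -> child and always connect adjacent levels
    (SOC -> HLGT -> HLT -> PT -> LLT); multiple parents are allowed.
    """

    terms: dict[str, Term]
    graph: nx.DiGraph
    _cui_index: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._cui_index:
            for code, term in self.terms.items():
                self._cui_index.setdefault(term.cui, code)

    def __contains__(self, code: str) -> bool:
        return code in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def child_to_parents(self) -> dict[str, set[str]]:
        return {
            code: set(self.graph.predecessors(code))
            for code in self.terms
            if self.graph.in_degree(code) > 0
        }

    def code_for_cui(self, cui: str) -> Optional[str]:
        """Hierarchy code for a CUI, or None if the CUI is not in the graph."""
        return self._cui_index.get(cui)

    def descendants(self, code: str) -> set[str]:
        """Transitive closure of children of ``code``, excluding ``code``."""
        if code not in self.terms:
            raise KeyError(f"unknown hierarchy code {code!r}")
        return set(nx.descendants(self.graph, code))

    def descendant_cuis(self, code: str) -> set[str]:
        return {self.terms[c].cui for c in self.descendants(code)}

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular form: one row per (term, parent) edge.

        Roots get an empty ``parent_code``.  Rows are sorted by
        (meddra_code, parent_code) so serialization is reproducible.
        """
        rows = []
        for code, term in self.terms.items():
            parents = sorted(self.graph.predecessors(code))
            for parent in parents or [""]:
                rows.append((code, term.cui, term.level.name, term.name, parent))
        df = pd.DataFrame(rows, columns=HIERARCHY_COLUMNS)
        return df.sort_values(["meddra_code", "parent_code"], kind="stable").reset_index(drop=True)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class KnowledgeBase:
    """Confirmed adverse events of one drug, restricted to one indication."""

    drug_id: str
    indication: str
    ade_terms: set[Term]
    provenance: Provenance

    def __post_init__(self) -> None:
        cuis = [t.cui for t in self.ade_terms]
        if len(cuis) != len(set(cuis)):
            raise ValueError("duplicate CUIs within ade_terms")

    def cuis(self) -> set[str]:
        """The exact (un-expanded) confirmed CUI set."""
        return {t.cui for t in self.ade_terms}

    def __len__(self) -> int:
        return len(self.ade_terms)


def _build_hierarchy(df: pd.DataFrame) -> Hierarchy:
    terms: dict[str, Term] = {}
    for code, group in df.groupby("meddra_code", sort=False):
        uniq = group[["cui", "level", "name"]].drop_duplicates()
        if len(uniq) > 1:
            raise HierarchyError(f"duplicate meddra_code {code!r} with conflicting rows")
        row = uniq.iloc[0]
        terms[str(code)] = Term(
            cui=str(row["cui"]),
            meddra_code=str(code),
            level=Level.parse(str(row["level"])),
            name=str(row["name"]),
        )

    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for _, row in df.iterrows():
        parent = str(row["parent_code"]) if not pd.isna(row["parent_code"]) else ""
        child = str(row["meddra_code"])
        child_level = terms[child].level
        if parent == "":
            if child_level is not Level.SOC:
                raise HierarchyError(
                    f"non-SOC term {child!r} ({child_level.name}) has no parent"
                )
            continue
        if parent not in terms:
            raise HierarchyError(f"unknown parent code {parent!r} referenced by {child!r}")
        parent_level = terms[parent].level
        if parent_level.value != child_level.value + 1:
            raise HierarchyError(
                f"edge {parent!r} ({parent_level.name}) -> {child!r} "
                f"({child_level.name}) does not connect adjacent levels"
            )
        graph.add_edge(parent, child)

    # Adjacent-level edges cannot form a cycle, but guard against future
    # relaxations of that check.
    if not nx.is_directed_acyclic_graph(graph):
        raise HierarchyError("cycle detected in hierarchy")
    return Hierarchy(terms=terms, graph=graph)


def load_hierarchy(path: Union[str, Path]) -> Hierarchy:
    """Read a hierarchy table (TSV with header) and validate its structure.

    Expected columns: ``meddra_code  cui  level  name  parent_code`` with an
    empty ``parent_code`` on SOC (root) rows.  A term with several parents
    appears on several rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(HIERARCHY_COLUMNS) - set(df.columns)
    if missing:
        raise HierarchyError(f"hierarchy file missing columns: {sorted(missing)}")
    return _build_hierarchy(df[HIERARCHY_COLUMNS])


def descendants(hierarchy: Hierarchy, code: str) -> set[str]:
    """Functional alias for :meth:`Hierarchy.descendants`."""
    return hierarchy.descendants(code)


def _read_sider_table(path: Union[str, Path]) -> tuple[pd.DataFrame, int]:
    """Read a SIDER-dialect TSV (optionally gzipped), skipping malformed rows."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        header=0,
        on_bad_lines="skip",
    )
    missing = set(SIDER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SIDER-dialect file missing columns: {sorted(missing)}")
    df = df[SIDER_COLUMNS]
    ok = (df["cui"] != "") & (df["label_id"] != "")
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("skipped %d malformed rows in %s", n_skipped, path)
    return df[ok], n_skipped


def _term_from_row(row: pd.Series, default_level: Level = Level.LLT) -> Term:
    try:
        level = Level.parse(row.get("meddra_type", "")) if row.get("meddra_type") else default_level
    except ValueError:
        level = default_level
    code = str(row["meddra_code"]) or str(row["cui"])
    return Term(cui=str(row["cui"]), meddra_code=code, level=level, name=str(row["name"]))


def load_sider_kb(
    indications_path: Union[str, Path],
    se_path: Union[str, Path],
    drug_id: str,
    indication_name: str,
) -> KnowledgeBase:
    """Extract a drug's indication-restricted confirmed ADEs from SIDER files.

    Labels (package inserts) of ``drug_id`` whose indications file carries
    ``indication_name`` (case-insensitive exact match on the name column) are
    selected; every side-effect term on those labels is returned,
    de-duplicated by CUI.  Not every label of a drug carries the same
    indication, which is why the restriction is per label, not per drug.
    """
    ind, _ = _read_sider_table(indications_path)
    se, _ = _read_sider_table(se_path)

    drug_ind = ind[ind["stitch_id_flat"] == drug_id]
    if drug_ind.empty:
        logger.warning("drug %s not found in SIDER indications file", drug_id)
    wanted = drug_ind[drug_ind["name"].str.lower() == indication_name.lower()]
    labels = set(wanted["label_id"])
    indication_cuis = set(wanted["cui"])

    on_label = se[(se["stitch_id_flat"] == drug_id) & (se["label_id"].isin(labels))]
    terms: dict[str, Term] = {}
    for _, row in on_label.iterrows():
        if row["cui"] in indication_cuis:
            continue  # the extraction indication itself is never a confirmed ADE
        terms.setdefault(row["cui"], _term_from_row(row))
    if not terms:
        logger.warning(
            "empty knowledge base for drug %s / indication %r", drug_id, indication_name
        )
    return KnowledgeBase(
        drug_id=drug_id,
        indication=indication_name,
        ade_terms=set(terms.values()),
        provenance=Provenance.SIDER,
    )


def load_adrecs_kb(
    path: Union[str, Path],
    drug_name: str,
    hierarchy: Optional[Hierarchy] = None,
) -> KnowledgeBase:
    """Read an ADReCS-like flat file and collect one drug's confirmed ADEs.

    The flat dialect has four columns: ``drug_name  ade_name  meddra_code
    cui``.  Matching on the drug name is case-insensitive; rows are
    de-duplicated by CUI.  Levels are resolved through ``hierarchy`` when one
    is supplied (the flat file does not carry them), else terms default to
    LLT, which is immaterial for matching since the join key is the CUI.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, on_bad_lines="skip")
    missing = set(ADRECS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ADReCS-dialect file missing columns: {sorted(missing)}")
    ok = (df["cui"] != "") & (df["drug_name"] != "")
    if (~ok).sum():
        logger.warning("skipped %d malformed rows in %s", int((~ok).sum()), path)
    df = df[ok]
    rows = df[df["drug_name"].str.lower() == drug_name.lower()]
    terms: dict[str, Term] = {}
    for _, row in rows.iterrows():
        level = Level.LLT
        if hierarchy is not None and row["meddra_code"] in hierarchy:
            level = hierarchy.terms[row["meddra_code"]].level
        code = str(row["meddra_code"]) or str(row["cui"])
        terms.setdefault(
            row["cui"],
            Term(cui=str(row["cui"]), meddra_code=code, level=level, name=str(row["ade_name"])),
        )
    if not terms:
        logger.warning("empty knowledge base for drug %r in %s", drug_name, path)
    return KnowledgeBase(
        drug_id=drug_name,
        indication="",
        ade_terms=set(terms.values()),
        provenance=Provenance.ADRECS,
    )


def expand_kb_flexible(kb: KnowledgeBase, hierarchy: Hierarchy) -> set[str]:
    """Expand a knowledge base downward for flexible mapping.

    Every knowledge-base term contributes its own CUI plus the CUIs of all
    its hierarchy descendants (transitively, down to LLT).  Terms that cannot
    be resolved in the hierarchy degrade gracefully to exact-only matching;
    their count is logged.  The result is always a superset of the exact CUI
    set.
    """
    expanded: set[str] = set()
    unresolved = 0
    for term in kb.ade_terms:
        expanded.add(term.cui)
        code = term.meddra_code if term.meddra_code in hierarchy else hierarchy.code_for_cui(term.cui)
        if code is None:
            unresolved += 1
            continue
        expanded |= hierarchy.descendant_cuis(code)
    if unresolved:
        logger.info(
            "%d of %d knowledge-base terms not resolvable in the hierarchy; "
            "kept as exact-only",
            unresolved,
            len(kb.ade_terms),
        )
    return expanded


def kb_terms_from_cuis(
    cuis: Iterable[str],
    hierarchy: Hierarchy,
    drug_id: str = "synthetic",
    indication: str = "",
) -> KnowledgeBase:
    """Build a synthetic-provenance KB directly from hierarchy CUIs."""
    terms = set()
    for cui in cuis:
        code = hierarchy.code_for_cui(cui)
        if code is None:
            terms.add(Term(cui=cui, meddra_code=cui, level=Level.LLT, name=cui))
        else:
            terms.add(hierarchy.terms[code])
    return KnowledgeBase(
        drug_id=drug_id, indication=indication, ade_terms=terms, provenance=Provenance.SYNTHETIC
    )
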
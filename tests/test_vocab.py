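"""Hierarchy loading, downward expansion, and knowledge-base readers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pharmsig import synth, vocab
from pharmsig.vocab import (
    HIERARCHY_COLUMNS,
    Hierarchy,
    HierarchyError,
    Level,
    Term,
    expand_kb_flexible,
    load_adrecs_kb,
    load_hierarchy,
    load_sider_kb,
)

SIDER_HEADER = "\t".join(vocab.SIDER_COLUMNS)


def _hier_file(tmp_path, rows):
    path = tmp_path / "h.tsv"
    df = pd.DataFrame(rows, columns=HIERARCHY_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


class TestLoadHierarchy:
    def test_binary_tree_has_31_terms_30_edges(self, binary_hierarchy, tmp_path):
        binary_hierarchy.to_tsv(tmp_path / "h.tsv")
        h = load_hierarchy(tmp_path / "h.tsv")
        assert len(h) == 31
        assert h.graph.number_of_edges() == 30

    def test_llt_with_soc_parent_rejected(self, tmp_path):
        rows = [
            ("S1", "C1", "SOC", "root", ""),
            ("L1", "C2", "LLT", "leaf", "S1"),
        ]
        with pytest.raises(HierarchyError, match="adjacent levels"):
            load_hierarchy(_hier_file(tmp_path, rows))

    def test_missing_parent_named_in_error(self, tmp_path):
        rows = [
            ("S1", "C1", "SOC", "root", ""),
            ("G1", "C2", "HLGT", "group", "NOPE"),
        ]
        with pytest.raises(HierarchyError, match="NOPE"):
            load_hierarchy(_hier_file(tmp_path, rows))

    def test_conflicting_duplicate_code_rejected(self, tmp_path):
        rows = [
            ("S1", "C1", "SOC", "root", ""),
            ("S1", "C9", "SOC", "other", ""),
        ]
        with pytest.raises(HierarchyError, match="duplicate"):
            load_hierarchy(_hier_file(tmp_path, rows))

    def test_non_soc_root_rejected(self, tmp_path):
        rows = [("P1", "C1", "PT", "orphan", "")]
        with pytest.raises(HierarchyError, match="no parent"):
            load_hierarchy(_hier_file(tmp_path, rows))

    def test_round_trip_is_bit_identical(self, binary_hierarchy, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        binary_hierarchy.to_tsv(p1)
        load_hierarchy(p1).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestDescendants:
    def test_root_covers_all_other_terms(self, binary_hierarchy):
        root = next(
            c for c, t in binary_hierarchy.terms.items() if t.level is Level.SOC
        )
        assert len(binary_hierarchy.descendants(root)) == 30

    def test_leaves_have_no_descendants(self, binary_hierarchy):
        for code, term in binary_hierarchy.terms.items():
            if term.level is Level.LLT:
                assert binary_hierarchy.descendants(code) == set()

    def test_unknown_code_raises(self, binary_hierarchy):
        with pytest.raises(KeyError):
            binary_hierarchy.descendants("nope")

    def test_high_level_term_reaches_specific_leaf(self, vasculitis_hierarchy):
        down = vasculitis_hierarchy.descendants("MDV02")
        assert "MDV04" in down  # Vasculitides covers Skin vasculitis NOS

    def test_matches_breadth_first_oracle_on_random_dag(self):
        rng = np.random.default_rng(42)
        h = _random_hierarchy(rng, n_per_level=(4, 10, 30, 60, 96))
        children: dict[str, set[str]] = {c: set() for c in h.terms}
        for parent, child in h.graph.edges:
            children[parent].add(child)

        def bfs(code):
            seen, frontier = set(), [code]
            while frontier:
                nxt = []
                for node in frontier:
                    for ch in children[node]:
                        if ch not in seen:
                            seen.add(ch)
                            nxt.append(ch)
                frontier = nxt
            return seen

        for code in h.terms:
            assert h.descendants(code) == bfs(code)


def _random_hierarchy(rng, n_per_level) -> Hierarchy:
    """Random multi-parent DAG with adjacency-respecting edges."""
    levels = [Level.SOC, Level.HLGT, Level.HLT, Level.PT, Level.LLT]
    rows, idx = [], 0
    prev: list[str] = []
    for li, n in enumerate(n_per_level):
        current = []
        for _ in range(n):
            code = f"N{idx:04d}"
            if li == 0:
                rows.append((code, f"C{idx:04d}", levels[0].name, code, ""))
            else:
                n_parents = 1 + int(rng.random() < 0.2)
                for parent in rng.choice(prev, size=min(n_parents, len(prev)), replace=False):
                    rows.append((code, f"C{idx:04d}", levels[li].name, code, parent))
            current.append(code)
            idx += 1
        prev = current
    df = pd.DataFrame(rows, columns=HIERARCHY_COLUMNS)
    return vocab._build_hierarchy(df)


class TestSiderKb:
    @pytest.fixture()
    def sider_files(self, tmp_path):
        ind = tmp_path / "ind.tsv"
        se = tmp_path / "se.tsv"
        ind.write_text(
            SIDER_HEADER + "\n"
            "L1\tCID100004112\tCID000004112\tC_RA\tLLT\tM_RA\tRheumatoid arthritis\n"
            "L2\tCID100004112\tCID000004112\tC_PS\tLLT\tM_PS\tPsoriasis\n"
            "L3\tCID100009999\tCID000009999\tC_RA\tLLT\tM_RA\tRheumatoid arthritis\n"
        )
        se.write_text(
            SIDER_HEADER + "\n"
            "L1\tCID100004112\tCID000004112\tC_X\tLLT\tM_X\tNausea\n"
            "L1\tCID100004112\tCID000004112\tC_Y\tPT\tM_Y\tVomiting\n"
            "L1\tCID100004112\tCID000004112\tC_Y\tLLT\tM_Y2\tVomiting NOS\n"
            "L2\tCID100004112\tCID000004112\tC_Z\tLLT\tM_Z\tRash\n"
        )
        return ind, se

    def test_indication_restriction(self, sider_files):
        kb = load_sider_kb(*sider_files, "CID100004112", "rheumatoid arthritis")
        assert kb.cuis() == {"C_X", "C_Y"}

    def test_other_indication_selects_other_label(self, sider_files):
        kb = load_sider_kb(*sider_files, "CID100004112", "Psoriasis")
        assert kb.cuis() == {"C_Z"}

    def test_llt_and_pt_rows_deduplicated_by_cui(self, sider_files):
        kb = load_sider_kb(*sider_files, "CID100004112", "Rheumatoid arthritis")
        assert sum(1 for t in kb.ade_terms if t.cui == "C_Y") == 1

    def test_absent_drug_gives_empty_kb(self, sider_files, caplog):
        kb = load_sider_kb(*sider_files, "CID100000000", "Rheumatoid arthritis")
        assert len(kb) == 0

    def test_indication_cui_never_in_ade_terms(self, tmp_path):
        ind = tmp_path / "ind.tsv"
        se = tmp_path / "se.tsv"
        ind.write_text(
            SIDER_HEADER + "\nL1\tCID1\tCID0\tC_RA\tLLT\tM_RA\tRheumatoid arthritis\n"
        )
        se.write_text(
            SIDER_HEADER + "\n"
            "L1\tCID1\tCID0\tC_RA\tLLT\tM_RA\tRheumatoid arthritis\n"
            "L1\tCID1\tCID0\tC_X\tLLT\tM_X\tNausea\n"
        )
        kb = load_sider_kb(ind, se, "CID1", "Rheumatoid arthritis")
        assert kb.cuis() == {"C_X"}


class TestAdrecsKb:
    def test_matching_rows_collected(self, tmp_path):
        path = tmp_path / "adrecs.tsv"
        path.write_text(
            "drug_name\tade_name\tmeddra_code\tcui\n"
            "methotrexate\tNausea\tM_X\tC_X\n"
            "Methotrexate\tVomiting\tM_Y\tC_Y\n"
            "aspirin\tRash\tM_Z\tC_Z\n"
        )
        kb = load_adrecs_kb(path, "METHOTREXATE")
        assert kb.cuis() == {"C_X", "C_Y"}

    def test_empty_file_gives_empty_kb(self, tmp_path, caplog):
        path = tmp_path / "adrecs.tsv"
        path.write_text("drug_name\tade_name\tmeddra_code\tcui\n")
        assert len(load_adrecs_kb(path, "methotrexate")) == 0

    def test_duplicate_rows_deduplicated(self, tmp_path):
        path = tmp_path / "adrecs.tsv"
        path.write_text(
            "drug_name\tade_name\tmeddra_code\tcui\n"
            "methotrexate\tNausea\tM_X\tC_X\n"
            "methotrexate\tNausea\tM_X\tC_X\n"
        )
        assert len(load_adrecs_kb(path, "methotrexate")) == 1


class TestFlexibleExpansion:
    def test_high_level_term_expands_to_leaf(self, vasculitis_hierarchy):
        kb = vocab.kb_terms_from_cuis({"C0V02"}, vasculitis_hierarchy)
        expanded = expand_kb_flexible(kb, vasculitis_hierarchy)
        assert {"C0V02", "C0V04"} <= expanded

    def test_leaf_only_kb_adds_nothing(self, binary_hierarchy):
        leaves = {t.cui for t in binary_hierarchy.terms.values() if t.level is Level.LLT}
        some = set(sorted(leaves)[:4])
        kb = vocab.kb_terms_from_cuis(some, binary_hierarchy)
        assert expand_kb_flexible(kb, binary_hierarchy) == some

    def test_root_covers_entire_tree(self, binary_hierarchy):
        root_cui = next(
            t.cui for t in binary_hierarchy.terms.values() if t.level is Level.SOC
        )
        kb = vocab.kb_terms_from_cuis({root_cui}, binary_hierarchy)
        assert len(expand_kb_flexible(kb, binary_hierarchy)) == 31

    def test_unresolvable_terms_kept_exact_only(self, binary_hierarchy):
        kb = vocab.kb_terms_from_cuis({"C_ALIEN"}, binary_hierarchy)
        assert expand_kb_flexible(kb, binary_hierarchy) == {"C_ALIEN"}

    @given(
        shape=st.tuples(*[st.integers(min_value=1, max_value=3)] * 4),
        n_kb=st.integers(min_value=0, max_value=6),
        salt=st.integers(min_value=0, max_value=10_000),
    )
    def test_expansion_is_superset_of_exact(self, shape, n_kb, salt):
        h = synth.gen_hierarchy(synth.SyntheticConfig(hierarchy_shape=shape))
        rng = np.random.default_rng(salt)
        codes = rng.choice(sorted(h.terms), size=min(n_kb, len(h)), replace=False)
        kb = vocab.kb_terms_from_cuis({h.terms[c].cui for c in codes}, h)
        assert expand_kb_flexible(kb, h) >= kb.cuis()


class TestTermInvariants:
    def test_empty_cui_rejected(self):
        with pytest.raises(ValueError):
            Term(cui="", meddra_code="M1", level=Level.LLT, name="x")

    def test_duplicate_kb_cuis_rejected(self):
        t1 = Term(cui="C1", meddra_code="M1", level=Level.LLT, name="a")
        t2 = Term(cui="C1", meddra_code="M2", level=Level.PT, name="b")
        with pytest.raises(ValueError, match="duplicate"):
            vocab.KnowledgeBase(
                drug_id="d", indication="i", ade_terms={t1, t2},
                provenance=vocab.Provenance.SYNTHETIC,
            )
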
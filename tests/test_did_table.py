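"""Flat-table assembly, dedup rules and file-dialect roundtrip."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from didkit.did_table import DIDRow, assemble, read_did, write_did
from didkit.drug_norm import DrugMatch, DrugNormalization, MatchType
from didkit.errors import ConsistencyError, FormatError, ValidationError
from didkit.indication_norm import IndicationMapping, InitialMapping
from didkit.ingest import ParsedPair
from didkit.subtypes import Polarity, SubtypeAnnotation

# strings that may carry tabs/newlines/backslashes but are nonempty and
# ';'-free (the intra-cell list separator)
text = st.text(
    alphabet=st.sampled_from("ab \t\n\r\\xyz"), min_size=1, max_size=12
).filter(lambda s: ";" not in s)
opt_text = st.none() | text
label = st.text(alphabet="abcdef", min_size=1, max_size=6)


@st.composite
def did_rows(draw):
    n_sub = draw(st.integers(0, 2))
    return DIDRow(
        source_id=draw(label),
        raw_drug_name=draw(text),
        entire_value=draw(text),
        target=draw(text),
        target_equals_entire=draw(st.booleans()),
        ind_match_quality=draw(st.sampled_from(list(MatchType))),
        cas_number=draw(opt_text),
        cas_authority=draw(st.none() | label),
        preferred_pt=draw(opt_text),
        drug_matches=tuple(
            (name, DrugMatch(draw(opt_text), draw(opt_text),
                             draw(st.sampled_from(list(MatchType)))))
            for name in sorted(draw(st.sets(label, max_size=2)))
        ),
        drug_cui=draw(opt_text),
        subtype_leaves=tuple(draw(st.lists(label, min_size=n_sub, max_size=n_sub))),
        subtype_roots=tuple(draw(st.lists(label, min_size=n_sub, max_size=n_sub))),
        subtype_polarities=tuple(
            draw(st.lists(st.sampled_from(list(Polarity)),
                          min_size=n_sub, max_size=n_sub))
        ),
        ind_entry_term=draw(opt_text),
        ind_preferred_term=draw(opt_text),
        ind_cui=draw(opt_text),
        ind_entry_status=draw(st.none() | st.sampled_from(["P", "S"])),
        ind_semantic_types=tuple(draw(st.lists(label, max_size=2))),
        ind_phenotypic=draw(st.booleans()),
        compound_index=draw(st.none() | st.integers(1, 5)),
        init_entry_term=draw(opt_text),
        init_entry_status=draw(st.none() | st.sampled_from(["P", "S"])),
        init_preferred_term=draw(opt_text),
        init_cui=draw(opt_text),
        init_semantic_types=tuple(draw(st.lists(label, max_size=2))),
    )


@st.composite
def unique_row_lists(draw):
    rows = draw(st.lists(did_rows(), max_size=6))
    seen, out = set(), []
    for r in rows:
        if r.quadruplet not in seen:
            seen.add(r.quadruplet)
            out.append(r)
    return out


def _norm(name="drugA", cas="1-11-1"):
    return DrugNormalization(
        raw_name=name,
        per_authority=(("chem", DrugMatch(cas, name, MatchType.PT_EXACT)),),
        cas_number=cas,
        cas_authority="chem",
        preferred_pt=name,
    )


def _mapping(target, cui, quality=MatchType.PT_EXACT, index=None):
    return IndicationMapping(
        target=target,
        entry_term=target,
        entry_status="P",
        preferred_term=target,
        cui=cui,
        semantic_types=("DSYN",),
        phenotypic=True,
        match_quality=quality,
        compound_index=index,
    )


class TestAssemble:
    def test_duplicate_quadruplets_keep_best_match_quality(self):
        pairs = [
            ParsedPair("s1", "drugA", "pain", "pain", True),
            ParsedPair("s1", "drugA", "pain", "pain", True),
        ]
        maps = {
            "pain": [_mapping("pain", "C1", MatchType.SYNONYM)],
        }
        rows = assemble(pairs, {"drugA": _norm()}, maps)
        assert len(rows) == 1
        # now feed two map variants through two distinct entire values
        pairs = [
            ParsedPair("s1", "drugA", "for pain", "pain", False),
            ParsedPair("s1", "drugA", "pain", "pain", True),
        ]
        maps = {"pain": [_mapping("pain", "C1", MatchType.SYNONYM),
                         _mapping("pain", "C1", MatchType.PT_EXACT)]}
        rows = assemble(pairs, {"drugA": _norm()}, maps)
        assert len(rows) == 1
        assert rows[0].ind_match_quality is MatchType.PT_EXACT

    def test_compound_components_share_target(self):
        pairs = [ParsedPair("s1", "drugA", "nausea and vomiting",
                            "nausea and vomiting", True)]
        maps = {
            "nausea and vomiting": [
                _mapping("nausea and vomiting", "C1", index=1),
                _mapping("nausea and vomiting", "C2", index=2),
            ]
        }
        rows = assemble(pairs, {"drugA": _norm()}, maps)
        assert len(rows) == 2
        assert {r.ind_cui for r in rows} == {"C1", "C2"}
        assert {r.target for r in rows} == {"nausea and vomiting"}

    def test_empty_inputs_give_empty_table(self):
        assert assemble([], {}, {}) == []

    def test_missing_normalization_is_consistency_error(self):
        pairs = [ParsedPair("s1", "ghost", "pain", "pain", True)]
        with pytest.raises(ConsistencyError):
            assemble(pairs, {}, {"pain": [_mapping("pain", "C1")]})

    def test_rows_sorted_by_source_drug_target(self):
        pairs = [
            ParsedPair("s2", "b", "pain", "pain", True),
            ParsedPair("s1", "z", "pain", "pain", True),
            ParsedPair("s1", "a", "pain", "pain", True),
        ]
        norms = {n: _norm(n) for n in "abz"}
        rows = assemble(pairs, norms, {"pain": [_mapping("pain", "C1")]})
        assert [(r.source_id, r.raw_drug_name) for r in rows] == [
            ("s1", "a"), ("s1", "z"), ("s2", "b")
        ]


class TestRoundtrip:
    @given(unique_row_lists())
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_write_read_identity(self, rows):
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "t.tsv"
            write_did(rows, path)
            assert read_did(path) == rows

    def test_write_is_deterministic(self, tmp_path):
        rows = [
            DIDRow("s1", "drugA", "e\tv", "t\nv", False,
                   ind_cui="C1", ind_match_quality=MatchType.SYNONYM)
        ]
        write_did(rows, tmp_path / "a.tsv")
        write_did(rows, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_duplicate_quadruplet_rejected_with_key(self, tmp_path):
        row = DIDRow("s1", "drugA", "pain", "pain", True, ind_cui="C1")
        path = tmp_path / "dup.tsv"
        write_did([row], path)
        content = path.read_text()
        path.write_text(content + content.splitlines()[1] + "\n")
        with pytest.raises(ValidationError, match="duplicate quadruplet"):
            read_did(path)

    def test_header_mismatch_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("wrong\theader\n")
        with pytest.raises(FormatError):
            read_did(path)

    def test_legacy_mode_tolerates_missing_initial_block(self, tmp_path):
        row = DIDRow("s1", "drugA", "pain", "pain", True, ind_cui="C1",
                     init_cui="C9", init_entry_term="x", init_entry_status="P",
                     init_preferred_term="X")
        path = tmp_path / "full.tsv"
        write_did([row], path)
        lines = path.read_text().split("\n")
        header = lines[0].split("\t")
        keep = [i for i, h in enumerate(header) if not h.startswith("init_")]
        trimmed = "\n".join(
            "\t".join(line.split("\t")[i] for i in keep if i < len(line.split("\t")))
            for line in lines if line
        )
        legacy_path = tmp_path / "legacy.tsv"
        legacy_path.write_text(trimmed + "\n")
        with pytest.raises(FormatError):
            read_did(legacy_path)  # strict mode refuses
        (got,) = read_did(legacy_path, legacy=True)
        assert got.init_cui is None and got.ind_cui == "C1"
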
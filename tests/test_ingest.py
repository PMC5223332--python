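"""Source adapters: filtering rules, accounting invariants, target extraction."""

from __future__ import annotations

import random
import re

import pytest

from didkit.errors import ConfigurationError, InputError
from didkit.ingest import (
    ParsedPair,
    RawSourceRecord,
    SourceStyle,
    ingest_freetext_source,
    ingest_hierarchy_source,
    ingest_pair_source,
    split_targets,
)
from didkit.lexicon import Authority, ConceptDictionary, ConceptEntry
from didkit._text import term_key


def pair_rec(drug, relation, term, sid="s1"):
    return RawSourceRecord(sid, SourceStyle.PAIR, drug, relation=relation, term=term)


def free_rec(drug, text, sid="s3", **aux):
    return RawSourceRecord(sid, SourceStyle.FREETEXT, drug, text=text, **aux)


class TestPairAdapter:
    ALLOW = frozenset({"may_treat", "may_prevent", "has_role"})
    BLOCK = frozenset({"metabolite", "prodrug", "epitope"})

    def test_blocklisted_role_object_dropped_and_tallied(self):
        pairs, rep = ingest_pair_source(
            [pair_rec("drugA", "has_role", "metabolite")], self.ALLOW, self.BLOCK
        )
        assert pairs == []
        assert rep.per_rule_removed["role_blocklist"] == 1

    def test_allowed_relation_yields_whole_value_target(self):
        pairs, rep = ingest_pair_source(
            [pair_rec("drugA", "may_treat", "hypertension")], self.ALLOW, self.BLOCK
        )
        assert len(pairs) == 1
        assert pairs[0].target == pairs[0].entire_value == "hypertension"
        assert pairs[0].target_equals_entire
        assert rep.parsed == rep.filtered == 1

    def test_empty_input(self):
        pairs, rep = ingest_pair_source([], self.ALLOW, self.BLOCK)
        assert pairs == [] and rep.initial == rep.filtered == rep.parsed == 0

    def test_disallowed_relation_and_duplicates_tallied(self):
        records = [
            pair_rec("a", "has_part", "x"),
            pair_rec("a", "may_treat", "x"),
            pair_rec("a", "may_treat", "x"),
        ]
        pairs, rep = ingest_pair_source(records, self.ALLOW, self.BLOCK)
        assert len(pairs) == 1
        assert rep.per_rule_removed == {"relation_not_allowed": 1, "duplicate": 1}
        assert sum(rep.per_rule_removed.values()) + rep.filtered == rep.initial

    def test_non_pair_record_rejected(self):
        with pytest.raises(InputError):
            ingest_pair_source(
                [RawSourceRecord("s", SourceStyle.HIERARCHY, "d",
                                 levels=(("A", "t"),))],
                self.ALLOW, self.BLOCK,
            )


class TestHierarchyAdapter:
    def test_duplicate_term_at_nested_levels_collapses(self):
        rec = RawSourceRecord(
            "s2", SourceStyle.HIERARCHY, "drugX",
            levels=(
                ("B01", "Antithrombotic Agents"),
                ("B01A", "Antithrombotic Agents"),
                ("B01AC", "Platelet aggregation inhibitors"),
            ),
        )
        pairs, rep = ingest_hierarchy_source([rec])
        assert [p.target for p in pairs] == [
            "Antithrombotic Agents", "Platelet aggregation inhibitors"
        ]
        assert rep.initial == 3 and rep.filtered == 2
        assert rep.per_rule_removed["duplicate_term"] == 1

    def test_combination_drug_name_dropped(self):
        rec = RawSourceRecord(
            "s2", SourceStyle.HIERARCHY, "X, combinations",
            levels=(("A01", "t"),),
        )
        pairs, rep = ingest_hierarchy_source([rec])
        assert pairs == []
        assert rep.per_rule_removed["combination_drug"] == 1

    def test_ill_formed_code_like_name_dropped(self):
        rec = RawSourceRecord("s2", SourceStyle.HIERARCHY, "B01",
                              levels=(("A01", "t"),))
        _, rep = ingest_hierarchy_source([rec])
        assert rep.per_rule_removed["ill_formed_drug"] == 1

    def test_single_unique_level(self):
        rec = RawSourceRecord("s2", SourceStyle.HIERARCHY, "drugY",
                              levels=(("C03", "Diuretics"),))
        pairs, rep = ingest_hierarchy_source([rec])
        assert len(pairs) == 1
        assert rep.initial == rep.filtered == rep.parsed == 1

    def test_empty_level_list_rejected(self):
        with pytest.raises(InputError):
            ingest_hierarchy_source(
                [RawSourceRecord("s2", SourceStyle.HIERARCHY, "d", levels=())]
            )


class TestFreetextAdapter:
    def test_length_boundary_540_dropped_539_kept(self):
        texts = {539: "a" * 539, 540: "a" * 540}
        pairs, rep = ingest_freetext_source(
            [free_rec("d539", texts[539]), free_rec("d540", texts[540])]
        )
        assert [p.raw_drug_name for p in pairs] == ["d539"]
        assert rep.per_rule_removed["overlong_text"] == 1

    def test_newlines_count_as_single_spaces_for_length(self):
        # 539 chars + 1 newline -> 540 after conversion -> dropped
        text = "a" * 269 + "\n" + "a" * 270
        _, rep = ingest_freetext_source([free_rec("d", text)])
        assert rep.per_rule_removed["overlong_text"] == 1

    def test_trade_name_variants_collapse(self):
        recs = [
            free_rec("generic", "for pain", trade_name="Brand A"),
            free_rec("generic", "for pain", trade_name="Brand B"),
        ]
        pairs, rep = ingest_freetext_source(recs)
        assert len(pairs) == 1
        assert rep.per_rule_removed["duplicate"] == 1

    def test_combination_product_dropped(self):
        _, rep = ingest_freetext_source(
            [free_rec("alpha and beta", "for pain")]
        )
        assert rep.per_rule_removed["combination_product"] == 1

    def test_negative_max_len_rejected(self):
        with pytest.raises(ConfigurationError):
            ingest_freetext_source([], max_len=-1)

    def test_parsed_exceeds_filtered_only_with_multi_target_values(self, umls_ind):
        recs = [free_rec("drugA", "treatment of hypertension and angina")]
        pairs, rep = ingest_freetext_source(recs, indication_dict=umls_ind)
        assert rep.filtered == 1 and rep.parsed == 2
        assert [p.target for p in pairs] == ["hypertension", "angina"]


# ---------------------------------------------------------------------------
# split_targets vs a brute-force all-substrings oracle


def brute_split(text: str, dictionary: ConceptDictionary) -> list[str]:
    """Independent oracle: enumerate every token span per sentence, then pick
    non-overlapping matches leftmost-first, longest at each position."""
    out = []
    for sm in re.finditer(r"[^.;]+", text):
        sentence, base = sm.group(0), sm.start()
        toks = list(re.finditer(r"\S+", sentence))
        matches = []
        for i in range(len(toks)):
            for j in range(i + 1, len(toks) + 1):
                phrase = text[base + toks[i].start(): base + toks[j - 1].end()]
                if dictionary.lookup_key(phrase):
                    matches.append((i, j, phrase))
        cursor = 0
        while True:
            avail = [m for m in matches if m[0] >= cursor]
            if not avail:
                break
            start = min(m[0] for m in avail)
            best = max((m for m in avail if m[0] == start), key=lambda m: m[1])
            out.append(best[2])
            cursor = best[1]
    seen, dedup = set(), []
    for t in out:
        if t not in seen:
            seen.add(t)
            dedup.append(t)
    return dedup


class TestSplitTargets:
    def test_two_known_terms_extracted(self, umls_ind):
        got = split_targets("treatment of hypertension and angina", umls_ind)
        assert got == [("hypertension", False), ("angina", False)]

    def test_whole_string_match_flagged(self, umls_ind):
        assert split_targets("hypertension", umls_ind) == [("hypertension", True)]

    def test_no_match_passthrough(self, umls_ind):
        assert split_targets("for oral use only", umls_ind) == [
            ("for oral use only", True)
        ]

    def test_multiword_term_beats_embedded_single_word(self, umls_ind):
        got = split_targets("history of hypertensive disease", umls_ind)
        assert got == [("hypertensive disease", False)]

    def test_matches_brute_force_oracle_on_random_texts(self, umls_ind):
        rng = random.Random(20240901)
        terms = ["hypertension", "angina", "nausea", "vomiting", "pain",
                 "hypertensive disease", "bacterial infections"]
        fillers = ["for", "the", "treatment", "of", "and", "in", "adults",
                   "relief", "management"]
        for _ in range(200):
            words = []
            for _ in range(rng.randint(1, 12)):
                if rng.random() < 0.4:
                    words.append(rng.choice(terms))
                else:
                    words.append(rng.choice(fillers))
            text = " ".join(words)
            if rng.random() < 0.3:
                text += "."
            expected = brute_split(text, umls_ind)
            if not expected:
                expected_pairs = [(text, True)]
            else:
                expected_pairs = [(t, t == text) for t in expected]
            assert split_targets(text, umls_ind) == expected_pairs

    def test_match_positions_left_to_right_non_overlapping(self, umls_ind):
        text = "pain and nausea; vomiting after angina"
        got = [t for t, _ in split_targets(text, umls_ind)]
        pos = [text.index(t) for t in got]
        assert pos == sorted(pos)

    def test_empty_value_rejected(self, umls_ind):
        with pytest.raises(InputError):
            split_targets("", umls_ind)


def test_adapters_are_deterministic(umls_ind):
    recs = [
        free_rec("drugA", "treatment of hypertension and angina"),
        free_rec("drugB", "pain relief"),
    ]
    first = ingest_freetext_source(recs, indication_dict=umls_ind)
    second = ingest_freetext_source(recs, indication_dict=umls_ind)
    assert first == second
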
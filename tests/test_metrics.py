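"""Integration metrics: TR, coverage, overlap, Zipf, richness."""

from __future__ import annotations

import random
from itertools import count

import pytest

from didkit.did_table import DIDRow
from didkit.drug_norm import MatchType
from didkit.errors import ConsistencyError, InputError
from didkit.metrics import (
    OverlapStats,
    coverage,
    overlap,
    overlap_change,
    present,
    richness,
    tr,
    tr_drugs,
    tr_indications,
    zipf,
)

_ids = count()


def row(source, drug, target, cas=None, cui=None, ind_cui=None):
    return DIDRow(
        source_id=source,
        raw_drug_name=drug,
        entire_value=target,
        target=target,
        target_equals_entire=True,
        ind_match_quality=MatchType.PT_EXACT if ind_cui else MatchType.UNMAPPED,
        cas_number=cas,
        drug_cui=cui,
        ind_cui=ind_cui,
    )


class TestTR:
    def test_all_names_to_one_concept(self):
        names = ["a", "b", "c", "d"]
        res = tr(names, {n: "c1" for n in names})
        assert (res.n_normalized, res.n_unnormalized, res.n_unique_raw) == (1, 0, 4)
        assert res.tr == 0.25

    def test_injective_mapping_gives_one(self):
        names = ["a", "b", "c", "d"]
        res = tr(names, {n: n.upper() for n in names})
        assert res.tr == 1.0

    def test_unmapped_names_count_in_numerator(self):
        res = tr(["a", "b"], {"a": None, "b": None})
        assert res.tr == 1.0 and res.n_unnormalized == 2

    def test_matches_brute_force_on_random_mappings(self):
        rng = random.Random(11)
        for _ in range(300):
            u = rng.randint(1, 30)
            names = [f"n{i}" for i in range(u)]
            mapping = {
                n: (None if rng.random() < 0.2 else f"c{rng.randint(0, 9)}")
                for n in names
            }
            # brute force: explicit set construction over the image
            image = {v for v in mapping.values() if v is not None}
            x = sum(1 for v in mapping.values() if v is None)
            expected = (len(image) + x) / u
            assert tr(names, mapping).tr == expected

    def test_duplicated_names_leave_tr_unchanged(self):
        names = ["a", "b", "c"]
        mapping = {"a": "c1", "b": "c1", "c": None}
        assert tr(names * 5, mapping) == tr(names, mapping)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            tr([], {})
        with pytest.raises(InputError):
            tr(["a"], {})

    def test_drug_tr_bases(self):
        rows = [
            row("s1", "aspirin", "pain", cas="50-78-2", cui="C7", ind_cui="C1"),
            row("s1", "acetylsalicylic acid", "pain", cas="50-78-2", ind_cui="C1"),
            row("s1", "mystery drug", "pain", ind_cui="C1"),
        ]
        assert tr_drugs(rows, "cas").tr == pytest.approx(2 / 3)
        assert tr_drugs(rows, "either").tr == pytest.approx(2 / 3)
        # on a CUI basis only aspirin is normalized; the others stay raw
        assert tr_drugs(rows, "cui").tr == pytest.approx(1.0)

    def test_indication_tr_uses_final_cuis(self):
        rows = [
            row("s1", "a", "fever", ind_cui="C1"),
            row("s1", "a", "pyrexia", ind_cui="C1"),
            row("s1", "a", "weirdness"),
        ]
        res = tr_indications(rows)
        assert (res.n_normalized, res.n_unnormalized, res.n_unique_raw) == (1, 1, 3)


class TestCoverage:
    def test_single_source_covers_everything(self):
        rows = [row("s1", "a", "t1", cas="1", ind_cui="C1"),
                row("s1", "b", "t2", cas="2", ind_cui="C2"),
                row("s1", "b", "t3", cas="2", ind_cui="C3")]
        cov = coverage(rows)
        assert cov.percentages["s1"] == {"drug": 100.0, "indication": 100.0,
                                         "pair": 100.0}
        assert cov.totals == {"drug": 2, "indication": 3, "pair": 3}

    def test_full_sharing_gives_100_percent_each(self):
        rows = [row(s, "a", "t", cas="1", ind_cui="C1") for s in ("s1", "s2")]
        cov = coverage(rows)
        for s in ("s1", "s2"):
            assert cov.percentages[s]["pair"] == 100.0

    def test_counts_match_brute_force_sets(self):
        rng = random.Random(5)
        rows = []
        for s in ("s1", "s2", "s3"):
            for _ in range(30):
                d, t = f"d{rng.randint(0, 9)}", f"t{rng.randint(0, 9)}"
                rows.append(row(s, d, t, cas=f"cas-{d}", ind_cui=f"C-{t}"))
        cov = coverage(rows)
        for s in ("s1", "s2", "s3"):
            mine = {(r.cas_number, r.ind_cui) for r in rows if r.source_id == s}
            assert cov.counts[s]["pair"] == len(mine)


class TestOverlap:
    def test_private_source_scores_one(self):
        rows = [row("s1", "a", "t", cas="1", ind_cui="C1"),
                row("s2", "b", "u", cas="2", ind_cui="C2")]
        stats = overlap(rows, "drug", "raw")
        assert stats.per_source == {"s1": 1.0, "s2": 1.0}

    def test_complete_sharing_scores_n_sources(self):
        sources = ["s1", "s2", "s3", "s4"]
        rows = [row(s, "a", "t", cas="1", ind_cui="C1") for s in sources]
        stats = overlap(rows, "pair", "normalized")
        assert all(v == 4.0 for v in stats.per_source.values())
        assert stats.pooled == 4.0

    def test_matches_brute_force_recount(self):
        rng = random.Random(99)
        rows = []
        for s in ("s1", "s2", "s3", "s4"):
            for _ in range(25):
                d = f"d{rng.randint(0, 14)}"
                rows.append(row(s, d, f"t{rng.randint(0, 5)}", cas=f"c{d}"))
        stats = overlap(rows, "drug", "raw")
        incidence = {}
        for r in rows:
            incidence.setdefault(r.raw_drug_name, set()).add(r.source_id)
        for s in ("s1", "s2", "s3", "s4"):
            mine = {r.raw_drug_name for r in rows if r.source_id == s}
            expected = sum(len(incidence[d]) for d in mine) / len(mine)
            assert stats.per_source[s] == expected

    def test_scores_bounded_by_source_count(self):
        rng = random.Random(3)
        rows = [
            row(f"s{rng.randint(1, 5)}", f"d{rng.randint(0, 8)}",
                f"t{rng.randint(0, 8)}")
            for _ in range(120)
        ]
        n_sources = len({r.source_id for r in rows})
        for entity in ("drug", "indication", "pair"):
            stats = overlap(rows, entity, "raw")
            for v in stats.per_source.values():
                assert 1.0 <= v <= n_sources


class TestOverlapChange:
    def _stats(self, entity, stage, per_source, pooled):
        return OverlapStats(entity=entity, stage=stage,
                            per_source=per_source, pooled=pooled)

    def test_printed_legend_example(self):
        raw = self._stats("drug", "raw", {"evoc_eProj": 1.00}, 1.64)
        norm = self._stats("drug", "normalized", {"evoc_eProj": 2.21}, 1.87)
        change = overlap_change(raw, norm)
        assert present(change.per_source["evoc_eProj"]) == 1.21
        assert present(change.pooled) == 0.23

    def test_identity_normalization_changes_nothing(self):
        rows = [row("s1", "a", "t", cas=None, ind_cui=None),
                row("s2", "a", "t", cas=None, ind_cui=None)]
        raw = overlap(rows, "pair", "raw")
        # with no normalization data the normalized space falls back to raw keys
        norm = overlap(rows, "pair", "normalized")
        change = overlap_change(raw, norm)
        assert all(v == 0.0 for v in change.per_source.values())
        assert change.pooled == 0.0

    def test_source_set_mismatch_rejected(self):
        raw = self._stats("drug", "raw", {"s1": 1.0}, 1.0)
        norm = self._stats("drug", "normalized", {"s2": 1.0}, 1.0)
        with pytest.raises(ConsistencyError):
            overlap_change(raw, norm)

    def test_entity_mismatch_rejected(self):
        raw = self._stats("drug", "raw", {"s1": 1.0}, 1.0)
        norm = self._stats("indication", "normalized", {"s1": 1.0}, 1.0)
        with pytest.raises(ConsistencyError):
            overlap_change(raw, norm)


class TestZipf:
    def test_small_example(self):
        rows = [row("s1", "shared", "t"), row("s2", "shared", "t"),
                row("s1", "only1", "t"), row("s2", "only2", "t")]
        assert zipf(rows, "drug", "raw") == {1: 2, 2: 1}

    def test_counts_conserve_unique_entities(self):
        rng = random.Random(17)
        rows = [
            row(f"s{rng.randint(1, 6)}", f"d{rng.randint(0, 20)}",
                f"t{rng.randint(0, 20)}")
            for _ in range(200)
        ]
        for entity in ("drug", "indication", "pair"):
            hist = zipf(rows, entity, "raw")
            uniques = {
                (r.raw_drug_name, r.target) if entity == "pair"
                else (r.raw_drug_name if entity == "drug" else r.target)
                for r in rows
            }
            assert sum(hist.values()) == len(uniques)


class TestRichness:
    def test_arithmetic_mean_indications_per_drug(self):
        rows = [row("s1", "A", t, ind_cui=f"C{t}") for t in ("t1", "t2", "t3")]
        rows.append(row("s1", "B", "t9", ind_cui="C9"))
        rich = richness(rows, "raw")
        assert rich["s1"].indications_per_drug == 2.0

    def test_private_singletons_give_unity(self):
        rows = [row("s1", f"d{i}", f"t{i}") for i in range(5)]
        rich = richness(rows, "raw")
        assert rich["s1"].indications_per_drug == 1.0
        assert rich["s1"].drugs_per_indication == 1.0

    def test_consistency_identity(self):
        rng = random.Random(8)
        rows = [
            row("s1", f"d{rng.randint(0, 6)}", f"t{rng.randint(0, 9)}")
            for _ in range(60)
        ]
        rich = richness(rows, "raw")
        drugs = {r.raw_drug_name for r in rows}
        pairs = {(r.raw_drug_name, r.target) for r in rows}
        assert rich["s1"].indications_per_drug * len(drugs) == pytest.approx(len(pairs))


def test_present_rounds_half_even_to_two_places():
    assert present(2.125) == 2.12
    assert present(2.135) == 2.14
    assert present(1.005) == 1.0
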
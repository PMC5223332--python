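"""Synthetic drug-indication worlds with exact ground truth.

The generator plays the role of the licensed/proprietary corpora the real
database was built from: it fabricates concept dictionaries (a CAS-bearing
chemical authority and a UMLS-like medical authority), a phenotype remap
table, and raw sources in all three export styles, while recording for every
emitted string its true concept. Because the record of what was emitted is
kept as plain per-source entity sets, every integration metric has an
analytic twin (:func:`expected_metrics`) computed by set arithmetic alone —
independent of the ingest/normalize/assemble code path it is used to check.

What the worlds emulate: multiple sources naming the same drug via preferred
terms, synonyms and salt variants; indications phrased as disease terms or
as therapeutic-class terms that need phenotypic remapping (with a
configurable "stuck" residue); nested hierarchy levels with deliberate term
repetition; free-text indication sections including a configurable fraction
exceeding the tractability cutoff; plus blocklisted role objects,
combination products and ill-formed names that the filters must drop.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .defaults import DEFAULT_SALT_TOKENS, default_scheme
from .errors import ValidationError
from .ingest import RawSourceRecord, SourceStyle
from .lexicon import (
    Authority,
    ConceptDictionary,
    ConceptEntry,
    RemapTable,
    SemanticTypeScheme,
)

__all__ = [
    "WorldSpec",
    "DrugConcept",
    "IndicationUnit",
    "GroundTruth",
    "World",
    "build_world",
    "emit_sources",
    "expected_metrics",
]

_SYLLABLES = (
    "ba be bo bu da de do du fa fe fi fo ga ge gi go ka ke ko ku la le li lo "
    "ma me mi mo na ne ni no pa pe pi po ra re ri ro sa se si so ta te ti to "
    "va ve vi vo za ze zi zo"
).split()

_DISEASE_SUFFIXES = ("disease", "syndrome", "infection", "disorder")
_CLASS_SUFFIXES = ("inhibitors", "agents", "blockers", "modulators")

ENTITIES = ("drug", "indication", "pair")


@dataclass(frozen=True)
class WorldSpec:
    """Study conditions for one synthetic world; all randomness hangs off *seed*."""

    n_sources: int = 3
    n_drug_concepts: int = 30
    n_indication_concepts: int = 24
    synonyms_per_concept: int = 2       # total aliases per concept incl. the PT
    salt_variant_rate: float = 0.25
    unmappable_rate: float = 0.05
    nonphenotypic_rate: float = 0.3     # fraction of indication units with a class term
    stuck_rate: float = 0.1             # fraction of class terms without a remap entry
    share_fraction: float = 0.3         # fraction of concepts shared by all sources
    indications_per_drug_mean: float = 3.0
    freetext_overlong_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "salt_variant_rate": self.salt_variant_rate,
            "unmappable_rate": self.unmappable_rate,
            "nonphenotypic_rate": self.nonphenotypic_rate,
            "stuck_rate": self.stuck_rate,
            "share_fraction": self.share_fraction,
            "freetext_overlong_rate": self.freetext_overlong_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.n_sources < 1:
            raise ValidationError("n_sources must be >= 1")
        if self.n_drug_concepts < self.n_sources:
            raise ValidationError("need at least one drug concept per source")
        if self.n_indication_concepts < self.n_sources:
            raise ValidationError("need at least one indication concept per source")
        if self.synonyms_per_concept < 1:
            raise ValidationError("synonyms_per_concept must be >= 1")
        if self.indications_per_drug_mean < 1:
            raise ValidationError("indications_per_drug_mean must be >= 1")


@dataclass(frozen=True)
class DrugConcept:
    cas: str
    cui: str
    preferred_term: str
    synonyms: tuple[str, ...]            # S-status aliases (PT excluded)
    salt_variant: Optional[str] = None   # alias in no dictionary; resolves as NARROWER


@dataclass(frozen=True)
class IndicationUnit:
    """One underlying indication: a disease concept, optionally a class term."""

    disease_cui: str
    disease_pt: str
    disease_synonyms: tuple[str, ...]
    class_cui: Optional[str] = None
    class_pt: Optional[str] = None
    class_synonyms: tuple[str, ...] = ()
    class_remapped: bool = False         # class -> disease entry in the remap table

    def final_key(self, phrased_as_class: bool) -> tuple[str, str]:
        """Ground-truth normalized identity of a mappable phrasing."""
        if phrased_as_class and self.class_cui:
            if self.class_remapped:
                return ("cui", self.disease_cui)
            return ("cui", self.class_cui)
        return ("cui", self.disease_cui)


@dataclass
class GroundTruth:
    """Exact record of everything emitted, keyed the way the metrics key it."""

    raw: dict[str, dict[str, set]] = field(default_factory=dict)
    norm: dict[str, dict[str, set]] = field(default_factory=dict)
    alias_norm: dict[str, tuple[str, str]] = field(default_factory=dict)
    term_norm: dict[str, tuple[str, str]] = field(default_factory=dict)
    planned: dict[str, Counter] = field(default_factory=dict)

    def _ensure(self, source: str) -> None:
        if source not in self.raw:
            self.raw[source] = {e: set() for e in ENTITIES}
            self.norm[source] = {e: set() for e in ENTITIES}
            self.planned[source] = Counter()

    def record_pair(
        self,
        source: str,
        alias: str,
        dkey: tuple[str, str],
        term: str,
        ikey: tuple[str, str],
    ) -> None:
        self._ensure(source)
        self.raw[source]["drug"].add(alias)
        self.raw[source]["indication"].add(term)
        self.raw[source]["pair"].add((alias, term))
        self.norm[source]["drug"].add(dkey)
        self.norm[source]["indication"].add(ikey)
        self.norm[source]["pair"].add((dkey, ikey))
        self.alias_norm[alias] = dkey
        self.term_norm[term] = ikey


@dataclass
class World:
    spec: WorldSpec
    drug_concepts: tuple[DrugConcept, ...]
    units: tuple[IndicationUnit, ...]
    dictionaries: tuple[ConceptDictionary, ...]
    ranking: tuple[Authority, ...]
    remap: RemapTable
    scheme: SemanticTypeScheme
    cui_authority: str
    ground_truth: GroundTruth = field(default_factory=GroundTruth)


def _new_word(rng: random.Random, used: set[str], lo: int = 2, hi: int = 4) -> str:
    while True:
        word = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(lo, hi)))
        if word not in used:
            used.add(word)
            return word


def build_world(spec: WorldSpec) -> World:
    """Build dictionaries, remap table, scheme and concept inventory.

    Deterministic: the same spec (including its seed) yields an identical
    world. Every alias that will ever be emitted is decidable by
    construction — synonyms resolve exactly, salt variants resolve as
    narrower matches, and unmappable names are invented fresh at emission.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    used_words: set[str] = set()
    used_cas: set[str] = set()
    salt_tokens = sorted(DEFAULT_SALT_TOKENS)

    drugs: list[DrugConcept] = []
    for i in range(spec.n_drug_concepts):
        pt = _new_word(rng, used_words)
        synonyms = tuple(
            _new_word(rng, used_words) for _ in range(spec.synonyms_per_concept - 1)
        )
        while True:
            cas = f"{rng.randint(100, 99999)}-{rng.randint(10, 99)}-{rng.randint(0, 9)}"
            if cas not in used_cas:
                used_cas.add(cas)
                break
        salt_variant = None
        if rng.random() < spec.salt_variant_rate:
            salt_variant = f"{pt} {rng.choice(salt_tokens)}"
        drugs.append(
            DrugConcept(
                cas=cas,
                cui=f"C1{i:06d}",
                preferred_term=pt,
                synonyms=synonyms,
                salt_variant=salt_variant,
            )
        )

    units: list[IndicationUnit] = []
    remap_entries: dict[str, str] = {}
    for j in range(spec.n_indication_concepts):
        disease_pt = f"{_new_word(rng, used_words)} {rng.choice(_DISEASE_SUFFIXES)}"
        disease_syns = tuple(
            f"{_new_word(rng, used_words)} {rng.choice(_DISEASE_SUFFIXES)}"
            for _ in range(spec.synonyms_per_concept - 1)
        )
        disease_cui = f"C0{j:06d}"
        class_cui = class_pt = None
        class_syns: tuple[str, ...] = ()
        class_remapped = False
        if rng.random() < spec.nonphenotypic_rate:
            class_cui = f"C8{j:06d}"
            class_pt = f"{_new_word(rng, used_words)} {rng.choice(_CLASS_SUFFIXES)}"
            class_syns = tuple(
                f"{_new_word(rng, used_words)} {rng.choice(_CLASS_SUFFIXES)}"
                for _ in range(spec.synonyms_per_concept - 1)
            )
            class_remapped = rng.random() >= spec.stuck_rate
            if class_remapped:
                remap_entries[class_cui] = disease_cui
        units.append(
            IndicationUnit(
                disease_cui=disease_cui,
                disease_pt=disease_pt,
                disease_synonyms=disease_syns,
                class_cui=class_cui,
                class_pt=class_pt,
                class_synonyms=class_syns,
                class_remapped=class_remapped,
            )
        )

    chemref_auth = Authority("chemref", 1)
    umls_auth = Authority("umls", 2)
    chem_entries = [
        ConceptEntry(
            concept_id=d.cas,
            preferred_term=d.preferred_term,
            synonyms=((d.preferred_term, "P"),)
            + tuple((s, "S") for s in d.synonyms),
            cas_number=d.cas,
        )
        for d in drugs
    ]
    umls_entries = [
        ConceptEntry(
            concept_id=d.cui,
            preferred_term=d.preferred_term,
            synonyms=((d.preferred_term, "P"),)
            + tuple((s, "S") for s in d.synonyms),
            semantic_types=("PHSU",),
        )
        for d in drugs
    ]
    for u in units:
        umls_entries.append(
            ConceptEntry(
                concept_id=u.disease_cui,
                preferred_term=u.disease_pt,
                synonyms=((u.disease_pt, "P"),)
                + tuple((s, "S") for s in u.disease_synonyms),
                semantic_types=("DSYN",),
            )
        )
        if u.class_cui:
            umls_entries.append(
                ConceptEntry(
                    concept_id=u.class_cui,
                    preferred_term=u.class_pt or "",
                    synonyms=((u.class_pt or "", "P"),)
                    + tuple((s, "S") for s in u.class_synonyms),
                    semantic_types=("ANTB",),
                )
            )

    scheme = default_scheme()
    remap = RemapTable(remap_entries)
    chemref = ConceptDictionary(chemref_auth, chem_entries)
    umls = ConceptDictionary(umls_auth, umls_entries)
    remap.validate_against(umls, scheme)
    return World(
        spec=spec,
        drug_concepts=tuple(drugs),
        units=tuple(units),
        dictionaries=(chemref, umls),
        ranking=(chemref_auth, umls_auth),
        remap=remap,
        scheme=scheme,
        cui_authority="umls",
    )


def _partition(items: list, n_sources: int, share_fraction: float, rng: random.Random):
    """Shared pool (all sources) plus round-robin private pools."""
    n_shared = round(share_fraction * len(items))
    shared = items[:n_shared]
    privates: list[list] = [[] for _ in range(n_sources)]
    for i, item in enumerate(items[n_shared:]):
        privates[i % n_sources].append(item)
    return [shared + privates[i] for i in range(n_sources)]


_STYLE_CYCLE = (SourceStyle.PAIR, SourceStyle.HIERARCHY, SourceStyle.FREETEXT)

_OVERLONG_FILLER = (
    " Detailed guidance on dosage, administration, monitoring and special"
    " populations continues at considerable length in this section."
)


def emit_sources(world: World) -> dict[str, list[RawSourceRecord]]:
    """Emit raw source files for every source and record the ground truth.

    Sources cycle through the three styles. Each source draws drugs and
    indication units from a shared pool (per ``share_fraction``) plus a
    private pool, picks one alias per drug and one phrasing per indication
    unit (class phrasing for hierarchy-style sources where available), and
    adds the planned noise: blocklisted role objects, combination products,
    ill-formed names, duplicate hierarchy levels and overlong texts.
    Deterministic under the spec's seed; calling twice re-emits identically.
    """
    spec = world.spec
    rng = random.Random(spec.seed + 1000003)
    world.ground_truth = GroundTruth()
    gt = world.ground_truth
    used_words = {w for d in world.drug_concepts
                  for w in (d.preferred_term, *d.synonyms)}
    for u in world.units:
        for t in (u.disease_pt, *u.disease_synonyms, u.class_pt or "",
                  *u.class_synonyms):
            for w in t.split():
                used_words.add(w)

    drug_pools = _partition(list(world.drug_concepts), spec.n_sources,
                            spec.share_fraction, rng)
    unit_pools = _partition(list(world.units), spec.n_sources,
                            spec.share_fraction, rng)

    sources: dict[str, list[RawSourceRecord]] = {}
    for i in range(spec.n_sources):
        style = _STYLE_CYCLE[i % len(_STYLE_CYCLE)]
        sid = f"{style.value.lower()}_{i + 1:02d}"
        my_drugs = drug_pools[i]
        my_units = unit_pools[i]
        records: list[RawSourceRecord] = []
        gt._ensure(sid)
        planned = gt.planned[sid]

        alias_of: dict[DrugConcept, tuple[str, tuple[str, str]]] = {}
        for d in my_drugs:
            if rng.random() < spec.unmappable_rate:
                alias = _new_word(rng, used_words)
                alias_of[d] = (alias, ("raw", alias))
            else:
                options = [d.preferred_term, *d.synonyms]
                if d.salt_variant:
                    options.append(d.salt_variant)
                alias_of[d] = (rng.choice(options), ("cas", d.cas))

        term_of: dict[IndicationUnit, tuple[str, tuple[str, str]]] = {}
        for u in my_units:
            phrased_as_class = style is SourceStyle.HIERARCHY and u.class_cui is not None
            unmappable = (
                style is not SourceStyle.FREETEXT
                and rng.random() < spec.unmappable_rate
            )
            if unmappable:
                term = f"{_new_word(rng, used_words)} {rng.choice(_DISEASE_SUFFIXES)}"
                term_of[u] = (term, ("raw", term))
            elif phrased_as_class:
                term = rng.choice([u.class_pt, *u.class_synonyms])
                term_of[u] = (term, u.final_key(True))
            else:
                term = rng.choice([u.disease_pt, *u.disease_synonyms])
                term_of[u] = (term, u.final_key(False))

        units_per_drug: dict[DrugConcept, list[IndicationUnit]] = {}
        for d in my_drugs:
            k = int(round(rng.gauss(spec.indications_per_drug_mean, 1.0)))
            k = max(1, min(len(my_units), 8, k))
            units_per_drug[d] = rng.sample(my_units, k)

        if style is SourceStyle.PAIR:
            for d in my_drugs:
                alias, dkey = alias_of[d]
                for u in units_per_drug[d]:
                    term, ikey = term_of[u]
                    records.append(
                        RawSourceRecord(sid, style, alias,
                                        relation="may_treat", term=term)
                    )
                    gt.record_pair(sid, alias, dkey, term, ikey)
            n_blocked = max(1, len(my_drugs) // 5)
            for _ in range(n_blocked):
                d = rng.choice(my_drugs)
                records.append(
                    RawSourceRecord(
                        sid, style, alias_of[d][0], relation="has_role",
                        term=rng.choice(["metabolite", "prodrug", "epitope"]),
                    )
                )
            planned["role_blocklist"] = n_blocked
            n_bad_rel = max(1, len(my_drugs) // 10)
            for _ in range(n_bad_rel):
                d = rng.choice(my_drugs)
                records.append(
                    RawSourceRecord(
                        sid, style, alias_of[d][0], relation="has_part",
                        term=rng.choice([u.disease_pt for u in my_units]),
                    )
                )
            planned["relation_not_allowed"] = n_bad_rel

        elif style is SourceStyle.HIERARCHY:
            for idx, d in enumerate(my_drugs):
                alias, dkey = alias_of[d]
                base = f"{chr(65 + idx % 26)}{idx % 100:02d}"
                levels: list[tuple[str, str]] = []
                code = base
                terms = [term_of[u] for u in units_per_drug[d]]
                for term, _ikey in terms:
                    levels.append((code, term))
                    code += chr(65 + len(levels) % 26)
                if rng.random() < 0.3:
                    # deliberate repetition of a term at an adjacent level
                    levels.insert(1, (levels[0][0] + "X", levels[0][1]))
                    planned["duplicate_term"] += 1
                records.append(
                    RawSourceRecord(sid, style, alias, levels=tuple(levels))
                )
                for term, ikey in terms:
                    gt.record_pair(sid, alias, dkey, term, ikey)
            if len(my_drugs) >= 2:
                a1 = alias_of[my_drugs[0]][0]
                a2 = alias_of[my_drugs[1]][0]
                records.append(
                    RawSourceRecord(
                        sid, style, f"{a1} and {a2}",
                        levels=(("Z99", term_of[my_units[0]][0]),),
                    )
                )
                planned["combination_drug"] += 1
            records.append(
                RawSourceRecord(sid, style, "B01",
                                levels=(("Z98", term_of[my_units[0]][0]),))
            )
            planned["ill_formed_drug"] += 1

        else:  # FREETEXT
            for d in my_drugs:
                alias, dkey = alias_of[d]
                terms = [term_of[u] for u in units_per_drug[d]]
                text = (
                    "For the treatment of "
                    + " and ".join(term for term, _ in terms)
                    + "."
                )
                records.append(
                    RawSourceRecord(
                        sid, style, alias, text=text,
                        trade_name=f"TN{rng.randint(100, 999)}",
                        dosage=f"{rng.choice([5, 10, 25, 50])} mg",
                        supplier=f"supplier{rng.randint(1, 9)}",
                    )
                )
                for term, ikey in terms:
                    gt.record_pair(sid, alias, dkey, term, ikey)
                if rng.random() < 0.2:
                    records.append(
                        RawSourceRecord(
                            sid, style, alias, text=text,
                            trade_name=f"TN{rng.randint(100, 999)}",
                            dosage=f"{rng.choice([5, 10, 25, 50])} mg",
                            supplier=f"supplier{rng.randint(1, 9)}",
                        )
                    )
                    planned["duplicate"] += 1
                if rng.random() < spec.freetext_overlong_rate:
                    long_text = text
                    while len(long_text) < 560:
                        long_text += _OVERLONG_FILLER
                    records.append(
                        RawSourceRecord(
                            sid, style, alias, text=long_text,
                            trade_name=f"TN{rng.randint(100, 999)}",
                        )
                    )
                    planned["overlong_text"] += 1
            if len(my_drugs) >= 2:
                a1 = alias_of[my_drugs[0]][0]
                a2 = alias_of[my_drugs[1]][0]
                records.append(
                    RawSourceRecord(
                        sid, style, f"{a1} and {a2}",
                        text="For the treatment of nothing in particular.",
                    )
                )
                planned["combination_product"] += 1

        sources[sid] = records
    return sources


def expected_metrics(world: World) -> dict:
    """Analytic metrics computed from the ground truth by set arithmetic.

    Returns the same JSON-style structure as
    :func:`didkit.pipeline.metrics_summary` so the two can be compared for
    exact equality. Shares no code with the pipeline path: everything here
    is recomputed from the per-source emission record.
    """
    gt = world.ground_truth
    if not gt.raw:
        raise ValidationError("emit_sources must run before expected_metrics")
    sources = sorted(gt.raw)

    def tr_block(mapping: dict[str, tuple[str, str]]) -> list:
        u = len(mapping)
        x = sum(1 for key in mapping.values() if key[0] == "raw")
        n = len({key for key in mapping.values() if key[0] != "raw"})
        return [n, x, u, (n + x) / u]

    def sets_for(entity: str, stage: str) -> dict[str, set]:
        store = gt.raw if stage == "raw" else gt.norm
        return {s: store[s][entity] for s in sources}

    def overlap_block(entity: str, stage: str) -> dict:
        sets = sets_for(entity, stage)
        sharing: Counter = Counter()
        for s in sources:
            for key in sets[s]:
                sharing[key] += 1
        per_source = {
            s: sum(sharing[k] for k in sets[s]) / len(sets[s]) for s in sources
        }
        pooled = sum(sharing.values()) / len(sharing)
        return {"per_source": per_source, "pooled": pooled}

    def zipf_block(entity: str, stage: str) -> dict:
        sets = sets_for(entity, stage)
        sharing: Counter = Counter()
        for s in sources:
            for key in sets[s]:
                sharing[key] += 1
        hist = {str(k): 0 for k in range(1, len(sources) + 1)}
        for count in sharing.values():
            hist[str(count)] += 1
        return hist

    coverage_counts = {
        s: {e: len(gt.norm[s][e]) for e in ENTITIES} for s in sources
    }
    totals = {
        e: len(set().union(*(gt.norm[s][e] for s in sources))) for e in ENTITIES
    }
    coverage_pct = {
        s: {e: 100.0 * coverage_counts[s][e] / totals[e] for e in ENTITIES}
        for s in sources
    }

    richness = {}
    for stage in ("raw", "normalized"):
        store = gt.raw if stage == "raw" else gt.norm
        richness[stage] = {
            s: [
                len(store[s]["pair"]) / len(store[s]["drug"]),
                len(store[s]["pair"]) / len(store[s]["indication"]),
            ]
            for s in sources
        }

    return {
        "tr": {
            "drug": tr_block(gt.alias_norm),
            "indication": tr_block(gt.term_norm),
        },
        "overlap": {
            f"{entity}/{stage}": overlap_block(entity, stage)
            for entity in ENTITIES
            for stage in ("raw", "normalized")
        },
        "zipf": {
            f"{entity}/{stage}": zipf_block(entity, stage)
            for entity in ENTITIES
            for stage in ("raw", "normalized")
        },
        "coverage": {
            "totals": totals,
            "counts": coverage_counts,
            "percentages": coverage_pct,
        },
        "richness": richness,
    }
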
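"""Integration metrics over the assembled drug-indication table.

* **Terminological reduction** TR = (N + X) / U, where N is the number of
  distinct normalized identifiers among the mapped names, X the number of
  unique raw names left unnormalized and U the number of unique raw names.
  TR = 1 means normalization merged nothing; lower is stronger unification.
  For drug names the normalized identifier can be the CAS number, the CUI,
  or either (selectable), mirroring the three reported variants.
* **Coverage** — per-source unique normalized drugs / indications / pairs,
  as counts and as percentages of the global unique totals.
* **Overlap** — for each source, the mean over its unique entities of the
  number of sources containing that entity (self always counts, so scores
  lie in [1, S]); the pooled "All" score averages over the union of unique
  entities. The change score is normalized minus raw, elementwise.
* **Zipf sharing distribution** — for each sharing count k in 1..S, the
  number of unique entities contributed by exactly k sources.
* **Richness** — per-source average indications per drug and drugs per
  indication (unique pairs divided by unique drugs / unique indications).

Identity spaces: at the *raw* stage drugs are raw names and indications are
target strings. At the *normalized* stage entities are namespaced keys —
``("cas", ...)`` / ``("cui", ...)`` for mapped names, falling back to
``("raw", ...)`` for unmapped ones so that unnormalizable content still
counts as (private) content. Reported numbers are kept at full precision;
:func:`present` applies the 2-decimal round-half-even used for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Hashable, Iterable, Literal, Mapping, Optional, Sequence

from .did_table import DIDRow
from .errors import ConsistencyError, InputError

__all__ = [
    "Entity",
    "Stage",
    "DrugBasis",
    "TRResult",
    "OverlapStats",
    "CoverageStats",
    "SourceRichness",
    "tr",
    "tr_drugs",
    "tr_indications",
    "coverage",
    "overlap",
    "overlap_change",
    "zipf",
    "richness",
    "present",
]

Entity = Literal["drug", "indication", "pair"]
Stage = Literal["raw", "normalized"]
DrugBasis = Literal["cas", "cui", "either"]

ENTITIES: tuple[Entity, ...] = ("drug", "indication", "pair")
STAGES: tuple[Stage, ...] = ("raw", "normalized")


def present(value: float, places: int = 2) -> float:
    """Presentation rounding: *places* decimals, round-half-even."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))


# --------------------------------------------------------------------------
# entity keys


def drug_norm_key(row: DIDRow, basis: DrugBasis = "either") -> tuple[str, str]:
    if basis not in ("cas", "cui", "either"):
        raise InputError(f"unknown drug basis {basis!r}")
    if basis in ("cas", "either") and row.cas_number:
        return ("cas", row.cas_number)
    if basis in ("cui", "either") and row.drug_cui:
        return ("cui", row.drug_cui)
    return ("raw", row.raw_drug_name)


def ind_norm_key(row: DIDRow) -> tuple[str, str]:
    if row.ind_cui:
        return ("cui", row.ind_cui)
    return ("raw", row.target)


def _entity_key(row: DIDRow, entity: Entity, stage: Stage, basis: DrugBasis) -> Hashable:
    if stage == "raw":
        if entity == "drug":
            return row.raw_drug_name
        if entity == "indication":
            return row.target
        return (row.raw_drug_name, row.target)
    if entity == "drug":
        return drug_norm_key(row, basis)
    if entity == "indication":
        return ind_norm_key(row)
    return (drug_norm_key(row, basis), ind_norm_key(row))


def _source_sets(
    rows: Sequence[DIDRow], entity: Entity, stage: Stage, basis: DrugBasis
) -> dict[str, set[Hashable]]:
    out: dict[str, set[Hashable]] = {}
    for row in rows:
        out.setdefault(row.source_id, set()).add(_entity_key(row, entity, stage, basis))
    return out


# --------------------------------------------------------------------------
# terminological reduction


@dataclass(frozen=True)
class TRResult:
    """TR = (N + X) / U over one set of raw names."""

    n_normalized: int     # N: distinct normalized identifiers among mapped names
    n_unnormalized: int   # X: unique raw names left unnormalized
    n_unique_raw: int     # U: unique raw names
    tr: float


def tr(
    raw_names: Iterable[str], mapping: Mapping[str, Optional[Hashable]]
) -> TRResult:
    """Terminological reduction of *raw_names* under a name -> ID mapping.

    *mapping* must be defined on every raw name; a value of None marks a name
    that remains unnormalized.
    """
    names = set(raw_names)
    if not names:
        raise InputError("tr requires at least one raw name")
    missing = [n for n in names if n not in mapping]
    if missing:
        raise InputError(f"mapping undefined for {len(missing)} raw names")
    unnormalized = sum(1 for n in names if mapping[n] is None)
    normalized_ids = {mapping[n] for n in names if mapping[n] is not None}
    n, x, u = len(normalized_ids), unnormalized, len(names)
    return TRResult(n_normalized=n, n_unnormalized=x, n_unique_raw=u, tr=(n + x) / u)


def tr_drugs(rows: Sequence[DIDRow], basis: DrugBasis = "either") -> TRResult:
    """Drug-name TR over the table, on a CAS / CUI / combined basis."""
    mapping: dict[str, Optional[Hashable]] = {}
    for row in rows:
        key = drug_norm_key(row, basis)
        mapping[row.raw_drug_name] = None if key[0] == "raw" else key
    return tr(mapping.keys(), mapping)


def tr_indications(rows: Sequence[DIDRow]) -> TRResult:
    """Indication-target TR over the table (final, post-remap CUIs)."""
    mapping: dict[str, Optional[Hashable]] = {}
    for row in rows:
        key = ind_norm_key(row)
        mapping[row.target] = None if key[0] == "raw" else key
    return tr(mapping.keys(), mapping)


# --------------------------------------------------------------------------
# coverage


@dataclass(frozen=True)
class CoverageStats:
    """Per-source unique counts and percentages of the global unique totals."""

    stage: Stage
    totals: dict[Entity, int]
    counts: dict[str, dict[Entity, int]]       # source -> entity -> count
    percentages: dict[str, dict[Entity, float]]


def coverage(
    rows: Sequence[DIDRow], stage: Stage = "normalized", basis: DrugBasis = "either"
) -> CoverageStats:
    if not rows:
        raise InputError("coverage requires a nonempty table")
    totals: dict[Entity, int] = {}
    counts: dict[str, dict[Entity, int]] = {}
    percentages: dict[str, dict[Entity, float]] = {}
    per_entity_sets = {e: _source_sets(rows, e, stage, basis) for e in ENTITIES}
    for entity in ENTITIES:
        union: set[Hashable] = set()
        for s in per_entity_sets[entity].values():
            union |= s
        totals[entity] = len(union)
    for source in sorted({r.source_id for r in rows}):
        counts[source] = {}
        percentages[source] = {}
        for entity in ENTITIES:
            c = len(per_entity_sets[entity].get(source, ()))
            counts[source][entity] = c
            percentages[source][entity] = 100.0 * c / totals[entity]
    return CoverageStats(stage=stage, totals=totals, counts=counts,
                         percentages=percentages)


# --------------------------------------------------------------------------
# overlap


@dataclass(frozen=True)
class OverlapStats:
    """Average sharing counts for one entity at one stage (or their change)."""

    entity: Entity
    stage: str  # "raw", "normalized" or "change"
    per_source: dict[str, float]
    pooled: float  # the "All" row: mean over the union of unique entities


def overlap(
    rows: Sequence[DIDRow],
    entity: Entity,
    stage: Stage,
    basis: DrugBasis = "either",
) -> OverlapStats:
    """Average number of sources sharing each unique entity, per source.

    Self always counts, so every score is >= 1; a source whose entities
    appear nowhere else scores exactly 1.0.
    """
    sets = _source_sets(rows, entity, stage, basis)
    if not sets:
        raise InputError("overlap requires at least one source")
    sharing: dict[Hashable, int] = {}
    for s in sets.values():
        for key in s:
            sharing[key] = sharing.get(key, 0) + 1
    per_source = {
        source: sum(sharing[k] for k in keys) / len(keys)
        for source, keys in sets.items()
        if keys
    }
    union = set(sharing)
    pooled = sum(sharing[k] for k in union) / len(union)
    return OverlapStats(entity=entity, stage=stage, per_source=per_source,
                        pooled=pooled)


def overlap_change(raw_stats: OverlapStats, normalized_stats: OverlapStats) -> OverlapStats:
    """Change scores: normalized minus raw, elementwise over identical sources."""
    if raw_stats.entity != normalized_stats.entity:
        raise ConsistencyError(
            f"entity mismatch: {raw_stats.entity!r} vs {normalized_stats.entity!r}"
        )
    if set(raw_stats.per_source) != set(normalized_stats.per_source):
        raise ConsistencyError("overlap change requires identical source sets")
    return OverlapStats(
        entity=raw_stats.entity,
        stage="change",
        per_source={
            s: normalized_stats.per_source[s] - raw_stats.per_source[s]
            for s in raw_stats.per_source
        },
        pooled=normalized_stats.pooled - raw_stats.pooled,
    )


# --------------------------------------------------------------------------
# Zipf sharing distribution


def zipf(
    rows: Sequence[DIDRow],
    entity: Entity,
    stage: Stage,
    basis: DrugBasis = "either",
) -> dict[int, int]:
    """Histogram k -> number of unique entities shared by exactly k sources.

    Bins run 1..S (S = number of sources present); the counts sum to the
    number of unique entities at that stage.
    """
    sets = _source_sets(rows, entity, stage, basis)
    if not sets:
        raise InputError("zipf requires at least one source")
    sharing: dict[Hashable, int] = {}
    for s in sets.values():
        for key in s:
            sharing[key] = sharing.get(key, 0) + 1
    n_sources = len(sets)
    hist = {k: 0 for k in range(1, n_sources + 1)}
    for count in sharing.values():
        hist[count] += 1
    return hist


# --------------------------------------------------------------------------
# richness


@dataclass(frozen=True)
class SourceRichness:
    indications_per_drug: float
    drugs_per_indication: float


def richness(
    rows: Sequence[DIDRow], stage: Stage, basis: DrugBasis = "either"
) -> dict[str, SourceRichness]:
    """Per-source mean unique indications per drug and drugs per indication."""
    drugs = _source_sets(rows, "drug", stage, basis)
    inds = _source_sets(rows, "indication", stage, basis)
    prs = _source_sets(rows, "pair", stage, basis)
    out: dict[str, SourceRichness] = {}
    for source in sorted(drugs):
        n_drugs = len(drugs[source])
        n_inds = len(inds.get(source, ()))
        n_pairs = len(prs.get(source, ()))
        if n_drugs == 0 or n_inds == 0:
            raise InputError(f"source {source!r} has no drugs or no indications")
        out[source] = SourceRichness(
            indications_per_drug=n_pairs / n_drugs,
            drugs_per_indication=n_pairs / n_inds,
        )
    return out
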
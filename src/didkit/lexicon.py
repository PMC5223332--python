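"""Concept dictionaries, ranked authorities, semantic types and remap tables.

A :class:`ConceptDictionary` models one authority's terminology (e.g. a
ChemIDplus-like chemical dictionary or a UMLS-like medical dictionary): each
concept has an opaque identifier (CAS-number-like or CUI-like), one preferred
term (status ``P``) and any number of synonyms (status ``S``), optionally a
CAS number and semantic-type codes. Lookup is exact on a normalized term key
(case-insensitive, whitespace-collapsed; punctuation preserved).

Conflicts between authorities are resolved by an explicit ranking
(:func:`rank_resolve`): the candidate from the highest-ranked (lowest rank
number) authority wins; equal ranks are broken deterministically by the
lexicographically smallest concept identifier.

A :class:`SemanticTypeScheme` partitions semantic-type codes into *phenotypic*
types (diseases and other biological conditions, processes and functions) and
non-phenotypic ones (e.g. pharmacologic substances); a :class:`RemapTable`
carries curated mappings from non-phenotypic concepts (therapeutic classes
such as "Anti-Bacterial Agents") to phenotypic ones ("Bacterial Infections").
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._text import term_key
from .errors import ConfigurationError, InputError, ValidationError

__all__ = [
    "Authority",
    "ConceptEntry",
    "ConceptDictionary",
    "SemanticType",
    "SemanticTypeScheme",
    "RemapTable",
    "load_dictionary",
    "save_dictionary",
    "load_scheme",
    "save_scheme",
    "load_remap",
    "save_remap",
    "rank_resolve",
]

DICTIONARY_COLUMNS = ["concept_id", "term", "status", "cas_number", "semantic_types"]
SCHEME_COLUMNS = ["type_code", "tree_number", "label", "phenotypic"]
REMAP_COLUMNS = ["from_concept_id", "to_concept_id"]


@dataclass(frozen=True, order=True)
class Authority:
    """A terminology authority with a preference rank (1 = most preferred)."""

    name: str
    rank: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("authority name must be nonempty")
        if self.rank < 1:
            raise ConfigurationError(f"authority rank must be >= 1, got {self.rank}")


@dataclass(frozen=True)
class ConceptEntry:
    """One concept: preferred term, statused synonyms, optional CAS and types."""

    concept_id: str
    preferred_term: str
    synonyms: tuple[tuple[str, str], ...] = ()  # (term, status) incl. the PT as P
    cas_number: Optional[str] = None
    semantic_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.preferred_term:
            raise ValidationError(f"concept {self.concept_id!r}: empty preferred term")
        for term, status in self.synonyms:
            if status not in ("P", "S"):
                raise ValidationError(
                    f"concept {self.concept_id!r}: bad status {status!r} for {term!r}"
                )

    @property
    def terms(self) -> tuple[tuple[str, str], ...]:
        """All (term, status) pairs, guaranteeing the PT is present as P."""
        if any(s == "P" and term_key(t) == term_key(self.preferred_term)
               for t, s in self.synonyms):
            return self.synonyms
        return ((self.preferred_term, "P"),) + self.synonyms


class ConceptDictionary:
    """One authority's concept entries plus an exact-match term index."""

    def __init__(self, authority: Authority, entries: Iterable[ConceptEntry]):
        self.authority = authority
        self.entries: dict[str, ConceptEntry] = {}
        self.term_index: dict[str, list[tuple[ConceptEntry, str, str]]] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: ConceptEntry) -> None:
        if entry.concept_id in self.entries:
            raise ValidationError(
                f"duplicate concept_id {entry.concept_id!r} in dictionary "
                f"{self.authority.name!r}"
            )
        self.entries[entry.concept_id] = entry
        for term, status in entry.terms:
            self.term_index.setdefault(term_key(term), []).append((entry, term, status))

    def get(self, concept_id: str) -> Optional[ConceptEntry]:
        return self.entries.get(concept_id)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def max_key_words(self) -> int:
        """Longest indexed key in words; used by greedy phrase extraction."""
        return max((len(k.split()) for k in self.term_index), default=1)

    def lookup(self, term: str) -> list[tuple[ConceptEntry, str, str]]:
        """All (entry, matched term, status) whose term set contains *term*.

        Matching is exact on the normalized key. Raises
        :class:`~didkit.errors.InputError` on an empty or whitespace-only query.
        """
        key = term_key(term)
        if not key:
            raise InputError("lookup term must be nonempty")
        return list(self.term_index.get(key, ()))

    def lookup_key(self, term: str) -> list[tuple[ConceptEntry, str, str]]:
        """Like :meth:`lookup` but an empty key returns [] instead of raising."""
        key = term_key(term)
        if not key:
            return []
        return list(self.term_index.get(key, ()))


def lookup(dictionary: ConceptDictionary, term: str) -> list[tuple[ConceptEntry, str, str]]:
    """Module-level alias of :meth:`ConceptDictionary.lookup`."""
    return dictionary.lookup(term)


def load_dictionary(path: str | Path, authority: Authority) -> ConceptDictionary:
    """Load a dictionary from its TSV form (one row per (concept, term) pair).

    Columns: ``concept_id, term, status(P|S), cas_number, semantic_types``
    (semicolon-separated codes); header row required. Each concept must have
    exactly one P row (its preferred term); conflicting duplicates — a second
    P row or a repeated (concept_id, term) pair — are validation errors
    reported with their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"dictionary file not found: {path}")
    grouped: dict[str, dict] = {}
    order: list[str] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file (header row required)") from None
        if [h.strip() for h in header[: len(DICTIONARY_COLUMNS)]] != DICTIONARY_COLUMNS:
            raise ValidationError(
                f"{path}: bad header {header!r}, expected {DICTIONARY_COLUMNS!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ValidationError(f"{path}:{lineno}: expected >=3 columns, got {row!r}")
            cid, term, status = row[0].strip(), row[1].strip(), row[2].strip()
            cas = row[3].strip() if len(row) > 3 and row[3].strip() else None
            stypes = tuple(
                t.strip() for t in (row[4] if len(row) > 4 else "").split(";") if t.strip()
            )
            if not cid or not term:
                raise ValidationError(f"{path}:{lineno}: empty concept_id or term")
            if status not in ("P", "S"):
                raise ValidationError(
                    f"{path}:{lineno}: unknown status code {status!r} (expected P or S)"
                )
            rec = grouped.get(cid)
            if rec is None:
                rec = {"pt": None, "terms": [], "seen": set(), "cas": None, "stypes": []}
                grouped[cid] = rec
                order.append(cid)
            tkey = term_key(term)
            if tkey in rec["seen"]:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate concept_id {cid!r} "
                    f"(term {term!r} repeated)"
                )
            if status == "P":
                if rec["pt"] is not None:
                    raise ValidationError(
                        f"{path}:{lineno}: duplicate concept_id {cid!r} "
                        f"(second preferred term {term!r})"
                    )
                rec["pt"] = term
            rec["seen"].add(tkey)
            rec["terms"].append((term, status))
            if cas:
                if rec["cas"] and rec["cas"] != cas:
                    raise ValidationError(
                        f"{path}:{lineno}: conflicting CAS numbers for {cid!r}"
                    )
                rec["cas"] = cas
            for st in stypes:
                if st not in rec["stypes"]:
                    rec["stypes"].append(st)
    entries = []
    for cid in order:
        rec = grouped[cid]
        if rec["pt"] is None:
            raise ValidationError(f"{path}: concept {cid!r} has no P (preferred) term")
        entries.append(
            ConceptEntry(
                concept_id=cid,
                preferred_term=rec["pt"],
                synonyms=tuple(rec["terms"]),
                cas_number=rec["cas"],
                semantic_types=tuple(rec["stypes"]),
            )
        )
    return ConceptDictionary(authority, entries)


def save_dictionary(dictionary: ConceptDictionary, path: str | Path) -> None:
    """Write a dictionary back to the TSV form read by :func:`load_dictionary`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(DICTIONARY_COLUMNS)
        for cid in sorted(dictionary.entries):
            entry = dictionary.entries[cid]
            for term, status in entry.terms:
                writer.writerow(
                    [cid, term, status, entry.cas_number or "",
                     ";".join(entry.semantic_types)]
                )


def rank_resolve(
    candidates: Mapping[str, tuple[str, str]],
    ranking: Sequence[Authority],
) -> tuple[str, str]:
    """Resolve conflicting per-authority candidates by authority rank.

    *candidates* maps authority name -> (concept_id, preferred_term). Returns
    (preferred_term, winning authority name). The candidate of the
    highest-ranked authority (lowest rank number) wins; ties between
    equal-rank authorities are broken by the lexicographically smallest
    concept_id. Deterministic and independent of the mapping's enumeration
    order.
    """
    if not candidates:
        raise InputError("rank_resolve requires at least one candidate")
    rank_of = {a.name: a.rank for a in ranking}
    unknown = sorted(set(candidates) - set(rank_of))
    if unknown:
        raise ConfigurationError(
            f"candidate authorities absent from the ranking: {unknown}"
        )
    name = min(
        candidates,
        key=lambda n: (rank_of[n], candidates[n][0], n),
    )
    return candidates[name][1], name


@dataclass(frozen=True)
class SemanticType:
    type_code: str
    tree_number: str
    label: str
    phenotypic: bool


class SemanticTypeScheme:
    """Semantic-type codes with tree numbers and a phenotypic/non-phenotypic split."""

    def __init__(self, types: Iterable[SemanticType]):
        self.types: dict[str, SemanticType] = {}
        for st in types:
            if st.type_code in self.types:
                raise ValidationError(f"duplicate semantic type code {st.type_code!r}")
            self.types[st.type_code] = st

    def is_phenotypic(self, type_code: str) -> bool:
        st = self.types.get(type_code)
        return bool(st and st.phenotypic)

    def any_phenotypic(self, type_codes: Iterable[str]) -> bool:
        """True iff at least one of *type_codes* is a phenotypic type."""
        return any(self.is_phenotypic(c) for c in type_codes)

    def __contains__(self, type_code: str) -> bool:
        return type_code in self.types

    def __len__(self) -> int:
        return len(self.types)


def load_scheme(path: str | Path) -> SemanticTypeScheme:
    """Load a semantic-type scheme TSV: type_code, tree_number, label, phenotypic(0|1)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"scheme file not found: {path}")
    types = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != SCHEME_COLUMNS:
            raise ValidationError(f"{path}: bad header, expected {SCHEME_COLUMNS!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 4 or row[3].strip() not in ("0", "1"):
                raise ValidationError(f"{path}:{lineno}: bad scheme row {row!r}")
            types.append(
                SemanticType(row[0].strip(), row[1].strip(), row[2].strip(),
                             row[3].strip() == "1")
            )
    return SemanticTypeScheme(types)


def save_scheme(scheme: SemanticTypeScheme, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SCHEME_COLUMNS)
        for code in sorted(scheme.types):
            st = scheme.types[code]
            writer.writerow([st.type_code, st.tree_number, st.label,
                             "1" if st.phenotypic else "0"])


class RemapTable:
    """Curated concept-to-phenotype remappings (source CUI -> phenotypic CUI).

    The table must be idempotent under composition: a remap target may not
    itself be remapped elsewhere.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self.mapping: dict[str, str] = dict(mapping or {})
        for src, dst in self.mapping.items():
            if src != dst and dst in self.mapping and self.mapping[dst] != dst:
                raise ValidationError(
                    f"remap table not idempotent: {src!r} -> {dst!r} -> "
                    f"{self.mapping[dst]!r}"
                )

    def get(self, concept_id: str) -> Optional[str]:
        """The remap target for *concept_id*, or None if it has no entry."""
        return self.mapping.get(concept_id)

    def apply(self, concept_id: str) -> str:
        """Remap *concept_id* if an entry exists, else return it unchanged."""
        return self.mapping.get(concept_id, concept_id)

    def __len__(self) -> int:
        return len(self.mapping)

    def validate_against(
        self, dictionary: ConceptDictionary, scheme: SemanticTypeScheme
    ) -> None:
        """Check every target resolves to a phenotypic entry of *dictionary*."""
        for src, dst in self.mapping.items():
            entry = dictionary.get(dst)
            if entry is None:
                raise ConfigurationError(
                    f"remap target {dst!r} (from {src!r}) not in dictionary "
                    f"{dictionary.authority.name!r}"
                )
            if not scheme.any_phenotypic(entry.semantic_types):
                raise ConfigurationError(
                    f"remap target {dst!r} (from {src!r}) has no phenotypic type"
                )


def load_remap(path: str | Path) -> RemapTable:
    """Load a remap TSV: from_concept_id, to_concept_id (header required)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"remap file not found: {path}")
    mapping: dict[str, str] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != REMAP_COLUMNS:
            raise ValidationError(f"{path}: bad header, expected {REMAP_COLUMNS!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise ValidationError(f"{path}:{lineno}: bad remap row {row!r}")
            src = row[0].strip()
            if src in mapping:
                raise ValidationError(f"{path}:{lineno}: duplicate source {src!r}")
            mapping[src] = row[1].strip()
    return RemapTable(mapping)


def save_remap(table: RemapTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REMAP_COLUMNS)
        for src in sorted(table.mapping):
            writer.writerow([src, table.mapping[src]])
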
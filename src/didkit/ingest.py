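"""Source adapters: raw exports -> ParsedPair streams plus filter accounting.

Three raw-data styles are supported, mirroring how drug-indication content is
actually distributed:

* ``PAIR`` — controlled (drug, relation, indication term) triples, as in
  NDFRT-like or CTD-like exports. Filtering drops disallowed relations and
  blocklisted role objects (e.g. "metabolite", "prodrug", "epitope").
* ``HIERARCHY`` — ATC-like classification entries, one (level code, term) per
  level. Each level is a candidate indication; identical terms repeated at
  nested levels collapse to one pair, and combination or ill-formed drug
  names are dropped.
* ``FREETEXT`` — label-like records with an indications text section.
  Combination products and intractably long texts (>= 540 characters after
  newline -> space conversion) are dropped, and records sharing the same
  (generic name, text) that differ only by trade name / dosage / supplier
  collapse to one. Distinct indication concepts are then extracted from the
  surviving text by greedy leftmost-longest dictionary matching
  (:func:`split_targets`).

Every adapter returns a :class:`FilterReport` whose removals plus survivors
sum exactly to the initial candidate count.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from ._text import term_key
from .defaults import (
    DEFAULT_COMBINATION_TOKENS,
    DEFAULT_RELATION_ALLOWLIST,
    DEFAULT_ROLE_BLOCKLIST,
)
from .errors import ConfigurationError, InputError
from .lexicon import ConceptDictionary

__all__ = [
    "SourceStyle",
    "RawSourceRecord",
    "ParsedPair",
    "FilterReport",
    "ingest_pair_source",
    "ingest_hierarchy_source",
    "ingest_freetext_source",
    "split_targets",
    "is_combination_name",
    "is_ill_formed_name",
]

DEFAULT_MAX_TEXT_LEN = 540

# a leading token like "B01" or "B01AC": single letter then digits/alnum
_CODE_TOKEN = re.compile(r"^[A-Za-z]\d[0-9A-Za-z]*$")
_NUMERIC = re.compile(r"^[0-9\s.,\-]+$")


class SourceStyle(str, Enum):
    PAIR = "PAIR"
    HIERARCHY = "HIERARCHY"
    FREETEXT = "FREETEXT"


@dataclass(frozen=True)
class RawSourceRecord:
    """One raw record from a source export; *style* selects the payload."""

    source_id: str
    style: SourceStyle
    drug_field: str
    relation: Optional[str] = None          # PAIR
    term: Optional[str] = None              # PAIR
    levels: Optional[tuple[tuple[str, str], ...]] = None  # HIERARCHY: (code, term)
    text: Optional[str] = None              # FREETEXT
    trade_name: str = ""                    # FREETEXT aux
    dosage: str = ""                        # FREETEXT aux
    supplier: str = ""                      # FREETEXT aux


@dataclass(frozen=True)
class ParsedPair:
    """One (source, raw drug name, entire indication value, target) record."""

    source_id: str
    raw_drug_name: str
    entire_value: str
    target: str
    target_equals_entire: bool


@dataclass
class FilterReport:
    """Accounting for one adapter run: initial -> filtered -> parsed."""

    initial: int = 0
    filtered: int = 0
    parsed: int = 0
    per_rule_removed: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        removed = sum(self.per_rule_removed.values())
        if removed + self.filtered != self.initial:
            raise ConfigurationError(
                f"filter accounting broken: {removed} removed + "
                f"{self.filtered} filtered != {self.initial} initial"
            )


def is_combination_name(
    name: str, tokens: Sequence[str] = DEFAULT_COMBINATION_TOKENS
) -> bool:
    """Heuristic combination-product detection by separator tokens."""
    low = name.casefold()
    return any(tok in low for tok in tokens)


def is_ill_formed_name(name: str) -> bool:
    """Empty, purely numeric, or leading classification-code token."""
    stripped = name.strip()
    if not stripped:
        return True
    if _NUMERIC.match(stripped):
        return True
    first = stripped.split()[0]
    return bool(_CODE_TOKEN.match(first))


def ingest_pair_source(
    records: Iterable[RawSourceRecord],
    relation_allowlist: Optional[frozenset[str] | set[str]] = DEFAULT_RELATION_ALLOWLIST,
    role_blocklist: frozenset[str] | set[str] = DEFAULT_ROLE_BLOCKLIST,
) -> tuple[list[ParsedPair], FilterReport]:
    """Convert PAIR-style records to parsed pairs.

    Records whose relation is outside *relation_allowlist* (when given) or
    whose object term is in *role_blocklist* are dropped and tallied.
    Survivors have target = entire value (single-concept values), and
    duplicates on (drug, entire value) collapse.
    """
    records = list(records)
    removed: Counter[str] = Counter()
    block_keys = {term_key(t) for t in role_blocklist}
    seen: set[tuple[str, str]] = set()
    pairs: list[ParsedPair] = []
    for rec in records:
        if rec.style is not SourceStyle.PAIR:
            raise InputError(f"non-PAIR record in pair adapter: {rec!r}")
        if rec.relation is None or rec.term is None:
            raise InputError(f"PAIR record missing relation/term: {rec!r}")
        if relation_allowlist is not None and rec.relation not in relation_allowlist:
            removed["relation_not_allowed"] += 1
            continue
        if term_key(rec.term) in block_keys:
            removed["role_blocklist"] += 1
            continue
        key = (rec.drug_field, rec.term)
        if key in seen:
            removed["duplicate"] += 1
            continue
        seen.add(key)
        pairs.append(
            ParsedPair(rec.source_id, rec.drug_field, rec.term, rec.term, True)
        )
    report = FilterReport(
        initial=len(records),
        filtered=len(pairs),
        parsed=len({(p.raw_drug_name, p.target) for p in pairs}),
        per_rule_removed=dict(removed),
    )
    report.check()
    return pairs, report


def ingest_hierarchy_source(
    records: Iterable[RawSourceRecord],
    combination_tokens: Sequence[str] = DEFAULT_COMBINATION_TOKENS,
) -> tuple[list[ParsedPair], FilterReport]:
    """Convert HIERARCHY-style records (one ordered level list per record).

    Every hierarchy level is a candidate (drug, term) pair; identical terms
    repeated at nested levels (e.g. the same class name at B01 and B01A)
    collapse to one pair. Combination and ill-formed drug names are dropped
    with all their levels tallied.
    """
    records = list(records)
    removed: Counter[str] = Counter()
    seen: set[tuple[str, str]] = set()
    pairs: list[ParsedPair] = []
    initial = 0
    for rec in records:
        if rec.style is not SourceStyle.HIERARCHY:
            raise InputError(f"non-HIERARCHY record in hierarchy adapter: {rec!r}")
        if not rec.levels:
            raise InputError(f"hierarchy record with empty level list: {rec!r}")
        initial += len(rec.levels)
        if is_combination_name(rec.drug_field, combination_tokens):
            removed["combination_drug"] += len(rec.levels)
            continue
        if is_ill_formed_name(rec.drug_field):
            removed["ill_formed_drug"] += len(rec.levels)
            continue
        for _code, term in rec.levels:
            key = (rec.drug_field, term_key(term))
            if key in seen:
                removed["duplicate_term"] += 1
                continue
            seen.add(key)
            pairs.append(
                ParsedPair(rec.source_id, rec.drug_field, term, term, True)
            )
    report = FilterReport(
        initial=initial,
        filtered=len(pairs),
        parsed=len({(p.raw_drug_name, p.target) for p in pairs}),
        per_rule_removed=dict(removed),
    )
    report.check()
    return pairs, report


def _flatten_text(text: str) -> str:
    """Convert newlines to single spaces (length is measured on the result)."""
    return re.sub(r"\r\n|[\r\n]", " ", text)


def ingest_freetext_source(
    records: Iterable[RawSourceRecord],
    max_len: int = DEFAULT_MAX_TEXT_LEN,
    indication_dict: Optional[ConceptDictionary] = None,
    combination_tokens: Sequence[str] = DEFAULT_COMBINATION_TOKENS,
) -> tuple[list[ParsedPair], FilterReport]:
    """Convert FREETEXT-style records (label-like indications sections).

    Drops combination products and texts of length >= *max_len* (540 by
    default: 539 characters is the longest tractable text); collapses records
    sharing (generic name, text) that differ only by trade name, dosage or
    supplier. When *indication_dict* is supplied the surviving texts are
    split into targets by :func:`split_targets`; otherwise each text becomes
    its own single target.
    """
    if max_len < 0:
        raise ConfigurationError(f"max_len must be nonnegative, got {max_len}")
    records = list(records)
    removed: Counter[str] = Counter()
    seen: set[tuple[str, str]] = set()
    survivors: list[tuple[str, str, str]] = []  # (source, drug, text)
    for rec in records:
        if rec.style is not SourceStyle.FREETEXT:
            raise InputError(f"non-FREETEXT record in freetext adapter: {rec!r}")
        if rec.text is None:
            raise InputError(f"FREETEXT record missing text: {rec!r}")
        text = _flatten_text(rec.text)
        if is_combination_name(rec.drug_field, combination_tokens):
            removed["combination_product"] += 1
            continue
        if len(text) >= max_len:
            removed["overlong_text"] += 1
            continue
        key = (rec.drug_field, text)
        if key in seen:
            removed["duplicate"] += 1
            continue
        seen.add(key)
        survivors.append((rec.source_id, rec.drug_field, text))
    pairs: list[ParsedPair] = []
    pair_seen: set[tuple[str, str]] = set()
    for source_id, drug, text in survivors:
        if indication_dict is not None:
            targets = split_targets(text, indication_dict)
        else:
            targets = [(text, True)]
        for target, flag in targets:
            pkey = (drug, target)
            if pkey in pair_seen:
                continue
            pair_seen.add(pkey)
            pairs.append(ParsedPair(source_id, drug, text, target, flag))
    report = FilterReport(
        initial=len(records),
        filtered=len(survivors),
        parsed=len(pair_seen),
        per_rule_removed=dict(removed),
    )
    report.check()
    return pairs, report


def split_targets(
    entire_value: str, indication_dict: ConceptDictionary
) -> list[tuple[str, bool]]:
    """Extract distinct indication targets from a raw value by dictionary scan.

    The text is split into sentences on ``.`` and ``;``; within each sentence
    a greedy leftmost-longest scan over whitespace tokens extracts maximal
    phrases whose normalized key is in the dictionary. Extracted matches are
    non-overlapping and in left-to-right order. If no dictionary term occurs
    anywhere, the entire value is returned as its own target flagged True.
    """
    if not entire_value:
        raise InputError("entire_value must be nonempty")
    max_words = indication_dict.max_key_words
    found: list[str] = []
    seen: set[str] = set()
    for sentence_match in re.finditer(r"[^.;]+", entire_value):
        sentence = sentence_match.group(0)
        base = sentence_match.start()
        tokens = list(re.finditer(r"\S+", sentence))
        i = 0
        while i < len(tokens):
            matched_end = None
            for j in range(min(i + max_words, len(tokens)), i, -1):
                phrase = entire_value[base + tokens[i].start(): base + tokens[j - 1].end()]
                if indication_dict.lookup_key(phrase):
                    matched_end = j
                    break
            if matched_end is None:
                i += 1
                continue
            phrase = entire_value[base + tokens[i].start(): base + tokens[matched_end - 1].end()]
            if phrase not in seen:
                seen.add(phrase)
                found.append(phrase)
            i = matched_end
    if not found:
        return [(entire_value, True)]
    return [(t, t == entire_value) for t in found]
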
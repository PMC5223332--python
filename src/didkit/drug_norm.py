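"""Drug/chemical name normalization across ranked concept dictionaries.

Raw names are resolved to CAS-style and CUI-style identifiers by exact
(case-insensitive) lookup in each supplied dictionary, with each match's
quality classified:

* ``PT_EXACT`` — key-equal to a preferred term;
* ``SYNONYM`` — key-equal to a non-preferred synonym;
* ``QUASI_SYNONYM`` — differs only by a minor chemical modifier
  ("cidofovir anhydrous" vs "Cidofovir");
* ``NARROWER`` — the raw name is a salt/derivative/formulation of the
  standard term ("arformoterol fumarate" vs "Arformoterol"); directionality
  is raw-to-standard;
* ``BROADER`` — the standard term is the salt form of the raw name;
* ``UNMAPPED`` — no dictionary hit.

Conflicting preferred terms across authorities are settled by
:func:`didkit.lexicon.rank_resolve` (e.g. a ChemIDplus-like authority ranked
above a ChEBI-like one makes "acetaminophen" win over "paracetamol" for CAS
103-90-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from ._text import term_key
from .defaults import DEFAULT_QUASI_TOKENS, DEFAULT_SALT_TOKENS
from .errors import InputError
from .lexicon import Authority, ConceptDictionary, ConceptEntry, rank_resolve

__all__ = [
    "MatchType",
    "MATCH_PRECEDENCE",
    "Lexicons",
    "DrugMatch",
    "DrugNormalization",
    "classify_drug_match",
    "normalize_drug",
]


class MatchType(str, Enum):
    PT_EXACT = "PT_EXACT"
    SYNONYM = "SYNONYM"
    QUASI_SYNONYM = "QUASI_SYNONYM"
    BROADER = "BROADER"
    NARROWER = "NARROWER"
    UNMAPPED = "UNMAPPED"


# precedence when one raw name hits several entries within one authority:
# exactness wins.
MATCH_PRECEDENCE: dict[MatchType, int] = {
    MatchType.PT_EXACT: 0,
    MatchType.SYNONYM: 1,
    MatchType.QUASI_SYNONYM: 2,
    MatchType.NARROWER: 3,
    MatchType.BROADER: 4,
    MatchType.UNMAPPED: 5,
}


@dataclass(frozen=True)
class Lexicons:
    """Token sets driving salt/formulation and quasi-synonym classification."""

    salt_tokens: frozenset[str] = DEFAULT_SALT_TOKENS
    quasi_tokens: frozenset[str] = DEFAULT_QUASI_TOKENS


@dataclass(frozen=True)
class DrugMatch:
    """One authority's best hit for a raw name."""

    concept_id: Optional[str]
    matched_term: Optional[str]
    match_type: MatchType

    @classmethod
    def unmapped(cls) -> "DrugMatch":
        return cls(None, None, MatchType.UNMAPPED)


@dataclass(frozen=True)
class DrugNormalization:
    """Per-raw-name normalization outcome across all supplied authorities."""

    raw_name: str
    per_authority: tuple[tuple[str, DrugMatch], ...]  # (authority name, match)
    cas_number: Optional[str] = None
    cas_authority: Optional[str] = None
    cui: Optional[str] = None
    preferred_pt: Optional[str] = None

    @property
    def matches(self) -> dict[str, DrugMatch]:
        return dict(self.per_authority)

    @property
    def is_unmapped(self) -> bool:
        return all(m.match_type is MatchType.UNMAPPED for _, m in self.per_authority)


def classify_drug_match(
    raw_name: str,
    entry: Optional[ConceptEntry],
    matched_term: Optional[str],
    status: Optional[str],
    salt_lexicon: frozenset[str] | set[str] = DEFAULT_SALT_TOKENS,
    quasi_lexicon: frozenset[str] | set[str] = DEFAULT_QUASI_TOKENS,
) -> MatchType:
    """Classify the quality of a (raw name, dictionary term) match.

    With no entry/term supplied the name is UNMAPPED. Otherwise key equality
    yields PT_EXACT (P status) or SYNONYM (S status); trailing salt-lexicon
    tokens on the raw side yield NARROWER and on the standard side BROADER
    (directionality raw-to-standard); a difference of quasi-lexicon tokens
    only yields QUASI_SYNONYM.
    """
    if not raw_name or not raw_name.strip():
        raise InputError("raw drug name must be nonempty")
    if entry is None or matched_term is None:
        return MatchType.UNMAPPED
    raw_toks = term_key(raw_name).split()
    std_toks = term_key(matched_term).split()
    if raw_toks == std_toks:
        return MatchType.PT_EXACT if status == "P" else MatchType.SYNONYM
    if (
        len(raw_toks) > len(std_toks)
        and raw_toks[: len(std_toks)] == std_toks
        and all(t in salt_lexicon for t in raw_toks[len(std_toks):])
    ):
        return MatchType.NARROWER
    if (
        len(std_toks) > len(raw_toks)
        and std_toks[: len(raw_toks)] == raw_toks
        and all(t in salt_lexicon for t in std_toks[len(raw_toks):])
    ):
        return MatchType.BROADER
    raw_core = [t for t in raw_toks if t not in quasi_lexicon]
    std_core = [t for t in std_toks if t not in quasi_lexicon]
    if raw_core == std_core and (raw_core != raw_toks or std_core != std_toks):
        return MatchType.QUASI_SYNONYM
    return MatchType.UNMAPPED


def _query_variants(raw_name: str, lexicons: Lexicons) -> list[str]:
    """Query strings to try against a dictionary, most exact first."""
    variants = [raw_name]
    toks = term_key(raw_name).split()
    # progressive trailing-salt stripping (raw is a narrower salt form)
    stripped = list(toks)
    while len(stripped) > 1 and stripped[-1] in lexicons.salt_tokens:
        stripped = stripped[:-1]
        variants.append(" ".join(stripped))
    # salt appending (the dictionary term is the salt form)
    for tok in sorted(lexicons.salt_tokens):
        variants.append(" ".join(toks + [tok]))
    # quasi-token removal and appending
    core = [t for t in toks if t not in lexicons.quasi_tokens]
    if core and core != toks:
        variants.append(" ".join(core))
    for tok in sorted(lexicons.quasi_tokens):
        variants.append(" ".join(toks + [tok]))
    return variants


def _best_match(
    raw_name: str, dictionary: ConceptDictionary, lexicons: Lexicons
) -> tuple[DrugMatch, Optional[ConceptEntry]]:
    best: Optional[tuple[int, str, str, MatchType, ConceptEntry]] = None
    for query in _query_variants(raw_name, lexicons):
        for entry, matched_term, status in dictionary.lookup_key(query):
            mt = classify_drug_match(
                raw_name, entry, matched_term, status,
                lexicons.salt_tokens, lexicons.quasi_tokens,
            )
            if mt is MatchType.UNMAPPED:
                continue
            cand = (MATCH_PRECEDENCE[mt], entry.concept_id, matched_term, mt, entry)
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is None:
        return DrugMatch.unmapped(), None
    _prec, cid, term, mt, entry = best
    return DrugMatch(cid, term, mt), entry


def normalize_drug(
    raw_name: str,
    dicts: Sequence[ConceptDictionary],
    ranking: Sequence[Authority],
    lexicons: Optional[Lexicons] = None,
    cui_authority: Optional[str] = None,
) -> DrugNormalization:
    """Normalize one raw drug/chemical name against every dictionary.

    Records each authority's best match (PT_EXACT > SYNONYM > QUASI_SYNONYM >
    NARROWER > BROADER precedence within one authority, concept-id
    tie-break), takes the CAS number from the highest-ranked authority that
    provides one, the CUI from the dictionary named by *cui_authority*, and
    derives the preferred PT by authority ranking over the mapped candidates.
    """
    if not dicts:
        raise InputError("normalize_drug requires at least one dictionary")
    if not raw_name or not raw_name.strip():
        raise InputError("raw drug name must be nonempty")
    lexicons = lexicons or Lexicons()
    per_authority: list[tuple[str, DrugMatch]] = []
    entries: dict[str, Optional[ConceptEntry]] = {}
    for dictionary in dicts:
        match, entry = _best_match(raw_name, dictionary, lexicons)
        per_authority.append((dictionary.authority.name, match))
        entries[dictionary.authority.name] = entry
    rank_of = {a.name: a.rank for a in ranking}

    cas_number = cas_authority = None
    for name, match in sorted(
        per_authority, key=lambda nm: rank_of.get(nm[0], len(rank_of) + 1)
    ):
        entry = entries[name]
        if match.match_type is not MatchType.UNMAPPED and entry and entry.cas_number:
            cas_number, cas_authority = entry.cas_number, name
            break

    cui = None
    if cui_authority is not None:
        for name, match in per_authority:
            if name == cui_authority and match.match_type is not MatchType.UNMAPPED:
                cui = match.concept_id

    preferred_pt = None
    candidates = {
        name: (match.concept_id, entries[name].preferred_term)
        for name, match in per_authority
        if match.match_type is not MatchType.UNMAPPED and entries[name] is not None
    }
    if candidates:
        preferred_pt, _winner = rank_resolve(candidates, ranking)

    return DrugNormalization(
        raw_name=raw_name,
        per_authority=tuple(per_authority),
        cas_number=cas_number,
        cas_authority=cas_authority,
        cui=cui,
        preferred_pt=preferred_pt,
    )
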
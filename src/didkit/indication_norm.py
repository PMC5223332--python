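"""Indication target normalization with phenotypic semantic-type preference.

A raw indication target (e.g. "bacterial infections" or "antibacterial
agent") is mapped by exact key lookup to a concept entry, preferring
candidates carrying a *phenotypic* semantic type (diseases and other
biological conditions, processes, functions). Targets that land on a
non-phenotypic concept — typically therapeutic-class terms like
"Anti-Bacterial Agents" — are then remapped through a curated
:class:`~didkit.lexicon.RemapTable` to the corresponding phenotypic concept
("Bacterial Infections"), the initial mapping being preserved and the final
match demoted to quasi-synonym quality. Non-phenotypic concepts without a
remap entry stay "stuck" where they are.

Entry terms are rendered for display the way the flat table prints them:
preferred (P) terms in proper case, synonyms (S) in lower case.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from ._text import term_key
from .drug_norm import MatchType
from .errors import ConfigurationError, InputError
from .lexicon import ConceptDictionary, RemapTable, SemanticTypeScheme

__all__ = [
    "InitialMapping",
    "IndicationMapping",
    "PhenotypeRemapOutcome",
    "map_indication",
    "remap_phenotype",
    "render_entry_term",
    "compound_map",
]

logger = logging.getLogger(__name__)


class PhenotypeRemapOutcome(str, Enum):
    ALREADY_PHENOTYPIC = "ALREADY_PHENOTYPIC"
    REMAPPED = "REMAPPED"
    STUCK = "STUCK"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class InitialMapping:
    """Pre-remap (non-phenotypic) mapping preserved alongside the final one."""

    entry_term: str
    entry_status: str
    preferred_term: str
    cui: str
    semantic_types: tuple[str, ...]


@dataclass(frozen=True)
class IndicationMapping:
    """One target's mapping to a concept, possibly after phenotypic remap."""

    target: str
    entry_term: Optional[str]
    entry_status: Optional[str]
    preferred_term: Optional[str]
    cui: Optional[str]
    semantic_types: tuple[str, ...]
    phenotypic: bool
    match_quality: MatchType
    initial_mapping: Optional[InitialMapping] = None
    compound_index: Optional[int] = None

    @property
    def is_unmapped(self) -> bool:
        return self.cui is None

    @classmethod
    def unmapped(cls, target: str) -> "IndicationMapping":
        return cls(
            target=target,
            entry_term=None,
            entry_status=None,
            preferred_term=None,
            cui=None,
            semantic_types=(),
            phenotypic=False,
            match_quality=MatchType.UNMAPPED,
        )


def render_entry_term(term: str, status: str) -> str:
    """Render a dictionary term for display: P -> proper case, S -> lower case."""
    if status not in ("P", "S"):
        raise InputError(f"status must be P or S, got {status!r}")
    if status == "P":
        return " ".join(w.capitalize() for w in term.split())
    return term.lower()


def map_indication(
    target: str, dictionary: ConceptDictionary, scheme: SemanticTypeScheme
) -> IndicationMapping:
    """Initial mapping of a target to the best-matching concept entry.

    Among exact-key matches a candidate with a phenotypic semantic type is
    preferred; then P status beats S; then the smallest concept_id wins.
    Unmatched targets yield an UNMAPPED mapping.
    """
    if not target or not target.strip():
        raise InputError("indication target must be nonempty")
    candidates = dictionary.lookup_key(target)
    if not candidates:
        return IndicationMapping.unmapped(target)
    entry, matched_term, status = min(
        candidates,
        key=lambda c: (
            not scheme.any_phenotypic(c[0].semantic_types),
            c[2] != "P",
            c[0].concept_id,
        ),
    )
    return IndicationMapping(
        target=target,
        entry_term=render_entry_term(matched_term, status),
        entry_status=status,
        preferred_term=render_entry_term(entry.preferred_term, "P"),
        cui=entry.concept_id,
        semantic_types=entry.semantic_types,
        phenotypic=scheme.any_phenotypic(entry.semantic_types),
        match_quality=MatchType.PT_EXACT if status == "P" else MatchType.SYNONYM,
    )


def remap_phenotype(
    mapping: IndicationMapping,
    remap: RemapTable,
    dictionary: ConceptDictionary,
    scheme: SemanticTypeScheme,
) -> tuple[IndicationMapping, PhenotypeRemapOutcome]:
    """Remap a non-phenotypic mapping to its phenotypic concept, if curated.

    Phenotypic mappings pass through unchanged (ALREADY_PHENOTYPIC); a
    non-phenotypic mapping with a remap entry is replaced by the phenotypic
    concept with the initial mapping preserved and quality set to
    QUASI_SYNONYM (REMAPPED); one without an entry stays put (STUCK).
    Idempotent: applying twice equals applying once.
    """
    if mapping.is_unmapped:
        return mapping, PhenotypeRemapOutcome.UNMAPPED
    if mapping.phenotypic:
        return mapping, PhenotypeRemapOutcome.ALREADY_PHENOTYPIC
    target_cui = remap.get(mapping.cui)
    if target_cui is None:
        return mapping, PhenotypeRemapOutcome.STUCK
    entry = dictionary.get(target_cui)
    if entry is None:
        raise ConfigurationError(
            f"remap target {target_cui!r} (from {mapping.cui!r}) absent from "
            f"dictionary {dictionary.authority.name!r}"
        )
    if not scheme.any_phenotypic(entry.semantic_types):
        raise ConfigurationError(
            f"remap target {target_cui!r} is not phenotypic under the scheme"
        )
    initial = InitialMapping(
        entry_term=mapping.entry_term or "",
        entry_status=mapping.entry_status or "",
        preferred_term=mapping.preferred_term or "",
        cui=mapping.cui or "",
        semantic_types=mapping.semantic_types,
    )
    final = IndicationMapping(
        target=mapping.target,
        entry_term=render_entry_term(entry.preferred_term, "P"),
        entry_status="P",
        preferred_term=render_entry_term(entry.preferred_term, "P"),
        cui=entry.concept_id,
        semantic_types=entry.semantic_types,
        phenotypic=True,
        match_quality=MatchType.QUASI_SYNONYM,
        initial_mapping=initial,
        compound_index=mapping.compound_index,
    )
    return final, PhenotypeRemapOutcome.REMAPPED


def _match_spans(target: str, dictionary: ConceptDictionary) -> list[str]:
    """Greedy leftmost-longest dictionary-matchable spans within *target*."""
    max_words = dictionary.max_key_words
    tokens = list(re.finditer(r"\S+", target))
    spans: list[str] = []
    i = 0
    while i < len(tokens):
        matched_end = None
        for j in range(min(i + max_words, len(tokens)), i, -1):
            phrase = target[tokens[i].start(): tokens[j - 1].end()]
            if dictionary.lookup_key(phrase):
                matched_end = j
                break
        if matched_end is None:
            i += 1
            continue
        spans.append(target[tokens[i].start(): tokens[matched_end - 1].end()])
        i = matched_end
    return spans


def compound_map(
    target: str,
    dictionary: ConceptDictionary,
    scheme: SemanticTypeScheme,
    remap: RemapTable,
) -> list[IndicationMapping]:
    """Map a target, partitioning it into components when no single concept covers it.

    A whole-key match yields a singleton (after phenotypic remap) with no
    compound index. Otherwise the target is partitioned into maximal
    dictionary-matchable spans (leftmost-longest), each mapped and remapped
    and indexed 1..k; uncovered residue is dropped (logged at debug level).
    A target with no matchable span yields a singleton UNMAPPED mapping.
    """
    whole = map_indication(target, dictionary, scheme)
    if not whole.is_unmapped:
        final, _outcome = remap_phenotype(whole, remap, dictionary, scheme)
        return [final]
    spans = _match_spans(target, dictionary)
    if not spans:
        return [IndicationMapping.unmapped(target)]
    covered = sum(len(s) for s in spans)
    if covered < len(term_key(target)):
        logger.debug("compound_map: residue dropped for target %r", target)
    results: list[IndicationMapping] = []
    for idx, span in enumerate(spans, start=1):
        part = map_indication(span, dictionary, scheme)
        part, _outcome = remap_phenotype(part, remap, dictionary, scheme)
        part = replace(
            part,
            target=target,
            compound_index=idx if len(spans) > 1 else None,
        )
        results.append(part)
    return results
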
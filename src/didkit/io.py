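"""TSV readers/writers for raw source exports and per-stage artifacts.

All files are UTF-8 TSV with a header row; cells containing tabs/newlines
are escaped with the same scheme as the DID table dialect, so every
write/read pair is an identity.

Source export formats (one file per source):

* PAIR:      ``source_id, drug, relation, indication_term``
* HIERARCHY: ``source_id, drug, level_code, level_term`` (one row per level,
  rows of one drug contiguous, ordered root -> leaf)
* FREETEXT:  ``source_id, generic_name, trade_name, dosage, supplier,
  indications_text``
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Sequence

from ._text import escape_cell, unescape_cell
from .drug_norm import DrugMatch, DrugNormalization, MatchType
from .errors import FormatError, InputError
from .indication_norm import IndicationMapping, InitialMapping, PhenotypeRemapOutcome
from .ingest import ParsedPair, RawSourceRecord, SourceStyle
from .subtypes import Polarity, SubtypeAnnotation

__all__ = [
    "read_source_file",
    "write_source_file",
    "read_pairs",
    "write_pairs",
    "read_drug_norms",
    "write_drug_norms",
    "read_indication_maps",
    "write_indication_maps",
    "read_subtype_maps",
    "write_subtype_maps",
]

PAIR_HEADER = ["source_id", "drug", "relation", "indication_term"]
HIERARCHY_HEADER = ["source_id", "drug", "level_code", "level_term"]
FREETEXT_HEADER = [
    "source_id", "generic_name", "trade_name", "dosage", "supplier",
    "indications_text",
]
PAIRS_HEADER = [
    "source_id", "raw_drug_name", "entire_value", "target", "target_equals_entire",
]
DRUGNORM_HEADER = [
    "raw_name", "cas_number", "cas_authority", "match_type", "preferred_pt",
    "cui", "per_authority",
]
INDNORM_HEADER = [
    "target", "match_quality", "entry_term", "entry_status", "preferred_term",
    "cui", "semantic_types", "phenotypic", "outcome", "compound_index",
    "init_entry_term", "init_entry_status", "init_preferred_term", "init_cui",
    "init_semantic_types",
]
SUBTYPES_HEADER = ["entire_value", "leaf", "root", "polarity"]


def _write_table(path: Path, header: Sequence[str], rows) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(escape_cell(c) for c in row) + "\n")


def _read_table(path: Path, header: Sequence[str]) -> list[list[str]]:
    if not path.exists():
        raise InputError(f"file not found: {path}")
    with path.open(encoding="utf-8", newline="") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines or lines[0].split("\t") != list(header):
        raise FormatError(f"{path}: bad header, expected {list(header)!r}")
    return [
        [unescape_cell(c) for c in line.split("\t")] for line in lines[1:] if line
    ]


# --------------------------------------------------------------------------
# raw source files


def write_source_file(
    records: Sequence[RawSourceRecord], style: SourceStyle, path: str | Path
) -> None:
    path = Path(path)
    if style is SourceStyle.PAIR:
        rows = [
            [r.source_id, r.drug_field, r.relation or "", r.term or ""]
            for r in records
        ]
        _write_table(path, PAIR_HEADER, rows)
    elif style is SourceStyle.HIERARCHY:
        rows = [
            [r.source_id, r.drug_field, code, term]
            for r in records
            for code, term in (r.levels or ())
        ]
        _write_table(path, HIERARCHY_HEADER, rows)
    else:
        rows = [
            [r.source_id, r.drug_field, r.trade_name, r.dosage, r.supplier,
             r.text or ""]
            for r in records
        ]
        _write_table(path, FREETEXT_HEADER, rows)


def read_source_file(path: str | Path, style: SourceStyle) -> list[RawSourceRecord]:
    path = Path(path)
    if style is SourceStyle.PAIR:
        return [
            RawSourceRecord(row[0], style, row[1], relation=row[2], term=row[3])
            for row in _read_table(path, PAIR_HEADER)
        ]
    if style is SourceStyle.HIERARCHY:
        records: list[RawSourceRecord] = []
        current: Optional[tuple[str, str]] = None
        levels: list[tuple[str, str]] = []
        for row in _read_table(path, HIERARCHY_HEADER):
            key = (row[0], row[1])
            if current is not None and key != current:
                records.append(
                    RawSourceRecord(current[0], style, current[1],
                                    levels=tuple(levels))
                )
                levels = []
            current = key
            levels.append((row[2], row[3]))
        if current is not None:
            records.append(
                RawSourceRecord(current[0], style, current[1], levels=tuple(levels))
            )
        return records
    return [
        RawSourceRecord(
            row[0], style, row[1], trade_name=row[2], dosage=row[3],
            supplier=row[4], text=row[5],
        )
        for row in _read_table(path, FREETEXT_HEADER)
    ]


# --------------------------------------------------------------------------
# parsed pairs


def write_pairs(pairs: Sequence[ParsedPair], path: str | Path) -> None:
    rows = [
        [p.source_id, p.raw_drug_name, p.entire_value, p.target,
         "Y" if p.target_equals_entire else "N"]
        for p in pairs
    ]
    _write_table(Path(path), PAIRS_HEADER, rows)


def read_pairs(path: str | Path) -> list[ParsedPair]:
    return [
        ParsedPair(row[0], row[1], row[2], row[3], row[4] == "Y")
        for row in _read_table(Path(path), PAIRS_HEADER)
    ]


# --------------------------------------------------------------------------
# drug normalizations


def write_drug_norms(
    norms: dict[str, DrugNormalization], path: str | Path
) -> None:
    rows = []
    for name in sorted(norms):
        n = norms[name]
        cas_match = ""
        if n.cas_authority is not None:
            cas_match = n.matches[n.cas_authority].match_type.value
        per_auth = json.dumps(
            {
                auth: [m.concept_id, m.matched_term, m.match_type.value]
                for auth, m in n.per_authority
            },
            sort_keys=True,
            separators=(",", ":"),
        )
        rows.append(
            [n.raw_name, n.cas_number or "", n.cas_authority or "", cas_match,
             n.preferred_pt or "", n.cui or "", per_auth]
        )
    _write_table(Path(path), DRUGNORM_HEADER, rows)


def read_drug_norms(path: str | Path) -> dict[str, DrugNormalization]:
    out: dict[str, DrugNormalization] = {}
    for row in _read_table(Path(path), DRUGNORM_HEADER):
        per_auth = tuple(
            (auth, DrugMatch(cid, term, MatchType(mt)))
            for auth, (cid, term, mt) in sorted(json.loads(row[6]).items())
        )
        out[row[0]] = DrugNormalization(
            raw_name=row[0],
            per_authority=per_auth,
            cas_number=row[1] or None,
            cas_authority=row[2] or None,
            cui=row[5] or None,
            preferred_pt=row[4] or None,
        )
    return out


# --------------------------------------------------------------------------
# indication mappings


def remap_outcome(mapping: IndicationMapping) -> PhenotypeRemapOutcome:
    """Reconstruct the remap outcome a final mapping went through."""
    if mapping.is_unmapped:
        return PhenotypeRemapOutcome.UNMAPPED
    if mapping.initial_mapping is not None:
        return PhenotypeRemapOutcome.REMAPPED
    if mapping.phenotypic:
        return PhenotypeRemapOutcome.ALREADY_PHENOTYPIC
    return PhenotypeRemapOutcome.STUCK


def write_indication_maps(
    maps: dict[str, Sequence[IndicationMapping]], path: str | Path
) -> None:
    rows = []
    for target in sorted(maps):
        for m in maps[target]:
            init = m.initial_mapping
            rows.append(
                [
                    m.target,
                    m.match_quality.value,
                    m.entry_term or "",
                    m.entry_status or "",
                    m.preferred_term or "",
                    m.cui or "",
                    ";".join(m.semantic_types),
                    "Y" if m.phenotypic else "N",
                    remap_outcome(m).value,
                    "" if m.compound_index is None else str(m.compound_index),
                    init.entry_term if init else "",
                    init.entry_status if init else "",
                    init.preferred_term if init else "",
                    init.cui if init else "",
                    ";".join(init.semantic_types) if init else "",
                ]
            )
    _write_table(Path(path), INDNORM_HEADER, rows)


def read_indication_maps(path: str | Path) -> dict[str, list[IndicationMapping]]:
    out: dict[str, list[IndicationMapping]] = {}
    for row in _read_table(Path(path), INDNORM_HEADER):
        init = None
        if row[13]:
            init = InitialMapping(
                entry_term=row[10],
                entry_status=row[11],
                preferred_term=row[12],
                cui=row[13],
                semantic_types=tuple(t for t in row[14].split(";") if t),
            )
        out.setdefault(row[0], []).append(
            IndicationMapping(
                target=row[0],
                match_quality=MatchType(row[1]),
                entry_term=row[2] or None,
                entry_status=row[3] or None,
                preferred_term=row[4] or None,
                cui=row[5] or None,
                semantic_types=tuple(t for t in row[6].split(";") if t),
                phenotypic=row[7] == "Y",
                compound_index=int(row[9]) if row[9] else None,
                initial_mapping=init,
            )
        )
    return out


# --------------------------------------------------------------------------
# subtype annotations


def write_subtype_maps(
    maps: dict[str, Sequence[SubtypeAnnotation]], path: str | Path
) -> None:
    rows = [
        [value, a.leaf, a.root, a.polarity.value]
        for value in sorted(maps)
        for a in maps[value]
    ]
    _write_table(Path(path), SUBTYPES_HEADER, rows)


def read_subtype_maps(path: str | Path) -> dict[str, list[SubtypeAnnotation]]:
    out: dict[str, list[SubtypeAnnotation]] = {}
    for row in _read_table(Path(path), SUBTYPES_HEADER):
        out.setdefault(row[0], []).append(
            SubtypeAnnotation(row[1], row[2], Polarity(row[3]))
        )
    return out
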
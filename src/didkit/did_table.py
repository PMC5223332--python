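"""Assembly and (de)serialization of the flat drug-indication table.

Each :class:`DIDRow` joins one parsed (source, raw drug, indication target)
record with its drug normalization, final indication mapping and subtype
annotations. Rows are unique on the quadruplet (source, raw drug name,
target, indication concept ID); duplicates collapse keeping the
highest-quality indication match.

The on-disk dialect is a UTF-8 TSV whose header names every field together
with the column letter it occupies in the published spreadsheet layout, e.g.
``target(AR)``. Cells are escaped so embedded tabs/newlines survive a
write/read roundtrip byte-exactly. A ``legacy`` read mode tolerates files
missing the optional initial-mapping block (columns BD-BL) and ignores
unknown extra columns, which is how a spreadsheet-exported supplement subset
is loaded.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._text import escape_cell, unescape_cell
from .drug_norm import MATCH_PRECEDENCE, DrugMatch, DrugNormalization, MatchType
from .errors import ConsistencyError, FormatError, InputError, ValidationError
from .indication_norm import IndicationMapping, InitialMapping
from .ingest import ParsedPair
from .subtypes import Polarity, SubtypeAnnotation

__all__ = ["DIDRow", "assemble", "write_did", "read_did", "DID_COLUMNS"]

# (field name, spreadsheet column letter(s)) in output order
DID_COLUMNS: tuple[tuple[str, str], ...] = (
    ("source_id", "B"),
    ("raw_drug_name", "D"),
    ("cas_number", "E"),
    ("cas_authority", "F"),
    ("preferred_pt", "G"),
    ("drug_matches", "I-AC"),
    ("drug_cui", "AD-AM"),
    ("subtype_leaf", "AN"),
    ("subtype_root", "AO"),
    ("subtype_polarity", "AP"),
    ("entire_value", "AQ"),
    ("target", "AR"),
    ("target_equals_entire", "AS"),
    ("ind_match_quality", "AT"),
    ("ind_entry_term", "AU"),
    ("ind_preferred_term", "AV"),
    ("ind_cui", "AW"),
    ("ind_entry_status", "AX"),
    ("ind_semantic_types", "AY"),
    ("ind_phenotypic", "AZ"),
    ("compound_index", "BA"),
    ("init_entry_term", "BD"),
    ("init_entry_status", "BE"),
    ("init_preferred_term", "BF"),
    ("init_cui", "BG"),
    ("init_semantic_types", "BH"),
)

_OPTIONAL_COLUMNS = {
    "init_entry_term",
    "init_entry_status",
    "init_preferred_term",
    "init_cui",
    "init_semantic_types",
    "compound_index",
}

HEADER = [f"{name}({letters})" for name, letters in DID_COLUMNS]


@dataclass(frozen=True)
class DIDRow:
    """One flattened drug-indication record."""

    source_id: str
    raw_drug_name: str
    entire_value: str
    target: str
    target_equals_entire: bool
    ind_match_quality: MatchType = MatchType.UNMAPPED
    cas_number: Optional[str] = None
    cas_authority: Optional[str] = None
    preferred_pt: Optional[str] = None
    drug_matches: tuple[tuple[str, DrugMatch], ...] = ()
    drug_cui: Optional[str] = None
    subtype_leaves: tuple[str, ...] = ()
    subtype_roots: tuple[str, ...] = ()
    subtype_polarities: tuple[Polarity, ...] = ()
    ind_entry_term: Optional[str] = None
    ind_preferred_term: Optional[str] = None
    ind_cui: Optional[str] = None
    ind_entry_status: Optional[str] = None
    ind_semantic_types: tuple[str, ...] = ()
    ind_phenotypic: bool = False
    compound_index: Optional[int] = None
    init_entry_term: Optional[str] = None
    init_entry_status: Optional[str] = None
    init_preferred_term: Optional[str] = None
    init_cui: Optional[str] = None
    init_semantic_types: tuple[str, ...] = ()

    @property
    def quadruplet(self) -> tuple[str, str, str, str]:
        """The uniqueness key: (source, raw drug name, target, indication CUI)."""
        return (self.source_id, self.raw_drug_name, self.target, self.ind_cui or "")


def assemble(
    pairs: Iterable[ParsedPair],
    drug_norms: Mapping[str, DrugNormalization],
    indication_maps: Mapping[str, Sequence[IndicationMapping]],
    subtype_annotations: Optional[Mapping[str, Sequence[SubtypeAnnotation]]] = None,
) -> list[DIDRow]:
    """Join per-stage outputs into the deduplicated flat table.

    *drug_norms* is keyed by raw drug name, *indication_maps* by target
    string (>= 1 mapping each, possibly UNMAPPED), *subtype_annotations* by
    entire value. One row is produced per (pair x indication mapping
    component); duplicate quadruplets collapse keeping the highest-quality
    indication match; rows come back sorted by (source, raw drug, target).
    """
    best: dict[tuple[str, str, str, str], DIDRow] = {}
    for pair in pairs:
        norm = drug_norms.get(pair.raw_drug_name)
        if norm is None:
            raise ConsistencyError(
                f"no drug normalization for raw name {pair.raw_drug_name!r}"
            )
        mappings = indication_maps.get(pair.target)
        if not mappings:
            raise ConsistencyError(
                f"no indication mapping for target {pair.target!r}"
            )
        annotations: Sequence[SubtypeAnnotation] = ()
        if subtype_annotations is not None:
            annotations = subtype_annotations.get(pair.entire_value, ())
        for m in mappings:
            row = DIDRow(
                source_id=pair.source_id,
                raw_drug_name=pair.raw_drug_name,
                entire_value=pair.entire_value,
                target=pair.target,
                target_equals_entire=pair.target_equals_entire,
                cas_number=norm.cas_number,
                cas_authority=norm.cas_authority,
                preferred_pt=norm.preferred_pt,
                drug_matches=norm.per_authority,
                drug_cui=norm.cui,
                subtype_leaves=tuple(a.leaf for a in annotations),
                subtype_roots=tuple(a.root for a in annotations),
                subtype_polarities=tuple(a.polarity for a in annotations),
                ind_match_quality=m.match_quality,
                ind_entry_term=m.entry_term,
                ind_preferred_term=m.preferred_term,
                ind_cui=m.cui,
                ind_entry_status=m.entry_status,
                ind_semantic_types=m.semantic_types,
                ind_phenotypic=m.phenotypic,
                compound_index=m.compound_index,
                init_entry_term=m.initial_mapping.entry_term if m.initial_mapping else None,
                init_entry_status=m.initial_mapping.entry_status if m.initial_mapping else None,
                init_preferred_term=m.initial_mapping.preferred_term if m.initial_mapping else None,
                init_cui=m.initial_mapping.cui if m.initial_mapping else None,
                init_semantic_types=m.initial_mapping.semantic_types if m.initial_mapping else (),
            )
            key = row.quadruplet
            incumbent = best.get(key)
            if incumbent is None or (
                MATCH_PRECEDENCE[row.ind_match_quality]
                < MATCH_PRECEDENCE[incumbent.ind_match_quality]
            ):
                best[key] = row
    return sorted(best.values(), key=lambda r: r.quadruplet)


def _join_checked(values: Iterable[str], what: str) -> str:
    vals = list(values)
    for v in vals:
        if ";" in v:
            raise ValidationError(f"{what} value {v!r} must not contain ';'")
    return ";".join(vals)


def _opt(value: Optional[str]) -> str:
    return value if value is not None else ""


def _row_cells(row: DIDRow) -> list[str]:
    matches_json = json.dumps(
        {
            name: [m.concept_id, m.matched_term, m.match_type.value]
            for name, m in row.drug_matches
        },
        sort_keys=True,
        separators=(",", ":"),
    )
    return [
        row.source_id,
        row.raw_drug_name,
        _opt(row.cas_number),
        _opt(row.cas_authority),
        _opt(row.preferred_pt),
        matches_json,
        _opt(row.drug_cui),
        _join_checked(row.subtype_leaves, "subtype leaf"),
        _join_checked(row.subtype_roots, "subtype root"),
        ";".join(p.value for p in row.subtype_polarities),
        row.entire_value,
        row.target,
        "Y" if row.target_equals_entire else "N",
        row.ind_match_quality.value,
        _opt(row.ind_entry_term),
        _opt(row.ind_preferred_term),
        _opt(row.ind_cui),
        _opt(row.ind_entry_status),
        _join_checked(row.ind_semantic_types, "semantic type"),
        "Y" if row.ind_phenotypic else "N",
        "" if row.compound_index is None else str(row.compound_index),
        _opt(row.init_entry_term),
        _opt(row.init_entry_status),
        _opt(row.init_preferred_term),
        _opt(row.init_cui),
        _join_checked(row.init_semantic_types, "semantic type"),
    ]


def write_did(rows: Iterable[DIDRow], path: str | Path) -> None:
    """Write rows to the DID TSV dialect; byte-deterministic for a given list.

    Embedded tabs/newlines/backslashes in free-text fields are escaped.
    Subtype labels and semantic-type codes must not contain ';' (it is the
    intra-cell list separator).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(HEADER) + "\n")
        for row in rows:
            fh.write("\t".join(escape_cell(c) for c in _row_cells(row)) + "\n")


def _none_if_empty(value: str) -> Optional[str]:
    return value if value else None


def _split_tuple(value: str) -> tuple[str, ...]:
    return tuple(v for v in value.split(";") if v) if value else ()


def _parse_row(cells: Mapping[str, str], path: Path, lineno: int) -> DIDRow:
    try:
        matches_raw = cells.get("drug_matches", "")
        matches: tuple[tuple[str, DrugMatch], ...] = ()
        if matches_raw:
            decoded = json.loads(matches_raw)
            matches = tuple(
                (name, DrugMatch(cid, term, MatchType(mt)))
                for name, (cid, term, mt) in sorted(decoded.items())
            )
        compound = cells.get("compound_index", "")
        return DIDRow(
            source_id=cells["source_id"],
            raw_drug_name=cells["raw_drug_name"],
            entire_value=cells["entire_value"],
            target=cells["target"],
            target_equals_entire=cells["target_equals_entire"] == "Y",
            cas_number=_none_if_empty(cells.get("cas_number", "")),
            cas_authority=_none_if_empty(cells.get("cas_authority", "")),
            preferred_pt=_none_if_empty(cells.get("preferred_pt", "")),
            drug_matches=matches,
            drug_cui=_none_if_empty(cells.get("drug_cui", "")),
            subtype_leaves=_split_tuple(cells.get("subtype_leaf", "")),
            subtype_roots=_split_tuple(cells.get("subtype_root", "")),
            subtype_polarities=tuple(
                Polarity(p) for p in _split_tuple(cells.get("subtype_polarity", ""))
            ),
            ind_match_quality=MatchType(cells.get("ind_match_quality", "UNMAPPED")),
            ind_entry_term=_none_if_empty(cells.get("ind_entry_term", "")),
            ind_preferred_term=_none_if_empty(cells.get("ind_preferred_term", "")),
            ind_cui=_none_if_empty(cells.get("ind_cui", "")),
            ind_entry_status=_none_if_empty(cells.get("ind_entry_status", "")),
            ind_semantic_types=_split_tuple(cells.get("ind_semantic_types", "")),
            ind_phenotypic=cells.get("ind_phenotypic", "N") == "Y",
            compound_index=int(compound) if compound else None,
            init_entry_term=_none_if_empty(cells.get("init_entry_term", "")),
            init_entry_status=_none_if_empty(cells.get("init_entry_status", "")),
            init_preferred_term=_none_if_empty(cells.get("init_preferred_term", "")),
            init_cui=_none_if_empty(cells.get("init_cui", "")),
            init_semantic_types=_split_tuple(cells.get("init_semantic_types", "")),
        )
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ValidationError(f"{path}:{lineno}: bad row ({exc})") from exc


def read_did(path: str | Path, legacy: bool = False) -> list[DIDRow]:
    """Read a DID TSV back into rows.

    In strict mode the header must match :data:`HEADER` exactly. In *legacy*
    mode the header is matched by field name: the optional initial-mapping
    block and compound index may be missing (rows then carry empty initial
    mappings) and unknown columns are ignored. Duplicate quadruplets are
    rejected with the offending key and line number.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"DID file not found: {path}")
    with path.open(encoding="utf-8", newline="") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header_cells = lines[0].split("\t")
    if legacy:
        names = [h.split("(")[0].strip() for h in header_cells]
        known = {name for name, _ in DID_COLUMNS}
        required = known - _OPTIONAL_COLUMNS
        missing = required - set(names)
        if missing:
            raise FormatError(f"{path}: missing required columns {sorted(missing)}")
        positions = {name: i for i, name in enumerate(names) if name in known}
    else:
        if header_cells != HEADER:
            raise FormatError(
                f"{path}: header mismatch (expected the didkit DID dialect; "
                f"use legacy=True for exported spreadsheet subsets)"
            )
        positions = {name: i for i, (name, _) in enumerate(DID_COLUMNS)}
    rows: list[DIDRow] = []
    seen: dict[tuple[str, str, str, str], int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        raw_cells = line.split("\t")
        cells = {
            name: unescape_cell(raw_cells[i])
            for name, i in positions.items()
            if i < len(raw_cells)
        }
        row = _parse_row(cells, path, lineno)
        key = row.quadruplet
        if key in seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate quadruplet {key!r} "
                f"(first seen at line {seen[key]})"
            )
        seen[key] = lineno
        rows.append(row)
    return rows
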
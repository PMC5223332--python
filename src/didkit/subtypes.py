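"""Indication-subtype tagging from lexical cues, with a three-level rollup.

Raw indication values often carry their subtype lexically: "treatment of
hypertension", the prefix in "Antidiabetic", the suffix in "Anxiolytic", or a
head noun as in "beta-adrenergic agonist". Cues tag a *leaf* form which rolls
up to a lexical *root* ("treating" -> "treat") and from there to a *polarity*:
NEGATIVE for inhibitory/therapeutic relations, POSITIVE for causative ones
("Carcinogens"), UNKNOWN where the direction is undecidable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .defaults import DEFAULT_CUE_ROWS, DEFAULT_ROLLUP_ROWS
from .errors import InputError

__all__ = [
    "CueKind",
    "Polarity",
    "SubtypeCue",
    "SubtypeAnnotation",
    "default_cues",
    "default_rollup_table",
    "load_cues",
    "load_rollup_table",
    "tag_subtypes",
    "rollup",
]

# a PREFIX cue must leave at least this many characters after the prefix, so
# "anti" does not fire on "ant..." words
MIN_PREFIX_REMAINDER = 3


class CueKind(str, Enum):
    PREFIX = "PREFIX"
    SUFFIX = "SUFFIX"
    HEAD_NOUN = "HEAD_NOUN"
    KEYWORD = "KEYWORD"


class Polarity(str, Enum):
    NEGATIVE = "NEGATIVE"
    POSITIVE = "POSITIVE"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class SubtypeCue:
    kind: CueKind
    surface: str
    leaf: str

    def __post_init__(self) -> None:
        if not self.surface:
            raise InputError("cue surface must be nonempty")


@dataclass(frozen=True)
class SubtypeAnnotation:
    leaf: str
    root: str
    polarity: Polarity

    @classmethod
    def unknown(cls) -> "SubtypeAnnotation":
        """The annotation emitted when no cue fires at all."""
        return cls(leaf="unknown", root="unknown", polarity=Polarity.UNKNOWN)


def default_cues() -> tuple[SubtypeCue, ...]:
    return tuple(
        SubtypeCue(CueKind(kind), surface, leaf)
        for kind, surface, leaf in DEFAULT_CUE_ROWS
    )


def default_rollup_table() -> dict[str, tuple[str, Polarity]]:
    return {
        leaf: (root, Polarity(pol)) for leaf, root, pol in DEFAULT_ROLLUP_ROWS
    }


def load_cues(path) -> tuple[SubtypeCue, ...]:
    """Load a cue TSV: kind, surface, leaf (header required)."""
    import csv
    from pathlib import Path

    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["kind", "surface", "leaf"]:
            raise InputError(f"{path}: bad cue header")
        return tuple(
            SubtypeCue(CueKind(row[0].strip()), row[1], row[2])
            for row in reader
            if row and row[0].strip()
        )


def load_rollup_table(path) -> dict[str, tuple[str, "Polarity"]]:
    """Load a rollup TSV: leaf, root, polarity (header required)."""
    import csv
    from pathlib import Path

    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["leaf", "root", "polarity"]:
            raise InputError(f"{path}: bad rollup header")
        return {
            row[0]: (row[1], Polarity(row[2].strip()))
            for row in reader
            if row and row[0].strip()
        }


def rollup(
    leaf: str, table: Optional[Mapping[str, tuple[str, Polarity]]] = None
) -> tuple[str, Polarity]:
    """Roll a leaf form up to (lexical root, polarity); unknown leaves pass through."""
    if table is None:
        table = default_rollup_table()
    return table.get(leaf, (leaf, Polarity.UNKNOWN))


def _tokens(text: str) -> list[str]:
    return re.findall(r"[a-z0-9]+", text.casefold())


def _cue_fires(cue: SubtypeCue, tokens: Sequence[str]) -> bool:
    surface = cue.surface.casefold()
    if cue.kind is CueKind.PREFIX:
        return any(
            t.startswith(surface) and len(t) - len(surface) >= MIN_PREFIX_REMAINDER
            for t in tokens
        )
    if cue.kind is CueKind.SUFFIX:
        return any(t.endswith(surface) and len(t) > len(surface) for t in tokens)
    # HEAD_NOUN and KEYWORD: contiguous token/phrase match
    words = _tokens(surface)
    if not words:
        return False
    n = len(words)
    return any(list(tokens[i: i + n]) == words for i in range(len(tokens) - n + 1))


def tag_subtypes(
    entire_value: str,
    cues: Optional[Iterable[SubtypeCue]] = None,
    rollup_table: Optional[Mapping[str, tuple[str, Polarity]]] = None,
) -> list[SubtypeAnnotation]:
    """Tag every subtype cue present in a raw indication value.

    Scanning is case-insensitive; each firing cue yields one annotation and
    duplicate leaves collapse. The returned list is never empty: with no cue
    present a single UNKNOWN annotation is produced.
    """
    cue_list = tuple(cues) if cues is not None else default_cues()
    if not cue_list:
        raise InputError("cue list must be nonempty")
    tokens = _tokens(entire_value)
    seen: set[str] = set()
    annotations: list[SubtypeAnnotation] = []
    for cue in cue_list:
        if cue.leaf in seen:
            continue
        if _cue_fires(cue, tokens):
            seen.add(cue.leaf)
            root, polarity = rollup(cue.leaf, rollup_table)
            annotations.append(SubtypeAnnotation(cue.leaf, root, polarity))
    if not annotations:
        return [SubtypeAnnotation.unknown()]
    return annotations
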
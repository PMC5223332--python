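"""Shared low-level text helpers: term keys and TSV cell escaping."""

from __future__ import annotations

_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}
_UNESCAPES = {"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}


def term_key(term: str) -> str:
    """Normalization key for terminology matching.

    Casefolds, collapses internal whitespace runs to single spaces and strips
    surrounding whitespace. Punctuation is preserved so chemical names that
    differ only by punctuation are not merged.
    """
    return " ".join(term.casefold().split())


def escape_cell(value: str) -> str:
    """Escape a string for one TSV cell (tabs, newlines, backslashes)."""
    out = []
    for ch in value:
        out.append(_ESCAPES.get(ch, ch))
    return "".join(out)


def unescape_cell(value: str) -> str:
    """Inverse of :func:`escape_cell`."""
    out = []
    i = 0
    n = len(value)
    while i < n:
        ch = value[i]
        if ch == "\\" and i + 1 < n and value[i + 1] in _UNESCAPES:
            out.append(_UNESCAPES[value[i + 1]])
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)
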
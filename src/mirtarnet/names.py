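"""Normalization of mature-miRNA names.

Printed miRNA lists mix species prefixes ("mmu-miR-223-3p"), bare names
("miR-223-3p") and lower-case variants.  Set operations in this package are
defined over normalized names: the species prefix is stripped and the
``miR``/``let`` stem is given its canonical casing, while everything after
the stem (numbering, arm suffixes such as ``-3p``/``-5p``, and oddities like
``miR-3102-5p.2-5p``) is preserved verbatim.
"""

from __future__ import annotations

import re

_STEM = re.compile(r"^(?:[a-z]{3,4}-)?(mir|let)(-\S*)$", re.IGNORECASE)

_CANONICAL = {"mir": "miR", "let": "let"}


def normalize_name(name: str) -> str:
    """Return the canonical form of a mature-miRNA name.

    >>> normalize_name("mmu-mir-223-3p")
    'miR-223-3p'
    >>> normalize_name("let-7a-5p")
    'let-7a-5p'
    """
    name = name.strip()
    m = _STEM.match(name)
    if m is None:
        return name
    return _CANONICAL[m.group(1).lower()] + m.group(2)


def normalize_all(names, *, on_collision: str = "error"):
    """Normalize a list of names, reporting collisions.

    Two distinct input names that normalize to the same string are never
    silently merged: with ``on_collision="error"`` a ``ValueError`` is
    raised; with ``"report"`` the collisions are returned alongside.
    """
    seen: dict[str, str] = {}
    collisions: list[tuple[str, str]] = []
    out = []
    for raw in names:
        norm = normalize_name(raw)
        if norm in seen and seen[norm] != raw:
            collisions.append((seen[norm], raw))
        seen.setdefault(norm, raw)
        out.append(norm)
    if collisions and on_collision == "error":
        raise ValueError(f"name normalization collisions: {collisions}")
    if on_collision == "report":
        return out, collisions
    return out
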
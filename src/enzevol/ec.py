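"""Enzyme Commission (E.C.) numbers and level-wise comparison.

The E.C. classification is a four-level hierarchical descriptor
``class.subclass.sub-subclass.serial``.  The first level (1-6) names the
overall chemistry (oxidoreductase, transferase, hydrolase, lyase,
isomerase, ligase); the second and third refine the bond type or group
transferred; the fourth is a serial number distinguishing substrate
specificity.  The identifiers carry no metric: 1.1.1.1 is no more similar
to 1.1.1.2 than to 1.1.1.25.  The only comparison this package ever makes
between two E.C. numbers is therefore *the first level at which they
differ*, which is the atomic operation behind every exchange count
downstream.

Partially specified annotations use ``-`` as a wildcard; a wildcard at
level *k* implies wildcards at all deeper levels.  Wildcard levels are
excluded from comparison: a partial annotation cannot witness a change.
Preliminary serials (``n1``-style) are ordinary distinct tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

#: default number of top-level classes (the six-class E.C. era).
N_CLASSES = 6

Level = Union[int, str, None]

_N_SERIAL = re.compile(r"^n\d+$")


class ECParseError(ValueError):
    """Raised when a string cannot be interpreted as an E.C. number."""


def _level_sort_key(v: Level) -> tuple:
    """Deterministic ordering of level tokens: integers first (numeric),
    then preliminary ``n``-serials (numeric on the digits), wildcards last."""
    if v is None:
        return (2, 0, "")
    if isinstance(v, int):
        return (0, v, "")
    return (1, int(v[1:]), v)


@dataclass(frozen=True)
class ECNumber:
    """A four-level E.C. identifier with wildcard support.

    ``levels`` is a 4-tuple; entries are positive ``int``, a preliminary
    serial string like ``"n1"``, or ``None`` for a wildcard.  Instances are
    immutable, hashable and totally ordered (deterministic tie-breaking
    order used throughout the package, not a similarity measure).
    """

    levels: tuple[Level, Level, Level, Level]

    def __post_init__(self) -> None:
        if len(self.levels) != 4:
            raise ECParseError(f"an E.C. number has 4 levels, got {len(self.levels)}")
        l1 = self.levels[0]
        if not isinstance(l1, int) or not 1 <= l1 <= N_CLASSES:
            raise ECParseError(
                f"E.C. class must be an integer in 1..{N_CLASSES}, got {l1!r}"
            )
        seen_wildcard = False
        for k, v in enumerate(self.levels):
            if v is None:
                seen_wildcard = True
            else:
                if seen_wildcard:
                    raise ECParseError(
                        f"specified level {k + 1} after a wildcard in {self.levels!r}"
                    )
                ok = (isinstance(v, int) and v > 0) or (
                    isinstance(v, str) and _N_SERIAL.match(v)
                )
                if not ok:
                    raise ECParseError(f"invalid E.C. level token {v!r}")

    # -- accessors ---------------------------------------------------------

    @property
    def ec_class(self) -> int:
        """Top-level class code (1-6)."""
        return self.levels[0]  # type: ignore[return-value]

    @property
    def is_fully_specified(self) -> bool:
        """True if no level is a wildcard."""
        return all(v is not None for v in self.levels)

    # -- rendering / ordering ---------------------------------------------

    def __str__(self) -> str:
        return ".".join("-" if v is None else str(v) for v in self.levels)

    def __repr__(self) -> str:  # compact; shows up in test diffs a lot
        return f"EC({self})"

    def sort_key(self) -> tuple:
        return tuple(_level_sort_key(v) for v in self.levels)

    def __lt__(self, other: "ECNumber") -> bool:
        return self.sort_key() < other.sort_key()


def parse_ec(text: str, n_classes: int = N_CLASSES) -> ECNumber:
    """Parse ``"a.b.c.d"`` (with ``-`` wildcards) into an :class:`ECNumber`.

    Raises :class:`ECParseError` naming the offending token for wrong
    arity, non-numeric non-wildcard tokens, a class outside ``1..n_classes``
    or a specified level following a wildcard.
    """
    if not text or not text.strip():
        raise ECParseError("empty E.C. string")
    tokens = text.strip().split(".")
    if len(tokens) != 4:
        raise ECParseError(f"expected 4 dot-separated levels, got {len(tokens)} in {text!r}")
    levels: list[Level] = []
    for k, tok in enumerate(tokens):
        tok = tok.strip()
        if tok == "-":
            levels.append(None)
        elif tok.isdigit():
            levels.append(int(tok))
        elif _N_SERIAL.match(tok):
            levels.append(tok)
        else:
            raise ECParseError(f"invalid token {tok!r} at level {k + 1} of {text!r}")
    l1 = levels[0]
    if not isinstance(l1, int) or not 1 <= l1 <= n_classes:
        raise ECParseError(f"class token {tokens[0]!r} outside 1..{n_classes}")
    return ECNumber(tuple(levels))  # type: ignore[arg-type]


def compare_level(a: ECNumber, b: ECNumber) -> int:
    """First level (1-4) at which ``a`` and ``b`` differ, 0 if identical.

    Only mutually specified levels are compared; a wildcard ends the
    comparison, so ``3.4.25.1`` vs ``3.4.25.-`` is 0 (a partial annotation
    cannot witness a change).  Symmetric by construction.
    """
    for k in range(4):
        va, vb = a.levels[k], b.levels[k]
        if va is None or vb is None:
            return 0
        if va != vb:
            return k + 1
    return 0
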
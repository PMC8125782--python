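"""ATC (Anatomical Therapeutic Chemical) code parsing and hierarchy projection.

The WHO ATC system classifies drugs on five nested levels:

==== ====================== ======= =======================
level meaning               length  example
==== ====================== ======= =======================
1    anatomical main group   1      ``J`` (anti-infectives)
2    therapeutic subgroup    3      ``J01``
3    pharmacological subgrp  4      ``J01C``
4    chemical subgroup       5      ``J01CR``
5    chemical substance      7      ``J01CR02``
==== ====================== ======= =======================

A code's level is inferred from its length alone; no registry lookup is
performed (the official ATC index is licensed).  An optional user-supplied
allow-list enables strict validation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "ATCCode",
    "ATCError",
    "MalformedCodeError",
    "UnknownGroupError",
    "CannotRefineError",
    "parse_atc",
    "project_to_level",
    "load_allow_list",
]

#: The 14 anatomical main groups of the ATC system.
ANATOMICAL_GROUPS = frozenset("ABCDGHJLMNPRSV")

#: Code length at each hierarchy level.
LEVEL_LENGTHS = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}
_LENGTH_TO_LEVEL = {v: k for k, v in LEVEL_LENGTHS.items()}

# position classes: letter, digit, digit, letter, letter, digit, digit
_PATTERN = re.compile(r"^[A-Z](\d(\d([A-Z]([A-Z](\d(\d)?)?)?)?)?)?$")


class ATCError(ValueError):
    """Base class for ATC code errors."""


class MalformedCodeError(ATCError):
    """Code has an invalid length or character in a wrong position."""


class UnknownGroupError(ATCError):
    """First character is not one of the 14 anatomical groups."""


class CannotRefineError(ATCError):
    """Projection requested to a level deeper than the code carries."""


@dataclass(frozen=True, order=True)
class ATCCode:
    """A validated ATC code at one of the five hierarchy levels."""

    text: str
    level: int

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.text


def parse_atc(text: str) -> ATCCode:
    """Parse ``text`` into a validated :class:`ATCCode`.

    Input is trimmed and uppercased.  The level is inferred from the
    length (1/3/4/5/7 characters for levels 1-5).

    Raises
    ------
    MalformedCodeError
        If the length is not a valid ATC length or a character violates
        its positional class (letter/digit pattern ``LDDLLDD``).
    UnknownGroupError
        If the leading letter is not one of the 14 anatomical groups.
    """
    code = text.strip().upper()
    if len(code) not in _LENGTH_TO_LEVEL:
        raise MalformedCodeError(
            f"{text!r}: length {len(code)} is not a valid ATC code length "
            f"(expected one of {sorted(_LENGTH_TO_LEVEL)})"
        )
    if not _PATTERN.match(code):
        raise MalformedCodeError(
            f"{text!r}: violates the ATC letter/digit positional pattern"
        )
    if code[0] not in ANATOMICAL_GROUPS:
        raise UnknownGroupError(
            f"{text!r}: {code[0]!r} is not one of the 14 anatomical groups"
        )
    return ATCCode(text=code, level=_LENGTH_TO_LEVEL[len(code)])


def project_to_level(code: ATCCode, target_level: int) -> ATCCode:
    """Project ``code`` upward in the hierarchy to ``target_level``.

    Projection truncates the code text to the target level's length;
    it is the identity when ``target_level == code.level``.  Refinement
    (projecting downward) is impossible and raises
    :class:`CannotRefineError`.
    """
    if target_level not in LEVEL_LENGTHS:
        raise ATCError(f"invalid ATC level {target_level!r}")
    if target_level > code.level:
        raise CannotRefineError(
            f"cannot refine {code.text} (level {code.level}) "
            f"to deeper level {target_level}"
        )
    return ATCCode(text=code.text[: LEVEL_LENGTHS[target_level]], level=target_level)


def load_allow_list(path: str | Path) -> frozenset[str]:
    """Read a plain-text allow-list (one code per line) for strict mode.

    Blank lines and ``#`` comments are ignored; each entry is validated
    with :func:`parse_atc`.
    """
    codes = set()
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            codes.add(parse_atc(entry).text)
    return frozenset(codes)
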
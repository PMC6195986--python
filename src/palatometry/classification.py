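"""Numerical cleft classification codes (LAHS-style).

A code covers four topographic regions in fixed order — upper lip, primary
palate (alveolus), hard palate, soft palate.  Each region carries either a
(right, left) pair of severity grades or a single midline grade; grades run
0 (no cleft) to 3 (most severe).  Canonical text form joins the regions
with hyphens, e.g. ``"03-01-00-00"`` (paired) or ``"00-00-3-3"`` (midline
hard and soft palate).  The parser also accepts en-dash separators, which
appear in typeset tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .errors import ParameterError

REGIONS = ("upper_lip", "primary_palate", "hard_palate", "soft_palate")
_GRADES = frozenset({0, 1, 2, 3})
_SEPARATORS = {"-", "–"}  # hyphen and en-dash

RegionGrade = Union[tuple[int, int], int]


def _check_grade(g: int, where: str) -> int:
    if not isinstance(g, (int,)) or isinstance(g, bool) or g not in _GRADES:
        raise ParameterError(f"{where}: grade must be an integer 0-3, got {g!r}")
    return int(g)


@dataclass(frozen=True)
class CleftCode:
    """Structured four-region classification code.

    Each region is either a ``(right, left)`` tuple or a single int for a
    midline cleft.
    """

    upper_lip: RegionGrade = (0, 0)
    primary_palate: RegionGrade = (0, 0)
    hard_palate: RegionGrade = (0, 0)
    soft_palate: RegionGrade = (0, 0)

    def __post_init__(self) -> None:
        for name in REGIONS:
            value = getattr(self, name)
            if isinstance(value, tuple):
                if len(value) != 2:
                    raise ParameterError(f"{name}: a paired region needs (right, left)")
                right = _check_grade(value[0], name)
                left = _check_grade(value[1], name)
                object.__setattr__(self, name, (right, left))
            else:
                object.__setattr__(self, name, _check_grade(value, name))

    @property
    def regions(self) -> tuple[RegionGrade, RegionGrade, RegionGrade, RegionGrade]:
        return tuple(getattr(self, name) for name in REGIONS)

    def is_midline(self, region: str) -> bool:
        return isinstance(getattr(self, region), int)

    @property
    def has_cleft(self) -> bool:
        return any(
            (value != 0 if isinstance(value, int) else value != (0, 0))
            for value in self.regions
        )


def encode_code(code: CleftCode) -> str:
    """Canonical text form: per region two digits (right, left) or one
    midline digit, regions joined by hyphens."""
    groups = []
    for value in code.regions:
        if isinstance(value, tuple):
            groups.append(f"{value[0]}{value[1]}")
        else:
            groups.append(f"{value}")
    return "-".join(groups)


def parse_code(text: str) -> CleftCode:
    """Parse a classification code string into a :class:`CleftCode`.

    Accepts hyphen or en-dash separators; each of the four groups is one
    (midline) or two (right, left) digits, grades 0-3.

    Raises
    ------
    ParameterError
        With the offending position, if the text does not match the scheme.
    """
    if not isinstance(text, str):
        raise ParameterError(f"expected a string, got {type(text).__name__}")
    s = text.strip()
    for sep in _SEPARATORS:
        s = s.replace(sep, "-")
    groups = s.split("-")
    if len(groups) != 4:
        raise ParameterError(
            f"expected 4 dash-separated groups, got {len(groups)} in {text!r}"
        )
    values: list[RegionGrade] = []
    for pos, (name, group) in enumerate(zip(REGIONS, groups), start=1):
        if not group.isdigit() or len(group) not in (1, 2):
            raise ParameterError(
                f"group {pos} ({name}) must be 1 or 2 digits, got {group!r}"
            )
        digits = [int(ch) for ch in group]
        for d in digits:
            if d not in _GRADES:
                raise ParameterError(
                    f"group {pos} ({name}): grade {d} out of range 0-3 in {text!r}"
                )
        values.append((digits[0], digits[1]) if len(digits) == 2 else digits[0])
    return CleftCode(*values)
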
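"""Tooth Agenesis Code (TAC) profiles and agenesis severity.

The TAC encodes an individual's congenitally-missing-teeth (CMT)
configuration quadrant by quadrant: each missing tooth at position p
(second FDI digit, 1 = central incisor .. 7 = second molar; third molars
excluded) contributes 2^(p-1), and the per-quadrant sum identifies the
agenesis pattern uniquely. Severity follows the usual clinical cut points:
mild (1-2 CMT), moderate (3-5), oligodontia (>= 6); zero CMT is control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "QUADRANTS",
    "TACProfile",
    "InvalidToothError",
    "validate_cmt_set",
    "encode_tac",
    "decode_tac",
    "classify_severity",
    "pattern_key",
    "pattern_group",
    "SEVERITY_ORDER",
]

QUADRANTS = (1, 2, 3, 4)
SEVERITY_ORDER = ("control", "mild", "moderate", "oligodontia")


class InvalidToothError(ValueError):
    """A tooth code is not a valid permanent-dentition FDI code (third molars excluded)."""


def validate_cmt_set(cmt: Iterable[int | str]) -> frozenset[int]:
    """Normalise and validate a set of FDI codes (11-17, 21-27, 31-37, 41-47)."""
    out = set()
    for code in cmt:
        c = int(code)
        q, p = divmod(c, 10)
        if p == 8:
            raise InvalidToothError(
                f"third molar {c} is excluded from agenesis coding by convention"
            )
        if q not in QUADRANTS or not 1 <= p <= 7:
            raise InvalidToothError(f"{c} is not a valid permanent-tooth FDI code")
        out.add(c)
    return frozenset(out)


@dataclass(frozen=True)
class TACProfile:
    """Quadrant-wise TAC values plus total CMT count and canonical pattern key."""

    quadrant_values: tuple[int, int, int, int]
    total_cmt: int
    pattern_key: str

    def __post_init__(self) -> None:
        for v in self.quadrant_values:
            if not 0 <= v <= 127:
                raise ValueError(f"quadrant TAC value {v} outside 0-127")
        bits = sum(int(v).bit_count() for v in self.quadrant_values)
        if bits != self.total_cmt:
            raise ValueError("total_cmt inconsistent with quadrant bit counts")


def pattern_key(cmt: Iterable[int | str]) -> str:
    """Canonical human-readable label: sorted FDI codes joined by '+' ('control' if empty)."""
    codes = sorted(validate_cmt_set(cmt))
    return "+".join(str(c) for c in codes) if codes else "control"


def encode_tac(cmt: Iterable[int | str]) -> TACProfile:
    """Encode a CMT set as quadrant-wise binary TAC values."""
    codes = validate_cmt_set(cmt)
    values = [0, 0, 0, 0]
    for c in codes:
        q, p = divmod(c, 10)
        values[q - 1] += 1 << (p - 1)
    return TACProfile(
        quadrant_values=tuple(values),
        total_cmt=len(codes),
        pattern_key=pattern_key(codes),
    )


def decode_tac(quadrant_values: Iterable[int]) -> frozenset[int]:
    """Invert :func:`encode_tac`: quadrant values back to the FDI code set."""
    values = tuple(int(v) for v in quadrant_values)
    if len(values) != 4:
        raise ValueError("expected exactly four quadrant values")
    codes = set()
    for q, v in zip(QUADRANTS, values):
        if not 0 <= v <= 127:
            raise ValueError(f"quadrant TAC value {v} outside 0-127")
        for p in range(1, 8):
            if v & (1 << (p - 1)):
                codes.add(10 * q + p)
    return frozenset(codes)


def classify_severity(total_cmt: int) -> str:
    """Severity category from the CMT count (0 control, 1-2 mild, 3-5 moderate, >=6 oligodontia)."""
    n = int(total_cmt)
    if n < 0:
        raise ValueError("CMT count cannot be negative")
    if n == 0:
        return "control"
    if n <= 2:
        return "mild"
    if n <= 5:
        return "moderate"
    return "oligodontia"


#: Named pattern groups used for the post hoc delay contrasts: unilateral and
#: bilateral mandibular second-premolar agenesis versus everything else.
_NAMED_GROUPS: dict[frozenset[int], str] = {
    frozenset(): "control",
    frozenset({35}): "35",
    frozenset({45}): "45",
    frozenset({35, 45}): "35+45",
}


def pattern_group(
    cmt: Iterable[int | str],
    named_groups: dict[frozenset[int], str] | None = None,
) -> str:
    """Canonical contrast label for a CMT configuration.

    Named configurations (by default the mandibular second-premolar patterns
    '35', '45', '35+45' and 'control') get their short label; any other
    configuration maps to its canonical pattern key. Pass ``named_groups`` to
    re-group (e.g., pooling either-side unilateral P2 agenesis).
    """
    codes = validate_cmt_set(cmt)
    groups = _NAMED_GROUPS if named_groups is None else named_groups
    return groups.get(codes, pattern_key(codes))
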
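"""Demirjian dental-age scoring with laterality substitution.

Dental age (DA) is estimated from the developmental stages (A-H) of the
seven left mandibular permanent teeth. When a left tooth is congenitally
missing, its right homologue is staged instead; when a tooth is missing
bilaterally, the position's stage is recorded as MISSING and the global
maturity score (and hence DA) cannot be computed directly - such individuals
are handled by the pattern-wise imputation models.

Chronological age (CA) is the time between the date of birth and the date of
the panoramic radiograph, in 365.25-day years, recorded to one decimal place
(half-up rounding). The outcome of interest downstream is DA - CA.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np

from .tables import (
    POSITIONS,
    STAGE_RANK,
    AgeConversionTable,
    MaturityScoreTable,
)

__all__ = [
    "MISSING",
    "StagedDentition",
    "DentalAgeResult",
    "InconsistentRecordError",
    "TooManyMissingError",
    "resolve_laterality",
    "score_dentition",
    "maturity_to_age",
    "chronological_age",
    "score_to_dental_age",
]

#: Sentinel for a bilaterally absent / non-assessable tooth position.
MISSING = None

#: Maximum number of bilaterally missing stage ratings a record may carry.
MAX_MISSING_POSITIONS = 2


class InconsistentRecordError(ValueError):
    """A tooth has no stage rating but is not recorded as congenitally missing."""


class TooManyMissingError(ValueError):
    """More than MAX_MISSING_POSITIONS positions are bilaterally missing."""


def _validate_stage(stage: str, tooth: int) -> str:
    if stage not in STAGE_RANK:
        raise ValueError(f"invalid stage {stage!r} for tooth {tooth} (expected A-H)")
    return stage


@dataclass(frozen=True)
class StagedDentition:
    """One child's seven mandibular tooth stages after laterality resolution.

    ``stages`` maps position 1-7 (central incisor .. second molar) to a stage
    letter A-H, or ``None`` (MISSING) when the tooth is bilaterally absent.
    ``source_side`` records, per position, whether the stage came from the
    left or right quadrant (``None`` for MISSING positions).
    """

    individual_id: str
    sex: str
    stages: Mapping[int, str | None]
    source_side: Mapping[int, str | None] = field(default=None)

    def __post_init__(self) -> None:
        if set(self.stages) != set(POSITIONS):
            raise ValueError(
                f"stages must cover exactly positions {POSITIONS}, got {sorted(self.stages)}"
            )
        for pos, st in self.stages.items():
            if st is not MISSING:
                _validate_stage(st, pos)
        n_missing = len(self.missing_positions)
        if n_missing > MAX_MISSING_POSITIONS:
            raise TooManyMissingError(
                f"{self.individual_id}: {n_missing} missing stage ratings "
                f"(maximum supported is {MAX_MISSING_POSITIONS})"
            )
        if self.source_side is None:
            object.__setattr__(
                self,
                "source_side",
                {p: ("left" if s is not MISSING else None) for p, s in self.stages.items()},
            )

    @property
    def missing_positions(self) -> tuple[int, ...]:
        return tuple(p for p in POSITIONS if self.stages[p] is MISSING)

    @property
    def complete(self) -> bool:
        return not self.missing_positions

    def stage_ranks(self) -> dict[int, int | None]:
        """Ordinal encoding A=1..H=8 (None for MISSING), for downstream models."""
        return {
            p: (STAGE_RANK[s] if s is not MISSING else None)
            for p, s in self.stages.items()
        }


@dataclass(frozen=True)
class DentalAgeResult:
    """Global maturity score and dental age; INCOMPLETE when a stage is MISSING."""

    maturity_score: float | None
    dental_age: float | None
    complete: bool

    def __post_init__(self) -> None:
        if self.complete != (self.maturity_score is not None) or self.complete != (
            self.dental_age is not None
        ):
            raise ValueError("maturity_score and dental_age present iff complete")


def resolve_laterality(
    individual_id: str,
    sex: str,
    left_stages: Mapping[int, str],
    right_stages: Mapping[int, str],
    cmt_set: Iterable[int],
) -> StagedDentition:
    """Resolve per-position stages from the left quadrant with right-side fallback.

    Parameters
    ----------
    left_stages, right_stages
        Stage letters keyed by FDI code (31-37 and 41-47). Entries may be
        absent for congenitally missing teeth.
    cmt_set
        Congenitally missing teeth in FDI notation (any quadrant; only the
        mandibular codes matter here).

    A position takes the left stage when the left tooth is present, otherwise
    the right stage, otherwise MISSING (bilateral absence). A mandibular tooth
    that has no stage but is not in ``cmt_set`` is an inconsistent record.
    """
    cmt = {int(c) for c in cmt_set}
    stages: dict[int, str | None] = {}
    side: dict[int, str | None] = {}
    for pos in POSITIONS:
        fdi_left, fdi_right = 30 + pos, 40 + pos
        left_missing = fdi_left in cmt
        right_missing = fdi_right in cmt
        if not left_missing:
            if fdi_left not in left_stages:
                raise InconsistentRecordError(
                    f"{individual_id}: tooth {fdi_left} has no stage rating and is "
                    "not recorded as congenitally missing"
                )
            stages[pos] = _validate_stage(left_stages[fdi_left], fdi_left)
            side[pos] = "left"
        elif not right_missing:
            if fdi_right not in right_stages:
                raise InconsistentRecordError(
                    f"{individual_id}: tooth {fdi_right} has no stage rating and is "
                    "not recorded as congenitally missing"
                )
            stages[pos] = _validate_stage(right_stages[fdi_right], fdi_right)
            side[pos] = "right"
        else:
            stages[pos] = MISSING
            side[pos] = None
    return StagedDentition(
        individual_id=individual_id, sex=sex, stages=stages, source_side=side
    )


def score_dentition(
    dentition: StagedDentition, table: MaturityScoreTable
) -> float | None:
    """Sum the seven self-weighted stage scores into a global maturity score.

    Returns ``None`` (INCOMPLETE) when any position is MISSING; such children
    are handled by the pattern-wise imputation models instead.
    """
    if table.sex != dentition.sex:
        raise ValueError(
            f"table sex {table.sex!r} does not match dentition sex {dentition.sex!r}"
        )
    if not dentition.complete:
        return None
    return sum(table.contribution(pos, dentition.stages[pos]) for pos in POSITIONS)


def maturity_to_age(
    score: float, table: AgeConversionTable, *, warn_out_of_range: bool = True
) -> float:
    """Convert a global maturity score to dental age (years).

    Exact table knots return their tabulated age; between knots the age is
    linearly interpolated. Scores outside the table range are clamped to the
    boundary age with a warning.
    """
    lo, hi = table.score_range
    if score < lo or score > hi:
        if warn_out_of_range:
            warnings.warn(
                f"maturity score {score:.2f} outside table range [{lo:.2f}, {hi:.2f}]; "
                "clamping to boundary age",
                stacklevel=2,
            )
        score = min(max(score, lo), hi)
    return float(np.interp(score, table.scores, table.ages))


def score_to_dental_age(
    dentition: StagedDentition,
    score_table: MaturityScoreTable,
    age_table: AgeConversionTable,
) -> DentalAgeResult:
    """Full stage -> maturity score -> dental age conversion for one child."""
    score = score_dentition(dentition, score_table)
    if score is None:
        return DentalAgeResult(maturity_score=None, dental_age=None, complete=False)
    da = maturity_to_age(score, age_table)
    return DentalAgeResult(maturity_score=score, dental_age=da, complete=True)


def chronological_age(
    birth_date: _dt.date | str, radiograph_date: _dt.date | str
) -> float:
    """Chronological age in 365.25-day years, half-up rounded to one decimal."""
    if isinstance(birth_date, str):
        birth_date = _dt.date.fromisoformat(birth_date)
    if isinstance(radiograph_date, str):
        radiograph_date = _dt.date.fromisoformat(radiograph_date)
    days = (radiograph_date - birth_date).days
    if days < 0:
        raise ValueError(
            f"radiograph date {radiograph_date} precedes birth date {birth_date}"
        )
    years = Decimal(days) / Decimal("365.25")
    return float(years.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
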
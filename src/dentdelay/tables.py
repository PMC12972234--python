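"""Sex-specific maturity-score and score-to-age reference tables.

The Demirjian system assigns each of the seven left mandibular permanent
teeth (central incisor to second molar) a self-weighted score for its
radiographic developmental stage (A-H); the seven scores sum to a global
maturity score on a 0-100 scale, which a second sex-specific table converts
to dental age in years.

The tables bundled with this package (``data/*_synthetic_v1.csv``) are a
SYNTHETIC stand-in, not a transcription of the published reference values:
they are generated from a logistic maturation model that satisfies every
structural invariant of the real system (non-negative contributions,
monotone in stage, stage-H contributions summing to exactly 100 per sex,
strictly increasing score-to-age map). All pipeline logic is table-agnostic;
users with access to the published tables can load them from CSV in the same
schema via :func:`load_score_table` / :func:`load_age_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "STAGE_RANK",
    "POSITIONS",
    "TOOTH_LABELS",
    "SEXES",
    "MaturityScoreTable",
    "AgeConversionTable",
    "TableError",
    "synthetic_score_table",
    "synthetic_age_table",
    "load_score_table",
    "load_age_table",
    "default_tables",
    "write_synthetic_fixtures",
]

#: Ordinal radiographic stages, rank 1..8.
STAGES: str = "ABCDEFGH"
STAGE_RANK: dict[str, int] = {s: i + 1 for i, s in enumerate(STAGES)}
RANK_STAGE: dict[int, str] = {r: s for s, r in STAGE_RANK.items()}

#: Mandibular tooth positions, mesial to distal (FDI second digit).
POSITIONS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
TOOTH_LABELS: dict[int, str] = {
    1: "I1", 2: "I2", 3: "C", 4: "PM1", 5: "PM2", 6: "M1", 7: "M2",
}

SEXES: tuple[str, str] = ("female", "male")

# --- synthetic-model constants -------------------------------------------------
# Per-tooth weight of a fully mature (stage H) tooth; sums to exactly 100.
_WEIGHTS: dict[str, dict[int, float]] = {
    "female": {1: 11.8, 2: 12.7, 3: 11.5, 4: 13.9, 5: 14.1, 6: 17.6, 7: 18.4},
    "male":   {1: 12.2, 2: 12.9, 3: 11.9, 4: 13.6, 5: 13.8, 6: 17.3, 7: 18.3},
}
# Fraction of the full per-tooth weight contributed at each stage (A..H).
_STAGE_FRACTION: tuple[float, ...] = (0.04, 0.11, 0.21, 0.35, 0.52, 0.70, 0.86, 1.00)
# Logistic maturity curve S(a) = 100 / (1 + exp(-k (a - a0))); girls mature earlier.
_LOGISTIC: dict[str, tuple[float, float]] = {"female": (0.35, 9.0), "male": (0.33, 9.6)}
_AGE_GRID = (0.0, 17.0, 0.1)       # start, stop (inclusive), step
_TERMINAL_KNOT = {"female": (100.0, 18.0), "male": (100.0, 18.5)}

_SCORE_FIXTURE = "maturity_scores_synthetic_v1.csv"
_AGE_FIXTURE = "score_to_age_synthetic_v1.csv"


class TableError(ValueError):
    """A reference table violates its structural invariants or coverage."""


def _check_sex(sex: str) -> str:
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    return sex


@dataclass(frozen=True)
class MaturityScoreTable:
    """Sex-specific map (tooth position, stage) -> maturity score contribution."""

    sex: str
    contributions: Mapping[tuple[int, str], float]

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        self.validate()

    def validate(self) -> None:
        for pos in POSITIONS:
            prev = -math.inf
            for stage in STAGES:
                key = (pos, stage)
                if key not in self.contributions:
                    raise TableError(f"missing entry for tooth {pos}, stage {stage}")
                c = self.contributions[key]
                if c < 0:
                    raise TableError(f"negative contribution at tooth {pos}, stage {stage}")
                if c < prev:
                    raise TableError(
                        f"contribution not monotone in stage at tooth {pos}, stage {stage}"
                    )
                prev = c
        if abs(self.max_score - 100.0) > 1e-6:
            raise TableError(
                f"stage-H contributions sum to {self.max_score}, expected 100"
            )

    @property
    def max_score(self) -> float:
        return sum(self.contributions[(pos, "H")] for pos in POSITIONS)

    def contribution(self, position: int, stage: str) -> float:
        try:
            return self.contributions[(position, stage)]
        except KeyError:
            raise TableError(
                f"no score for tooth position {position}, stage {stage!r} ({self.sex})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": self.sex, "tooth_position": pos, "stage": st,
             "score": self.contributions[(pos, st)]}
            for pos in POSITIONS for st in STAGES
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgeConversionTable:
    """Sex-specific strictly increasing (total maturity score, age in years) knots."""

    sex: str
    scores: np.ndarray
    ages: np.ndarray

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.scores.shape != self.ages.shape or self.scores.ndim != 1:
            raise TableError("scores and ages must be 1-D arrays of equal length")
        if len(self.scores) < 2:
            raise TableError("need at least two knots")
        if not (np.diff(self.scores) > 0).all():
            raise TableError("total scores must be strictly increasing")
        if not (np.diff(self.ages) > 0).all():
            raise TableError("ages must be strictly increasing")

    @property
    def score_range(self) -> tuple[float, float]:
        return float(self.scores[0]), float(self.scores[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sex": self.sex, "total_score": self.scores, "age_years": self.ages}
        )


# --- synthetic stand-in generation --------------------------------------------

def _maturity_fraction(age: float | np.ndarray, sex: str) -> np.ndarray:
    """Latent maturity fraction in (0, 1) at a given age (logistic model)."""
    k, a0 = _LOGISTIC[_check_sex(sex)]
    return 1.0 / (1.0 + np.exp(-k * (np.asarray(age, dtype=float) - a0)))


def _age_from_fraction(frac: float | np.ndarray, sex: str) -> np.ndarray:
    k, a0 = _LOGISTIC[_check_sex(sex)]
    f = np.clip(np.asarray(frac, dtype=float), 1e-12, 1 - 1e-12)
    return a0 + np.log(f / (1.0 - f)) / k


def stage_fraction(stage: str) -> float:
    """Fraction of a tooth's full weight contributed at a stage (synthetic model)."""
    return _STAGE_FRACTION[STAGE_RANK[stage] - 1]


def synthetic_score_table(sex: str) -> MaturityScoreTable:
    """Build the synthetic stand-in self-weighted score table for one sex."""
    w = _WEIGHTS[_check_sex(sex)]
    contributions = {
        (pos, st): round(w[pos] * frac, 2)
        for pos in POSITIONS
        for st, frac in zip(STAGES, _STAGE_FRACTION)
    }
    return MaturityScoreTable(sex=sex, contributions=contributions)


def synthetic_age_table(sex: str) -> AgeConversionTable:
    """Build the synthetic stand-in score-to-age conversion table for one sex."""
    start, stop, step = _AGE_GRID
    ages = np.round(np.arange(start, stop + step / 2, step), 1)
    scores = np.round(100.0 * _maturity_fraction(ages, sex), 3)
    t_score, t_age = _TERMINAL_KNOT[sex]
    scores = np.append(scores, t_score)
    ages = np.append(ages, t_age)
    return AgeConversionTable(sex=sex, scores=scores, ages=ages)


# --- CSV I/O -------------------------------------------------------------------

def load_score_table(path_or_frame: str | pd.DataFrame, sex: str) -> MaturityScoreTable:
    """Load a maturity score table (columns: sex, tooth_position, stage, score)."""
    df = (
        path_or_frame
        if isinstance(path_or_frame, pd.DataFrame)
        else pd.read_csv(path_or_frame, comment="#")
    )
    sub = df[df["sex"] == _check_sex(sex)]
    contributions = {
        (int(r.tooth_position), str(r.stage)): float(r.score)
        for r in sub.itertuples()
    }
    return MaturityScoreTable(sex=sex, contributions=contributions)


def load_age_table(path_or_frame: str | pd.DataFrame, sex: str) -> AgeConversionTable:
    """Load a score-to-age table (columns: sex, total_score, age_years)."""
    df = (
        path_or_frame
        if isinstance(path_or_frame, pd.DataFrame)
        else pd.read_csv(path_or_frame, comment="#")
    )
    sub = df[df["sex"] == _check_sex(sex)].sort_values("total_score")
    return AgeConversionTable(
        sex=sex,
        scores=sub["total_score"].to_numpy(float),
        ages=sub["age_years"].to_numpy(float),
    )


@dataclass(frozen=True)
class ReferenceTables:
    """The pair of tables the scoring pipeline needs, per sex."""

    score: Mapping[str, MaturityScoreTable]
    age: Mapping[str, AgeConversionTable]


def default_tables() -> ReferenceTables:
    """Load the bundled synthetic stand-in tables (validated on load)."""
    pkg = resources.files("dentdelay") / "data"
    with resources.as_file(pkg / _SCORE_FIXTURE) as p:
        score_df = pd.read_csv(p, comment="#")
    with resources.as_file(pkg / _AGE_FIXTURE) as p:
        age_df = pd.read_csv(p, comment="#")
    return ReferenceTables(
        score={s: load_score_table(score_df, s) for s in SEXES},
        age={s: load_age_table(age_df, s) for s in SEXES},
    )


def write_synthetic_fixtures(directory: str) -> list[str]:
    """Regenerate the bundled fixture CSVs (used once at packaging time)."""
    import os

    paths = []
    score_df = pd.concat([synthetic_score_table(s).to_frame() for s in SEXES])
    age_df = pd.concat([synthetic_age_table(s).to_frame() for s in SEXES])
    header = (
        "# SYNTHETIC stand-in reference table (not the published Demirjian values).\n"
        "# Generated by dentdelay.tables.write_synthetic_fixtures; logistic maturation model v1.\n"
    )
    for name, df in ((_SCORE_FIXTURE, score_df), (_AGE_FIXTURE, age_df)):
        path = os.path.join(directory, name)
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        paths.append(path)
    return paths
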
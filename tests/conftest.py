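import numpy as np
import pandas as pd
import pytest

from dentdelay.pipeline import score_cohort
from dentdelay.synthetic import CohortParams, generate
from dentdelay.tables import (
    POSITIONS,
    STAGES,
    AgeConversionTable,
    MaturityScoreTable,
    ReferenceTables,
    default_tables,
)

#: One fast single-point RF configuration, used where the grid is not under test.
FAST_GRID = [{"n_estimators": 300, "max_features": 3, "min_samples_leaf": 5}]


@pytest.fixture(scope="session")
def tables() -> ReferenceTables:
    return default_tables()


@pytest.fixture(scope="session")
def toy_tables() -> ReferenceTables:
    """Tiny hand-built tables, independent of the bundled fixtures."""
    # per-tooth stage contributions: weight * simple monotone fractions
    fractions = [0.0, 0.05, 0.1, 0.25, 0.5, 0.7, 0.85, 1.0]
    weights = {1: 14, 2: 14, 3: 14, 4: 14, 5: 14, 6: 14, 7: 16}
    score = {
        sex: MaturityScoreTable(
            sex=sex,
            contributions={
                (pos, st): weights[pos] * f
                for pos in POSITIONS
                for st, f in zip(STAGES, fractions)
            },
        )
        for sex in ("female", "male")
    }
    age = {
        sex: AgeConversionTable(
            sex=sex,
            scores=np.array([0.0, 20.0, 50.0, 80.0, 100.0]),
            ages=np.array([3.0, 6.0, 10.0, 13.0, 16.0]),
        )
        for sex in ("female", "male")
    }
    return ReferenceTables(score=score, age=age)


@pytest.fixture(scope="session")
def small_cohort():
    return generate(CohortParams(n_total=300, seed=7))


@pytest.fixture(scope="session")
def scored_small(small_cohort):
    return score_cohort(small_cohort.cohort)
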
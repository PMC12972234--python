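"""Synthetic hypodontia-cohort generator.

Produces cohorts with the statistical structure the analysis pipeline
assumes, so every stage is testable without real patient data:

* chronological ages uniform on 6-15 years, two groups (agenesis/control) of
  roughly equal size, more girls than boys;
* sex-specific stage-versus-age maturation driven by the same reference
  tables the scoring pipeline uses (a noiseless child scores back to its
  latent dental age within one stage-quantisation step);
* agenesis configurations concentrated on mandibular second premolars and
  maxillary lateral incisors, with a tunable bilateral correlation, and
  per-tooth probabilities calibrated once so the mean CMT count per affected
  child is about 1.8;
* an injected dental-development delay for the agenesis group (sex-specific,
  optionally growing with the CMT count), applied on the latent dental-age
  scale;
* bilaterally missing mandibular teeth blank both stage ratings, creating
  the missing-stage patterns the imputation models are built for (never more
  than two per child).

Ground-truth latent parameters are returned alongside the cohort for
parameter-recovery tests.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .agenesis import classify_severity, pattern_key, validate_cmt_set
from .tables import POSITIONS, STAGES, ReferenceTables, default_tables

__all__ = [
    "CohortParams",
    "SyntheticCohort",
    "default_agenesis_table",
    "generate",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = (
    ["id", "sex", "group", "ca_years"]
    + [f"stage_3{p}" for p in POSITIONS]
    + [f"stage_4{p}" for p in POSITIONS]
    + ["cmt"]
)


def default_agenesis_table() -> dict[int, float]:
    """Per-tooth agenesis probabilities for an affected child (FDI -> probability).

    Mandibular second premolars (35/45) and maxillary lateral incisors
    (12/22) dominate; homologous teeth share the same marginal probability.
    Together with a bilateral correlation of 0.3 these values put the mean
    CMT count per affected child near 1.8 after conditioning on >= 1 CMT.
    """
    per_pair = {
        # maxilla (positions 1-7)
        (1, 1): 0.004, (1, 2): 0.14, (1, 3): 0.006, (1, 4): 0.015,
        (1, 5): 0.08, (1, 6): 0.004, (1, 7): 0.012,
        # mandible
        (3, 1): 0.012, (3, 2): 0.025, (3, 3): 0.006, (3, 4): 0.015,
        (3, 5): 0.26, (3, 6): 0.004, (3, 7): 0.015,
    }
    out = {}
    for (q, p), prob in per_pair.items():
        out[10 * q + p] = prob          # left homologue (FDI quadrants 1, 3)
        out[10 * (q + 1) + p] = prob    # right homologue (quadrants 2, 4)
    return out


@dataclass(frozen=True)
class CohortParams:
    """Stated-world parameters of the generator (all ages/delays in years)."""

    n_total: int = 626
    agenesis_fraction: float = 0.5
    female_fraction: float = 0.575
    age_range: tuple[float, float] = (6.0, 15.0)
    delay_female: float = 0.94
    delay_male: float = 0.55
    severity_gradient: float = 0.0
    stage_noise_sd: float = 0.5
    bilateral_rho: float = 0.3
    agenesis_probs: Mapping[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("n_total must be at least 2")
        for name in ("agenesis_fraction", "female_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        if self.stage_noise_sd < 0 or not 0.0 <= self.bilateral_rho <= 1.0:
            raise ValueError("invalid noise or correlation parameter")
        if self.agenesis_probs is not None:
            probs = dict(self.agenesis_probs)
            validate_cmt_set(probs.keys())
            if any(not 0.0 <= p <= 1.0 for p in probs.values()):
                raise ValueError("agenesis probabilities must be in [0, 1]")

    def delay_for(self, sex: str) -> float:
        return self.delay_female if sex == "female" else self.delay_male


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort (shared CSV schema) plus its latent ground truth."""

    cohort: pd.DataFrame
    ground_truth: pd.DataFrame
    params: CohortParams

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.cohort.to_csv(buf, index=False)
        return buf.getvalue()


def _score_at_age(age: np.ndarray, age_table) -> np.ndarray:
    """Invert the score->age table: maturity score at a given age (interpolated)."""
    return np.interp(age, age_table.ages, age_table.scores)


def _stage_for_fraction(frac: float, thresholds: np.ndarray) -> str:
    """Nearest stage given a per-tooth maturity fraction and stage thresholds.

    ``thresholds`` are the midpoints between consecutive normalised stage
    contributions; the stage index is the number of midpoints below ``frac``.
    """
    return STAGES[int(np.searchsorted(thresholds, frac))]


def _tooth_thresholds(score_table) -> dict[int, np.ndarray]:
    out = {}
    for pos in POSITIONS:
        c = np.array([score_table.contribution(pos, s) for s in STAGES])
        norm = c / c[-1]
        out[pos] = (norm[:-1] + norm[1:]) / 2.0
    return out


def _sample_cmt(
    rng: np.random.Generator, probs: Mapping[int, float], rho: float
) -> frozenset[int]:
    codes = set()
    seen_pairs = set()
    for fdi, p in probs.items():
        q, pos = divmod(fdi, 10)
        left_q = q if q in (1, 3) else q - 1
        pair = (left_q, pos)
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        left_fdi, right_fdi = 10 * left_q + pos, 10 * (left_q + 1) + pos
        p_pair = probs.get(left_fdi, probs.get(right_fdi, 0.0))
        if rng.random() < rho:
            if rng.random() < p_pair:
                codes.update((left_fdi, right_fdi))
        else:
            if rng.random() < p_pair:
                codes.add(left_fdi)
            if rng.random() < p_pair:
                codes.add(right_fdi)
    return frozenset(codes)


def _bilateral_mandibular(cmt: frozenset[int]) -> tuple[int, ...]:
    return tuple(p for p in POSITIONS if (30 + p) in cmt and (40 + p) in cmt)


def generate(
    params: CohortParams = CohortParams(), tables: ReferenceTables | None = None
) -> SyntheticCohort:
    """Generate a synthetic cohort; reproducible from ``params.seed``.

    Per child: draw sex and group, CA ~ Uniform(age range); the latent dental
    age is CA minus the injected delay (agenesis group only); each tooth
    position gets an effective age jittered by ``stage_noise_sd`` and is
    discretised to the nearest stage implied by the reference tables;
    bilaterally missing mandibular teeth have their stage ratings blanked.
    """
    if tables is None:
        tables = default_tables()
    probs = dict(
        params.agenesis_probs
        if params.agenesis_probs is not None
        else default_agenesis_table()
    )
    rng = np.random.default_rng(params.seed)
    thresholds = {s: _tooth_thresholds(tables.score[s]) for s in ("female", "male")}
    age_support = {
        s: (float(tables.age[s].ages[0]), float(tables.age[s].ages[-1]))
        for s in ("female", "male")
    }

    n = params.n_total
    n_agenesis = int(round(params.agenesis_fraction * n))
    if not any(p > 0 for p in probs.values()):
        n_agenesis = 0  # no tooth can ever be missing: the cohort is all-control
    group = np.array(["agenesis"] * n_agenesis + ["control"] * (n - n_agenesis))
    rng.shuffle(group)
    sex = np.where(rng.random(n) < params.female_fraction, "female", "male")
    ca_true = rng.uniform(*params.age_range, size=n)

    n_clamped = 0
    cohort_rows, truth_rows = [], []
    for i in range(n):
        ind_id = f"S{i + 1:04d}"
        is_agenesis = group[i] == "agenesis"
        cmt: frozenset[int] = frozenset()
        if is_agenesis:
            for _ in range(200):
                cmt = _sample_cmt(rng, probs, params.bilateral_rho)
                if cmt and len(_bilateral_mandibular(cmt)) <= 2:
                    break
            else:  # pragma: no cover - astronomically unlikely fallback
                cmt = frozenset({35})
        delay = (
            params.delay_for(sex[i])
            + params.severity_gradient * max(len(cmt) - 1, 0)
            if is_agenesis
            else 0.0
        )
        latent_da = ca_true[i] - delay
        lo, hi = age_support[sex[i]]
        if not lo <= latent_da <= hi:
            latent_da = min(max(latent_da, lo), hi)
            n_clamped += 1

        eff_age = latent_da + rng.normal(0.0, params.stage_noise_sd, size=len(POSITIONS))
        eff_age = np.clip(eff_age, lo, hi)
        frac = _score_at_age(eff_age, tables.age[sex[i]]) / 100.0
        row: dict = {
            "id": ind_id,
            "sex": sex[i],
            "group": group[i],
            "ca_years": round(float(ca_true[i]), 1),
        }
        for k, pos in enumerate(POSITIONS):
            stage = _stage_for_fraction(frac[k], thresholds[sex[i]][pos])
            row[f"stage_3{pos}"] = "" if (30 + pos) in cmt else stage
            row[f"stage_4{pos}"] = "" if (40 + pos) in cmt else stage
        row["cmt"] = ";".join(str(c) for c in sorted(cmt))
        cohort_rows.append(row)
        missing = _bilateral_mandibular(cmt)
        truth_rows.append(
            {
                "id": ind_id,
                "group": group[i],
                "sex": sex[i],
                "ca_true": float(ca_true[i]),
                "latent_da": float(latent_da),
                "injected_delay": float(delay),
                "n_cmt": len(cmt),
                "severity": classify_severity(len(cmt)),
                "pattern_key": pattern_key(cmt),
                "missing_positions": "".join(str(p) for p in missing),
            }
        )
    if n_clamped:
        warnings.warn(
            f"{n_clamped} latent dental ages fell outside the conversion-table "
            "support and were clamped"
        )
    cohort = pd.DataFrame(cohort_rows, columns=COHORT_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(cohort=cohort, ground_truth=truth, params=params)
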
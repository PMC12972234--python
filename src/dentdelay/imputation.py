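"""Pattern-wise random-forest imputation of dental age.

Children with bilateral mandibular agenesis lack one or two of the seven
stage ratings, so the maturity-score sum is undefined for them. Following a
secondary-diagnosis approach, a dedicated random-forest regressor is trained
for each distinct pattern of missing stage ratings: the reference set is the
complete-case cohort (either group), the target is their table-derived
dental age, and the predictors are the stages of the remaining teeth
(ordinal A=1..H=8) plus sex. Hyperparameters are selected by the forest's
native out-of-bag (OOB) error; held-out test metrics (R2, ME, RMSE, MSE,
MAE) and Bland-Altman agreement summaries document each model before it is
applied to the pattern-matching individuals.

The staged-cohort DataFrame convention used throughout:
columns ``id, sex, group, ca, stage_1..stage_7, da`` where ``stage_p`` is the
ordinal stage rank (NaN = bilaterally missing) and ``da`` is dental age in
years (NaN until computed or imputed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .tables import POSITIONS

__all__ = [
    "MissingPattern",
    "PatternDataset",
    "ImputationModel",
    "FitReport",
    "BlandAltmanSummary",
    "DEFAULT_MIN_REFERENCE",
    "default_grid",
    "enumerate_patterns",
    "split_reference",
    "assemble_reference",
    "tune_and_train",
    "fit_report",
    "evaluate",
    "bland_altman",
    "variable_importance",
    "impute",
    "save_model",
    "load_model",
]

STAGE_COLUMNS = tuple(f"stage_{p}" for p in POSITIONS)
DEFAULT_MIN_REFERENCE = 50


@dataclass(frozen=True, order=True)
class MissingPattern:
    """The subset of tooth positions (1-7) whose stage rating is missing."""

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(sorted(set(int(p) for p in self.positions)))
        object.__setattr__(self, "positions", pos)
        if not pos:
            raise ValueError("a missing pattern cannot be empty")
        if len(pos) > 2:
            raise ValueError(
                f"pattern {pos}: more than two missing stage ratings is unsupported"
            )
        if any(p not in POSITIONS for p in pos):
            raise ValueError(f"pattern positions must be within {POSITIONS}")

    @property
    def label(self) -> str:
        return "P" + "".join(str(p) for p in self.positions)

    def predictor_columns(self) -> list[str]:
        return [f"stage_{p}" for p in POSITIONS if p not in self.positions] + ["sex_male"]


def _missing_positions(row: pd.Series) -> tuple[int, ...]:
    return tuple(p for p in POSITIONS if pd.isna(row[f"stage_{p}"]))


def enumerate_patterns(cohort: pd.DataFrame) -> dict[MissingPattern, list]:
    """Group individuals with >= 1 missing stage rating by their exact pattern.

    Returns a mapping pattern -> ids, sorted by pattern. Complete individuals
    are excluded; each incomplete individual belongs to exactly one pattern.
    """
    out: dict[MissingPattern, list] = {}
    for _, row in cohort.iterrows():
        missing = _missing_positions(row)
        if not missing:
            continue
        pattern = MissingPattern(missing)
        out.setdefault(pattern, []).append(row["id"])
    return dict(sorted(out.items()))


@dataclass(frozen=True)
class PatternDataset:
    """Train/test design matrices for one missing pattern's model."""

    pattern: MissingPattern
    feature_names: tuple[str, ...]
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    train_ids: tuple
    test_ids: tuple

    @property
    def n_train(self) -> int:
        return len(self.y_train)

    @property
    def n_test(self) -> int:
        return len(self.y_test)


def split_reference(
    reference: pd.DataFrame,
    *,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify_by: str | None = "sex",
) -> pd.Series:
    """Assign each complete-case reference individual to 'train' or 'test'.

    Stratified on sex by default so small pattern models see both sexes. The
    same assignment is shared by every pattern model unless recomputed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = pd.Series("test", index=reference.index, dtype=object)
    groups = (
        [g for _, g in reference.groupby(stratify_by, sort=True)]
        if stratify_by
        else [reference]
    )
    for g in groups:
        idx = g.index.to_numpy()
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        labels.loc[idx[:n_train]] = "train"
    return labels


class InsufficientReferenceError(RuntimeError):
    """Too few complete-case reference individuals to fit a pattern model."""


def assemble_reference(
    cohort: pd.DataFrame,
    pattern: MissingPattern,
    *,
    split: pd.Series | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
    min_reference: int = DEFAULT_MIN_REFERENCE,
) -> PatternDataset:
    """Build the train/test dataset for one pattern from complete-case individuals.

    Predictors are the stage ranks at positions *not* in the pattern plus a
    binary sex indicator; the target is the reference (table-derived) dental
    age. Individuals from either group contribute as long as all seven stages
    and DA are present.
    """
    complete = cohort[
        cohort[list(STAGE_COLUMNS)].notna().all(axis=1) & cohort["da"].notna()
    ]
    if len(complete) < min_reference:
        raise InsufficientReferenceError(
            f"pattern {pattern.label}: only {len(complete)} complete-case reference "
            f"individuals (minimum {min_reference}); cannot impute"
        )
    if split is None:
        split = split_reference(
            complete, train_fraction=train_fraction, seed=seed
        )
    split = split.reindex(complete.index)
    features = pattern.predictor_columns()
    X = complete.assign(
        sex_male=(complete["sex"] == "male").astype(float)
    )[features].to_numpy(float)
    y = complete["da"].to_numpy(float)
    is_train = (split == "train").to_numpy()
    return PatternDataset(
        pattern=pattern,
        feature_names=tuple(features),
        X_train=X[is_train],
        y_train=y[is_train],
        X_test=X[~is_train],
        y_test=y[~is_train],
        train_ids=tuple(complete.loc[is_train, "id"]),
        test_ids=tuple(complete.loc[~is_train, "id"]),
    )


def default_grid(n_features: int) -> list[dict]:
    """Small standard RF grid: trees x features-per-split x minimum leaf size."""
    mf = sorted({2, 3, max(1, math.ceil(n_features / 3))})
    return [
        {"n_estimators": t, "max_features": m, "min_samples_leaf": leaf}
        for t in (300, 500, 1000)
        for m in mf
        for leaf in (1, 5)
    ]


@dataclass
class ImputationModel:
    """A trained per-pattern random forest with its tuning metadata."""

    pattern: MissingPattern
    estimator: RandomForestRegressor
    feature_names: tuple[str, ...]
    hyperparameters: dict
    oob_rmse: float
    n_train: int
    seed: int
    grid_results: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))


def _oob_rmse(est: RandomForestRegressor, y: np.ndarray) -> float:
    pred = est.oob_prediction_
    ok = ~np.isnan(pred)
    if not ok.all():  # pragma: no cover - only with very few trees
        pred, y = pred[ok], y[ok]
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def tune_and_train(
    ds: PatternDataset,
    grid: Sequence[Mapping] | None = None,
    seed: int = 0,
) -> ImputationModel:
    """Select RF hyperparameters by OOB RMSE on the training split and refit.

    Every grid point is fitted on the training split only; the configuration
    with the smallest out-of-bag RMSE wins (first in grid order on ties).
    Fully deterministic given (ds, grid, seed).
    """
    if ds.n_train == 0:
        raise ValueError("empty training split")
    if np.ptp(ds.y_train) == 0:
        raise ValueError("degenerate target: zero variance in training DA")
    if grid is None:
        grid = default_grid(len(ds.feature_names))
    rows, best = [], None
    for i, params in enumerate(grid):
        params = dict(params)
        params["max_features"] = min(params.get("max_features", 1), len(ds.feature_names))
        est = RandomForestRegressor(
            oob_score=True, bootstrap=True, random_state=seed, n_jobs=1, **params
        )
        est.fit(ds.X_train, ds.y_train)
        rmse = _oob_rmse(est, ds.y_train)
        rows.append({**params, "oob_rmse": rmse})
        if best is None or rmse < best[0]:
            best = (rmse, params, est)
    oob, params, est = best
    return ImputationModel(
        pattern=ds.pattern,
        estimator=est,
        feature_names=ds.feature_names,
        hyperparameters=params,
        oob_rmse=oob,
        n_train=ds.n_train,
        seed=seed,
        grid_results=pd.DataFrame(rows),
    )


@dataclass(frozen=True)
class FitReport:
    """Standard regression validation metrics (years, except R2)."""

    r2: float
    me: float
    rmse: float
    mse: float
    mae: float
    n: int


def fit_report(reference: np.ndarray, predicted: np.ndarray) -> FitReport:
    """R2, mean error (pred - ref), RMSE, MSE and MAE for paired vectors."""
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1 or len(ref) == 0:
        raise ValueError("reference and predicted must be equal-length 1-D non-empty")
    err = pred - ref
    mse = float(np.mean(err**2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else float("nan")
    return FitReport(
        r2=r2,
        me=float(err.mean()),
        rmse=math.sqrt(mse),
        mse=mse,
        mae=float(np.abs(err).mean()),
        n=len(ref),
    )


def evaluate(model: ImputationModel, ds: PatternDataset) -> FitReport:
    """Test-split validation metrics for a fitted pattern model."""
    if ds.n_test == 0:
        raise ValueError("empty test split")
    return fit_report(ds.y_test, model.predict(ds.X_test))


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Bias and 95% limits of agreement for paired measurements."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    fraction_within_loa: float
    n: int


def bland_altman(
    reference: np.ndarray, predicted: np.ndarray
) -> tuple[BlandAltmanSummary, pd.DataFrame]:
    """Agreement between reference and predicted DA: bias +/- 1.96 SD.

    Returns the summary and the per-pair (mean, difference) table used for
    plotting. Differences are predicted - reference.
    """
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape or len(ref) < 2:
        raise ValueError("need at least two equal-length pairs")
    diff = pred - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(np.mean((diff >= lo) & (diff <= hi)))
    pairs = pd.DataFrame({"mean": (ref + pred) / 2.0, "difference": diff})
    return (
        BlandAltmanSummary(
            bias=bias, sd_diff=sd, loa_low=lo, loa_high=hi,
            fraction_within_loa=within, n=len(ref),
        ),
        pairs,
    )


def variable_importance(
    model: ImputationModel,
    ds: PatternDataset,
    *,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance (increase in test MSE), ranked, one row per predictor."""
    res = permutation_importance(
        model.estimator,
        ds.X_test,
        ds.y_test,
        scoring="neg_mean_squared_error",
        n_repeats=n_repeats,
        random_state=seed,
    )
    out = pd.DataFrame(
        {
            "predictor": ds.feature_names,
            "importance": res.importances_mean,
            "importance_sd": res.importances_std,
        }
    ).sort_values("importance", ascending=False, ignore_index=True)
    return out


class PatternMismatchError(ValueError):
    """An individual's missing positions do not equal the model's pattern."""


def impute(model: ImputationModel, individuals: pd.DataFrame) -> pd.Series:
    """Predict DA for individuals whose missing positions equal the model pattern.

    Returns predictions indexed like ``individuals``. Any individual whose
    missing-stage set differs from the model's pattern (including complete
    cases) raises :class:`PatternMismatchError`.
    """
    bad = [
        str(row["id"])
        for _, row in individuals.iterrows()
        if _missing_positions(row) != model.pattern.positions
    ]
    if bad:
        raise PatternMismatchError(
            f"individuals {bad} do not match pattern {model.pattern.label}"
        )
    X = individuals.assign(
        sex_male=(individuals["sex"] == "male").astype(float)
    )[list(model.feature_names)].to_numpy(float)
    return pd.Series(model.predict(X), index=individuals.index, name="da_imputed")


def save_model(model: ImputationModel, path: str) -> None:
    """Serialize a pattern model (joblib) with a JSON sidecar of its metadata."""
    import joblib

    joblib.dump(model, path)
    sidecar = {
        "pattern": list(model.pattern.positions),
        "feature_names": list(model.feature_names),
        "hyperparameters": model.hyperparameters,
        "oob_rmse": model.oob_rmse,
        "n_train": model.n_train,
        "seed": model.seed,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path: str) -> ImputationModel:
    import joblib

    return joblib.load(path)
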
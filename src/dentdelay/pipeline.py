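"""End-to-end pipeline: score -> enumerate patterns -> train/impute -> delays -> statistics."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agenesis import classify_severity, encode_tac, pattern_group, pattern_key
from .demirjian import (
    TooManyMissingError,
    InconsistentRecordError,
    resolve_laterality,
    score_to_dental_age,
)
from .imputation import (
    InsufficientReferenceError,
    MissingPattern,
    assemble_reference,
    bland_altman,
    enumerate_patterns,
    evaluate,
    impute,
    split_reference,
    tune_and_train,
    variable_importance,
)
from .stats import (
    compare_groups,
    compute_delays,
    fit_delay_model,
    marked_delay,
    pattern_kruskal,
    severity_anova,
)
from .tables import POSITIONS, ReferenceTables, default_tables

__all__ = ["PipelineConfig", "PipelineResult", "score_cohort", "run_pipeline"]

log = logging.getLogger("dentdelay")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the end-to-end run (seeds, RF grid, split, statistical options)."""

    seed: int = 0
    train_fraction: float = 0.8
    min_reference: int = 50
    rf_grid: Sequence[Mapping] | None = None
    welch: bool = False
    importance_repeats: int = 10
    compute_importance: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")


def score_cohort(
    cohort: pd.DataFrame, tables: ReferenceTables | None = None
) -> pd.DataFrame:
    """Stage-resolve and Demirjian-score a cohort (shared CSV schema in).

    Returns the staged cohort frame: ``id, sex, group, ca, stage_1..stage_7``
    (ordinal ranks, NaN = bilaterally missing), ``maturity_score``, ``da``
    (NaN until imputed for incomplete children), ``da_source``, TAC quadrant
    values, severity and pattern labels. Rows whose records are inconsistent
    or have more than two missing ratings are dropped with a log warning.
    """
    if tables is None:
        tables = default_tables()
    rows = []
    for _, raw in cohort.iterrows():
        cmt = frozenset(int(c) for c in str(raw["cmt"]).split(";") if c.strip())
        left = {
            30 + p: raw[f"stage_3{p}"]
            for p in POSITIONS
            if str(raw[f"stage_3{p}"]).strip()
        }
        right = {
            40 + p: raw[f"stage_4{p}"]
            for p in POSITIONS
            if str(raw[f"stage_4{p}"]).strip()
        }
        try:
            dent = resolve_laterality(str(raw["id"]), raw["sex"], left, right, cmt)
        except (InconsistentRecordError, TooManyMissingError) as exc:
            log.warning("dropping %s: %s", raw["id"], exc)
            continue
        result = score_to_dental_age(
            dent, tables.score[dent.sex], tables.age[dent.sex]
        )
        tac = encode_tac(cmt)
        row = {
            "id": dent.individual_id,
            "sex": dent.sex,
            "group": raw.get("group", "agenesis" if cmt else "control"),
            "ca": float(raw["ca_years"]),
        }
        ranks = dent.stage_ranks()
        for p in POSITIONS:
            row[f"stage_{p}"] = float(ranks[p]) if ranks[p] is not None else np.nan
        row.update(
            maturity_score=result.maturity_score,
            da=result.dental_age,
            da_source="demirjian" if result.complete else "",
            tac_q1=tac.quadrant_values[0],
            tac_q2=tac.quadrant_values[1],
            tac_q3=tac.quadrant_values[2],
            tac_q4=tac.quadrant_values[3],
            total_cmt=tac.total_cmt,
            severity=classify_severity(tac.total_cmt),
            pattern_key=tac.pattern_key,
            pattern_label=pattern_group(cmt),
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    """Everything the end-to-end run produced, in memory."""

    scored: pd.DataFrame
    patterns: dict[MissingPattern, list]
    pattern_reports: pd.DataFrame
    predictions: pd.DataFrame
    importances: pd.DataFrame
    delays: pd.DataFrame
    group_comparison: object
    group_comparison_by_sex: dict
    marked: object
    model: object
    severity_omnibus: pd.DataFrame | None
    severity_pairwise: pd.DataFrame | None
    kruskal: tuple | None
    config: PipelineConfig

    @property
    def delta(self) -> float:
        """Estimated group discrepancy in DA-CA (control minus agenesis), years."""
        if self.group_comparison is None:
            raise ValueError("group comparison unavailable (fewer than two groups)")
        return self.group_comparison.delta


def run_pipeline(
    cohort: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    tables: ReferenceTables | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    """Run the full analysis on a cohort in the shared CSV schema.

    Stages: Demirjian scoring -> missing-pattern enumeration -> per-pattern
    RF training/validation -> imputation -> delay table -> group, severity
    and pattern statistics. When ``out_dir`` is given, every artefact is
    written as CSV plus a JSON manifest (input hash, seed, versions).
    """
    if tables is None:
        tables = default_tables()
    scored = score_cohort(cohort, tables)
    if scored.empty:
        raise ValueError("no valid individuals after scoring")

    patterns = enumerate_patterns(scored)
    complete_mask = scored["da"].notna()
    split = None
    if patterns:
        complete = scored[complete_mask]
        split = split_reference(
            complete, train_fraction=config.train_fraction, seed=config.seed
        )
    report_rows, pred_frames, importance_frames = [], [], []
    for k, (pattern, ids) in enumerate(patterns.items()):
        try:
            ds = assemble_reference(
                scored,
                pattern,
                split=split,
                train_fraction=config.train_fraction,
                seed=config.seed,
                min_reference=config.min_reference,
            )
        except InsufficientReferenceError as exc:
            log.warning("%s", exc)
            continue
        model = tune_and_train(ds, grid=config.rf_grid, seed=config.seed + k)
        fit = evaluate(model, ds)
        ba, _ = bland_altman(ds.y_test, model.predict(ds.X_test))
        members = scored.loc[scored["id"].isin(ids)]
        pred = impute(model, members)
        scored.loc[pred.index, "da"] = pred.to_numpy()
        scored.loc[pred.index, "da_source"] = f"imputed({pattern.label})"
        pred_frames.append(
            pd.DataFrame(
                {
                    "id": members["id"].to_numpy(),
                    "pattern": pattern.label,
                    "da_imputed": pred.to_numpy(),
                }
            )
        )
        if config.compute_importance:
            imp = variable_importance(
                model, ds, n_repeats=config.importance_repeats, seed=config.seed
            )
            imp.insert(0, "pattern", pattern.label)
            importance_frames.append(imp)
        report_rows.append(
            {
                "pattern": pattern.label,
                "n_members": len(ids),
                "n_train": ds.n_train,
                "n_test": ds.n_test,
                "oob_rmse": model.oob_rmse,
                **model.hyperparameters,
                "r2": fit.r2,
                "me": fit.me,
                "rmse": fit.rmse,
                "mse": fit.mse,
                "mae": fit.mae,
                "ba_bias": ba.bias,
                "ba_sd": ba.sd_diff,
                "ba_loa_low": ba.loa_low,
                "ba_loa_high": ba.loa_high,
                "ba_within": ba.fraction_within_loa,
            }
        )

    delays = compute_delays(scored)
    group_sizes = delays.groupby("group").size()
    two_groups = set(group_sizes.index) >= {"control", "agenesis"} and group_sizes.min() >= 2
    comparison = by_sex = marked = model_fit = None
    if two_groups:
        comparison = compare_groups(delays, welch=config.welch)
        by_sex = {
            s: compare_groups(delays[delays["sex"] == s], welch=config.welch)
            for s in ("female", "male")
            if (
                delays[delays["sex"] == s]
                .groupby("group")
                .size()
                .reindex(["control", "agenesis"], fill_value=0)
                .ge(2)
                .all()
            )
        }
        marked = marked_delay(delays)
        model_fit = fit_delay_model(delays)
    else:
        by_sex = {}
        log.warning("fewer than two groups with n >= 2: group statistics skipped")
    sev_omni = sev_pair = None
    if delays["severity"].nunique() > 1:
        sev_omni, sev_pair = severity_anova(delays)
    kruskal = None
    if delays["pattern_label"].nunique() > 1:
        kruskal = pattern_kruskal(delays)

    result = PipelineResult(
        scored=scored,
        patterns=patterns,
        pattern_reports=pd.DataFrame(report_rows),
        predictions=(
            pd.concat(pred_frames, ignore_index=True)
            if pred_frames
            else pd.DataFrame(columns=["id", "pattern", "da_imputed"])
        ),
        importances=(
            pd.concat(importance_frames, ignore_index=True)
            if importance_frames
            else pd.DataFrame(columns=["pattern", "predictor", "importance"])
        ),
        delays=delays,
        group_comparison=comparison,
        group_comparison_by_sex=by_sex,
        marked=marked,
        model=model_fit,
        severity_omnibus=sev_omni,
        severity_pairwise=sev_pair,
        kruskal=kruskal,
        config=config,
    )
    if out_dir is not None:
        _write_reports(result, cohort, out_dir)
    return result


def _comparison_row(c) -> dict:
    return {
        "group_a": c.group_a, "group_b": c.group_b,
        "mean_a": c.mean_a, "sd_a": c.sd_a, "n_a": c.n_a,
        "mean_b": c.mean_b, "sd_b": c.sd_b, "n_b": c.n_b,
        "delta": c.delta, "ci_low": c.ci95[0], "ci_high": c.ci95[1],
        "t": c.t, "df": c.df, "p": c.p, "method": c.method,
    }


def _write_reports(result: PipelineResult, cohort: pd.DataFrame, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)

    def _save(df: pd.DataFrame, name: str, units: str) -> None:
        path = os.path.join(out_dir, name)
        with open(path, "w") as fh:
            fh.write(f"# units: {units}\n")
            df.to_csv(fh, index=False)

    _save(result.scored, "scored_cohort.csv", "ages in years; stages ordinal A=1..H=8")
    _save(result.pattern_reports, "pattern_models.csv", "metrics in years except r2")
    _save(result.predictions, "imputed_predictions.csv", "dental age in years")
    _save(result.importances, "variable_importance.csv", "increase in test MSE (years^2)")
    _save(result.delays, "delays.csv", "years")
    if result.group_comparison is not None:
        rows = [dict(_comparison_row(result.group_comparison), stratum="total")]
        rows += [
            dict(_comparison_row(c), stratum=s)
            for s, c in result.group_comparison_by_sex.items()
        ]
        _save(pd.DataFrame(rows), "group_comparison.csv", "years")
        _save(result.model.anova, "anova_type2.csv", "sum_sq in years^2")
        _save(result.model.residual_table(), "residuals_vs_fitted.csv", "years")
        marked_df = pd.DataFrame(
            [
                {
                    "group": g,
                    "n_below": b,
                    "n_total": t,
                    "proportion": result.marked.proportions[g],
                }
                for g, (b, t) in result.marked.counts.items()
            ]
        )
        marked_df["cutoff"] = result.marked.cutoff
        marked_df["chi2_yates"] = result.marked.chi2
        marked_df["p"] = result.marked.p
        _save(marked_df, "marked_delay.csv", "cutoff in years")
    if result.severity_pairwise is not None:
        _save(result.severity_omnibus, "severity_anova.csv", "DA-CA in years")
        _save(result.severity_pairwise, "severity_tukey.csv", "diff in years")
    if result.kruskal is not None:
        H, p, dunn = result.kruskal
        _save(dunn.assign(omnibus_H=H, omnibus_p=p), "pattern_dunn.csv", "ranks")

    cohort_hash = hashlib.sha256(
        cohort.to_csv(index=False).encode()
    ).hexdigest()
    manifest = {
        "dentdelay_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(result.config).items()
        },
        "input_sha256": cohort_hash,
        "n_individuals": int(len(cohort)),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
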
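"""Trial-table file I/O and the batch fitting pipeline.

Trial tables are comma-separated UTF-8 text with a header row naming the
seven columns ``participant_id, task, sequence_index, direction,
trial_index, drawer, angle_deg``.  Randomized rows carry direction 'none',
ordered/skipped rows 'ascending' or 'descending'; the key (participant,
task, sequence_index, trial_index) must be unique.

:func:`run_fit` binds the modules into the batch pipeline: per participant
and task it averages repetitions, fits the appropriate model, decomposes
the directional profiles, and writes a structured JSON document plus a flat
CSV results table, both byte-reproducible under a fixed configuration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import (
    captured_hysteresis_variance,
    classify_participants,
    factorial_ss,
    hysteresis_effect,
)
from .exceptions import (
    HystfitWarning,
    InsufficientDataError,
    ParseError,
    UndefinedVarianceError,
)
from .fit import fit_reuse_model, fit_sigmoid
from .profiles import ObservedProfile
from .synthetic import TRIAL_COLUMNS

__all__ = ["RunConfig", "read_trials", "write_trials", "run_fit"]

logger = logging.getLogger("hystfit")

_VALID_TASKS = {"randomized", "ordered", "skipped"}
_VALID_DIRECTIONS = {"none", "ascending", "descending"}
_KEY = ["participant_id", "task", "sequence_index", "trial_index"]


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table; malformed rows are reported by line.

    Line numbers in error messages count the header as line 1.
    """

    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc

    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    df = df[list(TRIAL_COLUMNS)]

    problems: list[str] = []

    def lines(mask) -> str:
        return ", ".join(str(i + 2) for i in df.index[mask][:10])

    for col in ("sequence_index", "trial_index", "drawer"):
        bad = ~df[col].apply(lambda v: float(v).is_integer() if pd.notna(v) else False)
        if bad.any():
            problems.append(f"non-integer {col} at line(s) {lines(bad)}")
    if not problems:
        df = df.astype({"sequence_index": int, "trial_index": int, "drawer": int})
        for col, lo in (("sequence_index", 1), ("trial_index", 1)):
            bad = df[col] < lo
            if bad.any():
                problems.append(f"{col} < {lo} at line(s) {lines(bad)}")
        bad = ~df["drawer"].between(1, 9)
        if bad.any():
            problems.append(f"drawer outside 1..9 at line(s) {lines(bad)}")
    bad = ~df["task"].isin(_VALID_TASKS)
    if bad.any():
        problems.append(f"unknown task at line(s) {lines(bad)}")
    bad = ~df["direction"].isin(_VALID_DIRECTIONS)
    if bad.any():
        problems.append(f"unknown direction at line(s) {lines(bad)}")
    bad = (df["task"] == "randomized") & (df["direction"] != "none")
    if bad.any():
        problems.append(f"randomized row with a direction at line(s) {lines(bad)}")
    bad = df["task"].isin({"ordered", "skipped"}) & (df["direction"] == "none")
    if bad.any():
        problems.append(f"ordered/skipped row without direction at line(s) {lines(bad)}")
    bad = ~pd.to_numeric(df["angle_deg"], errors="coerce").apply(np.isfinite)
    if bad.any():
        problems.append(f"non-finite angle_deg at line(s) {lines(bad)}")
    dup = df.duplicated(subset=_KEY, keep="first")
    if dup.any():
        problems.append(
            f"duplicate (participant, task, sequence, trial) key at line(s) {lines(dup)}"
        )
    if problems:
        raise ParseError(f"{path}: " + "; ".join(problems))
    df["angle_deg"] = df["angle_deg"].astype(float)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical column order."""
    trials[list(TRIAL_COLUMNS)].to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Batch-pipeline configuration."""

    input_path: str
    output_dir: str
    n_extra_starts: int = 4
    start_seed: int = 0


def _sig6(x):
    """Round floats to 6 significant digits, recursing into containers."""
    if isinstance(x, dict):
        return {k: _sig6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_sig6(v) for v in x]
    if isinstance(x, (float, np.floating)):
        return float(f"{float(x):.6g}")
    if isinstance(x, (int, np.integer, str, bool)) or x is None:
        return x
    return x


def _params_dict(result) -> dict:
    s = result.params.sigmoid
    return {
        "range_deg": s.range,
        "slope_deg_per_drawer": s.slope,
        "x_offset_drawers": s.x_offset,
        "y_offset_deg": s.y_offset,
        "reuse_frac": result.params.reuse,
    }


def _fit_one(profile: ObservedProfile, config: RunConfig):
    kwargs = dict(n_extra_starts=config.n_extra_starts, start_seed=config.start_seed)
    if profile.task == "randomized":
        return fit_sigmoid(profile, **kwargs)
    return fit_reuse_model(profile, **kwargs)


def run_fit(config: RunConfig) -> dict:
    """Fit every participant x task of a trial table and write results.

    Writes ``results.json`` (structured document, stable key order, floats
    at 6 significant digits) and ``results.csv`` (one row per participant x
    task) into ``config.output_dir``.  Participants whose directional tasks
    miss a direction are skipped with a warning.  Returns the document.
    """

    trials = read_trials(config.input_path)
    if trials.empty:
        raise InsufficientDataError(f"{config.input_path}: empty trial table")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "run_fit: input=%s starts=1+%d start_seed=%d",
        config.input_path, config.n_extra_starts, config.start_seed,
    )

    participants: dict = {}
    csv_rows = []
    ratio_by_pid: dict[str, tuple[float, float]] = {}

    for pid, p_trials in trials.groupby("participant_id"):
        participants[pid] = {}
        for task in sorted(p_trials["task"].unique()):
            profile = ObservedProfile.from_trials(p_trials, task)
            try:
                result = _fit_one(profile, config)
            except InsufficientDataError as exc:
                warnings.warn(
                    f"participant {pid}, task {task}: skipped ({exc})",
                    HystfitWarning,
                    stacklevel=2,
                )
                continue
            logger.info(
                "fit %s/%s: converged=%s starts=%d rmse=%.3f",
                pid, task, result.converged, result.n_starts_used, result.rmse,
            )
            entry = {
                "profile": {
                    f"{d}|{drawer}": float(v)
                    for (d, drawer), v in profile.cells.items()
                },
                "params": _params_dict(result),
                "captured_variance_pct": result.captured_variance_pct,
                "rmse_deg": result.rmse,
                "converged": result.converged,
                "n_starts_used": result.n_starts_used,
                "degenerate": result.degenerate,
            }
            row = {
                "participant_id": pid,
                "task": task,
                **_params_dict(result),
                "captured_variance_pct": result.captured_variance_pct,
                "rmse_deg": result.rmse,
                "converged": result.converged,
            }
            if task in ("ordered", "skipped"):
                wide = profile.matrix()
                ss = factorial_ss(wide)
                hyst = hysteresis_effect(profile)
                pred = result.fitted_cells.unstack(level="drawer").loc[
                    ["ascending", "descending"]
                ]
                try:
                    captured_hyst = captured_hysteresis_variance(
                        wide.to_numpy(), pred.to_numpy()
                    )
                except UndefinedVarianceError:
                    captured_hyst = float("nan")
                entry["factorial_ss"] = {
                    "ss_total": ss.ss_total,
                    "ss_sequence": ss.ss_sequence,
                    "ss_drawer": ss.ss_drawer,
                    "ss_interaction": ss.ss_interaction,
                }
                entry["hysteresis"] = {
                    "per_drawer_effect_deg": {
                        str(d): float(v)
                        for d, v in zip(hyst.drawers, hyst.per_drawer_effect)
                    },
                    "mean_effect_deg": hyst.mean_effect,
                    "combined_captured_pct": captured_hyst,
                }
                row.update(
                    ss_sequence=ss.ss_sequence,
                    ss_drawer=ss.ss_drawer,
                    ss_interaction=ss.ss_interaction,
                    mean_effect_deg=hyst.mean_effect,
                    combined_captured_pct=captured_hyst,
                )
                if task == "ordered":
                    ratio_by_pid[pid] = (ss.ss_sequence, ss.ss_interaction)
            participants[pid][task] = entry
            csv_rows.append(row)

    if not csv_rows:
        raise InsufficientDataError("no fittable participant/task combinations")

    # cohort summary: parameter means +/- SD per task, hysteresis/noise split
    results_df = pd.DataFrame(csv_rows)
    cohort: dict = {"parameters": {}}
    param_cols = [
        "range_deg", "slope_deg_per_drawer", "x_offset_drawers",
        "y_offset_deg", "reuse_frac",
    ]
    for task, grp in results_df.groupby("task"):
        cohort["parameters"][task] = {
            "mean": {c: float(grp[c].mean()) for c in param_cols},
            "sd": {c: float(grp[c].std(ddof=1)) for c in param_cols},
            "n": int(len(grp)),
        }
    if len(ratio_by_pid) >= 2:
        pids = sorted(ratio_by_pid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", HystfitWarning)
            groups = classify_participants(
                [ratio_by_pid[p][0] for p in pids],
                [ratio_by_pid[p][1] for p in pids],
                participant_ids=pids,
            )
        cohort["groups"] = {p: str(groups[p]) for p in pids}
        results_df["group"] = results_df["participant_id"].map(
            cohort["groups"]
        ).fillna("")

    document = _sig6(
        {
            "config": {
                "input_path": str(config.input_path),
                "n_extra_starts": config.n_extra_starts,
                "start_seed": config.start_seed,
            },
            "participants": participants,
            "cohort": cohort,
        }
    )
    json_path = out_dir / "results.json"
    json_path.write_text(
        json.dumps(document, sort_keys=True, indent=1, allow_nan=True) + "\n"
    )
    csv_path = out_dir / "results.csv"
    results_df = results_df.sort_values(["participant_id", "task"]).reset_index(
        drop=True
    )
    float_cols = results_df.select_dtypes(include=[float]).columns
    results_df[float_cols] = results_df[float_cols].map(lambda v: float(f"{v:.6g}"))
    results_df.to_csv(csv_path, index=False)
    logger.info("run_fit: wrote %s and %s", json_path, csv_path)
    return document
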
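"""CSV readers and writers for trial logs, questionnaire panels and allocations.

All tabular data are pandas DataFrames with fixed column schemas:

trials        participant_id, timepoint {pre, post}, trial_type
              {congruent, incongruent}, correct (bool), rt_ms (>0);
              after cleaning also discarded (bool) and discard_reason
              {none, error, absolute_bounds, sd_outlier}
scores        participant_id, assessment (0..3), instrument, total,
              optionally item_1..item_k
allocations   participant_id, condition (disgust=0 / neutral=1),
              stimuli (2D=0 / 3D=1)

Readers validate invariants row by row and raise :class:`SchemaError` with the
offending row number. Missing follow-ups are absent rows, never sentinels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger("abmtrial")

TIMEPOINTS = ("pre", "post")
TRIAL_TYPES = ("congruent", "incongruent")
DISCARD_REASONS = ("none", "error", "absolute_bounds", "sd_outlier")
INSTRUMENTS = ("LSAS-SR", "PHQ-9", "GAD-7", "DERS-16", "BBQ")
#: total-score range per instrument (min, max); LSAS-SR: 24 situations each
#: rated 0-3 for fear and again for avoidance -> 48 item ratings, range 0-144.
SCORE_RANGES = {
    "LSAS-SR": (0, 144),
    "PHQ-9": (0, 27),
    "GAD-7": (0, 21),
    "DERS-16": (16, 80),
    "BBQ": (0, 96),
}
LSAS_N_ITEMS = 48
ASSESSMENT_LABELS = {0: "pre", 1: "post", 2: "1-week", 3: "3-month"}

TRIAL_COLUMNS = ["participant_id", "timepoint", "trial_type", "correct", "rt_ms"]


class SchemaError(ValueError):
    """A CSV row violates the schema; the message names the row."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-level dot-probe log, one row per trial.

    Returns a DataFrame with discard fields initialised to none and row order
    preserved. Raises :class:`SchemaError` naming the first offending row for
    non-positive RTs or unknown enum values.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, TRIAL_COLUMNS, path)
    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        row = int(df.index[bad_tp][0])
        raise SchemaError(f"{path} row {row}: unknown timepoint {df.loc[row, 'timepoint']!r}")
    bad_tt = ~df["trial_type"].isin(TRIAL_TYPES)
    if bad_tt.any():
        row = int(df.index[bad_tt][0])
        raise SchemaError(f"{path} row {row}: unknown trial_type {df.loc[row, 'trial_type']!r}")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad_rt = rt.isna() | (rt <= 0)
    if bad_rt.any():
        row = int(df.index[bad_rt][0])
        raise SchemaError(f"{path} row {row}: rt_ms must be a positive number, got {df.loc[row, 'rt_ms']!r}")
    df["rt_ms"] = rt.astype(float)
    df["correct"] = df["correct"].astype(bool)
    if "discarded" not in df.columns:
        df["discarded"] = False
        df["discard_reason"] = "none"
    else:
        df["discarded"] = df["discarded"].astype(bool)
        bad = df["discarded"] != (df["discard_reason"] != "none")
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"{path} row {row}: discarded flag inconsistent with discard_reason")
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def _item_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("item_")]


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a long-format questionnaire panel (one row per participant x
    assessment x instrument), with optional item-level columns.

    For LSAS-SR rows carrying items, the item sum must equal the stated total
    (the questionnaire total is defined as the sum of its 48 ratings, each in
    0..3); a mismatch raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    if df.empty:
        logger.warning("read_scores: %s is empty", path)
        return pd.DataFrame(columns=["participant_id", "assessment", "instrument", "total"])
    _require_columns(df, ["participant_id", "assessment", "instrument", "total"], path)
    bad_inst = ~df["instrument"].isin(INSTRUMENTS)
    if bad_inst.any():
        row = int(df.index[bad_inst][0])
        raise SchemaError(f"{path} row {row}: unknown instrument {df.loc[row, 'instrument']!r}")
    df["assessment"] = df["assessment"].astype(int)
    if not df["assessment"].between(0, 3).all():
        row = int(df.index[~df["assessment"].between(0, 3)][0])
        raise SchemaError(f"{path} row {row}: assessment must be 0..3")
    for inst, (lo, hi) in SCORE_RANGES.items():
        sel = df["instrument"] == inst
        bad = sel & ~df["total"].between(lo, hi)
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(
                f"{path} row {row}: {inst} total {df.loc[row, 'total']} outside [{lo}, {hi}]"
            )
    items = _item_columns(df)
    if items:
        lsas = df["instrument"] == "LSAS-SR"
        with_items = lsas & df[items].notna().all(axis=1)
        if with_items.any():
            sums = df.loc[with_items, items].sum(axis=1)
            mismatch = sums != df.loc[with_items, "total"]
            if mismatch.any():
                row = int(mismatch.index[mismatch][0])
                raise SchemaError(
                    f"{path} row {row}: item sum {sums[row]} != total {df.loc[row, 'total']}"
                )
    return df


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False)


def read_allocations(path: str | Path) -> pd.DataFrame:
    """Read the participant -> group allocation table (two 0/1 dummies)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ["participant_id", "condition", "stimuli"], path)
    for col in ("condition", "stimuli"):
        df[col] = df[col].astype(int)
        if not df[col].isin((0, 1)).all():
            row = int(df.index[~df[col].isin((0, 1))][0])
            raise SchemaError(f"{path} row {row}: {col} must be 0 or 1")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate participant_id {dup!r}")
    return df


def write_allocations(alloc: pd.DataFrame, path: str | Path) -> None:
    alloc.to_csv(path, index=False)


GROUP_LABELS = {(0, 0): "2D disgust", (0, 1): "2D neutral", (1, 0): "3D disgust", (1, 1): "3D neutral"}


def group_label(stimuli: int, condition: int) -> str:
    """Human-readable group name from the two dummies."""
    return GROUP_LABELS[(int(stimuli), int(condition))]


def write_report(results: dict, path: str | Path) -> None:
    """Render a plain-text report of pipeline results.

    `results` maps section name -> DataFrame, Series or scalar mapping; every
    section is printed with its name so each statistic's provenance is visible.
    """
    lines: list[str] = []
    for section, value in results.items():
        lines.append(f"== {section} ==")
        if isinstance(value, pd.DataFrame):
            lines.append(value.to_string())
        elif isinstance(value, dict):
            for k, v in value.items():
                lines.append(f"{k}: {v}")
        else:
            lines.append(str(value))
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
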
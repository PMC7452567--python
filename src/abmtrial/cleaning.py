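"""Reaction-time trial cleaning and participant exclusion.

Three discard rules are applied per participant x timepoint x trial-type
cell, in fixed order, each trial receiving the first applicable reason:

1. error trials (incorrect probe response);
2. absolute bounds: rt < rt_min or rt > rt_max (defaults 200 / 2000 ms,
   exclusive);
3. a single, non-iterative SD pass: |rt - m| > sd_multiplier * s, where m
   and s are the mean and sample (n-1) SD of the trials surviving rules
   1-2 within the cell.

A participant is excluded when strictly more than discard_fraction_limit
(default 20%) of any cell's trials are discarded, counting error trials in
the denominator. Both conventions (which trials feed the SD statistics) are
config switches, since published pipelines differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CleaningConfig

CELL_KEYS = ["participant_id", "timepoint", "trial_type"]


@dataclass
class CleaningReport:
    """Per-cell discard tallies and the resulting participant exclusions.

    cells: one row per participant x timepoint x trial_type with n_total,
    n_error, n_absolute, n_sd_outlier, n_retained and discard_fraction
    (counts always reconcile: n_total = n_error + n_absolute + n_sd_outlier
    + n_retained). excluded: participant -> the first cell that triggered
    exclusion.
    """

    cells: pd.DataFrame
    excluded: dict[str, tuple[str, str]]

    @property
    def excluded_participants(self) -> set[str]:
        return set(self.excluded)


def clean_trials(
    trials: pd.DataFrame, config: CleaningConfig | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Annotate every trial with its discard status and tally per cell.

    Returns a copy of `trials` with `discarded` / `discard_reason` filled in,
    plus a :class:`CleaningReport`. Decisions depend only on cell membership,
    never on row order. A cell left empty after cleaning is reported with
    n_retained = 0; the bias index is undefined there and downstream scoring
    flags the participant.
    """
    config = config or CleaningConfig()
    config.validate()
    out = trials.copy()
    reason = np.full(len(out), "none", dtype=object)

    rt = out["rt_ms"].to_numpy(dtype=float)
    correct = out["correct"].to_numpy(dtype=bool)
    is_error = ~correct
    out_of_bounds = (rt < config.rt_min) | (rt > config.rt_max)
    reason[is_error] = "error"
    reason[~is_error & out_of_bounds] = "absolute_bounds"

    # SD rule on the survivors of rules 1-2 (configurable), one pass per cell
    survives_for_stats = np.ones(len(out), dtype=bool)
    if not config.errors_in_sd_stats:
        survives_for_stats &= ~is_error
    if config.sd_after_absolute:
        survives_for_stats &= ~out_of_bounds

    grouped = out.groupby(CELL_KEYS, sort=False).indices
    records = []
    for key, idx in grouped.items():
        idx = np.asarray(idx)
        stats_idx = idx[survives_for_stats[idx]]
        if stats_idx.size >= 2:
            m = rt[stats_idx].mean()
            s = rt[stats_idx].std(ddof=1)
            candidates = idx[(reason[idx] == "none")]
            outlier = np.abs(rt[candidates] - m) > config.sd_multiplier * s
            reason[candidates[outlier]] = "sd_outlier"
        n_total = idx.size
        n_error = int((reason[idx] == "error").sum())
        n_abs = int((reason[idx] == "absolute_bounds").sum())
        n_sd = int((reason[idx] == "sd_outlier").sum())
        n_ret = n_total - n_error - n_abs - n_sd
        records.append(
            dict(
                zip(CELL_KEYS, key),
                n_total=n_total,
                n_error=n_error,
                n_absolute=n_abs,
                n_sd_outlier=n_sd,
                n_retained=n_ret,
                discard_fraction=(n_total - n_ret) / n_total,
            )
        )

    out["discard_reason"] = reason
    out["discarded"] = reason != "none"
    cells = pd.DataFrame(records)
    report = CleaningReport(cells=cells, excluded=flag_exclusions(cells, config.discard_fraction_limit))
    return out, report


def flag_exclusions(cells: pd.DataFrame, limit: float = 0.20) -> dict[str, tuple[str, str]]:
    """Exclude a participant when any cell's discard fraction strictly
    exceeds `limit` ("more than 20%"), in either timepoint or trial type.

    Returns participant -> (timepoint, trial_type) of the first triggering
    cell in table order.
    """
    excluded: dict[str, tuple[str, str]] = {}
    over = cells[cells["discard_fraction"] > limit]
    for row in over.itertuples(index=False):
        excluded.setdefault(row.participant_id, (row.timepoint, row.trial_type))
    return excluded
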
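"""Jacobson-Truax reliable change and clinically significant change.

Reliable change compares an individual's pre-to-post change against
1.96 * S_diff, the 95% band of a null difference score given the measure's
reliability. Clinical significance adds criterion A: a follow-up score below
the baseline group mean minus 1.96 baseline SDs (i.e. outside the 95% range
of the baseline distribution). Combining the two yields the five-category
label used for trial reporting:

    reliable decrease & below cutoff      -> recovered
    reliable decrease & not below cutoff  -> improved
    no reliable change & below cutoff     -> non_reliably_recovered
    no reliable change & not below        -> unchanged
    reliable increase (any cutoff status) -> deteriorated

The reliable-change threshold is inclusive (>= 1.96 S_diff) and the cutoff
strict (<); both are measure-zero boundaries for continuous scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ASSESSMENT_LABELS

logger = logging.getLogger("abmtrial")

JT_LABELS = ("recovered", "non_reliably_recovered", "improved", "unchanged", "deteriorated")


@dataclass
class CriterionA:
    """Clinical cutoff: baseline_mean - multiplier * baseline_sd.

    With improvement = decrease, a score strictly below the cutoff lies
    outside the 95% interval of the baseline severity distribution.
    """

    baseline_mean: float
    baseline_sd: float
    multiplier: float = 1.96

    @property
    def cutoff(self) -> float:
        return self.baseline_mean - self.multiplier * self.baseline_sd


def reliable_change(
    pre: float,
    post: float,
    s_diff: float,
    multiplier: float = 1.96,
    improvement: str = "decrease",
) -> str:
    """Classify one pre/post pair as improved / unchanged / deteriorated.

    improved iff the change in the direction of improvement is
    >= multiplier * s_diff; deteriorated for the opposite direction.
    """
    if s_diff <= 0:
        raise ValueError("s_diff must be positive")
    delta = (pre - post) if improvement == "decrease" else (post - pre)
    if delta >= multiplier * s_diff:
        return "improved"
    if -delta >= multiplier * s_diff:
        return "deteriorated"
    return "unchanged"


def jt_classify(
    pre: float,
    post: float,
    s_diff: float,
    criterion_a: CriterionA,
    multiplier: float = 1.96,
    improvement: str = "decrease",
) -> str:
    """Five-category Jacobson-Truax label for one pre/post pair.

    A reliable deterioration takes precedence over below-cutoff status:
    a reliable increase ending below the cutoff is still deteriorated.
    """
    rel = reliable_change(pre, post, s_diff, multiplier, improvement)
    below = post < criterion_a.cutoff if improvement == "decrease" else post > criterion_a.cutoff
    if rel == "deteriorated":
        return "deteriorated"
    if rel == "improved":
        return "recovered" if below else "improved"
    return "non_reliably_recovered" if below else "unchanged"


def classify_cohort(
    scores: pd.DataFrame,
    s_diff: float,
    criterion_a: CriterionA | None = None,
    instrument: str = "LSAS-SR",
    multiplier: float = 1.96,
    improvement: str = "decrease",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every participant at every post-baseline assessment.

    `scores` is the long-format panel; assessment 0 is the baseline each
    later assessment is compared to. When criterion_a is None it is derived
    from the cohort's own baseline mean and SD. Participants lacking a
    baseline are excluded with a warning; a missing follow-up simply leaves
    that participant out of that timepoint's denominator.

    Returns (per-participant classification table, per-timepoint label
    counts). The classification table doubles as plot data for
    reliable-change scatter and category-distribution charts.
    """
    panel = scores[scores["instrument"] == instrument]
    wide = panel.pivot_table(index="participant_id", columns="assessment", values="total")
    if 0 not in wide.columns:
        raise ValueError("no baseline (assessment 0) scores present")
    no_baseline = wide.index[wide[0].isna()]
    for pid in no_baseline:
        logger.warning("participant %s lacks a baseline score; excluded from classification", pid)
    wide = wide.dropna(subset=[0])
    if criterion_a is None:
        criterion_a = CriterionA(float(wide[0].mean()), float(wide[0].std(ddof=1)), multiplier)
    rows = []
    for t in sorted(c for c in wide.columns if c != 0):
        sub = wide[[0, t]].dropna()
        for pid, (pre, post) in sub.iterrows():
            rel = reliable_change(pre, post, s_diff, multiplier, improvement)
            rows.append(
                {
                    "participant_id": pid,
                    "assessment": int(t),
                    "timepoint": ASSESSMENT_LABELS.get(int(t), str(t)),
                    "pre": pre,
                    "post": post,
                    "delta": post - pre,
                    "reliable": rel,
                    "below_cutoff": bool(post < criterion_a.cutoff),
                    "jt_label": jt_classify(pre, post, s_diff, criterion_a, multiplier, improvement),
                }
            )
    table = pd.DataFrame(rows)
    counts = (
        table.groupby("assessment")["jt_label"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(JT_LABELS), fill_value=0)
    )
    counts["n"] = counts.sum(axis=1)
    return table, counts
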
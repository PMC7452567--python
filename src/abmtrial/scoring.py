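"""Dot-probe bias-index scoring on cleaned trials.

bias index = mean RT(incongruent) - mean RT(congruent), in ms, computed on
retained trials only. Positive values indicate faster responses to probes
replacing the threatening (disgusted) face, i.e. attention allocated toward
threat; negative values indicate faster responses at the neutral location.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("abmtrial")


def bias_index(cleaned: pd.DataFrame) -> float:
    """Bias index for one participant x timepoint slice of cleaned trials.

    Requires at least one retained trial of each type; raises ValueError
    otherwise (the measurement is undefined for that cell).
    """
    kept = cleaned[~cleaned["discarded"]]
    means = kept.groupby("trial_type")["rt_ms"].mean()
    if "congruent" not in means or "incongruent" not in means:
        raise ValueError("bias index undefined: a trial type has no retained trials")
    return float(means["incongruent"] - means["congruent"])


def bias_table(cleaned: pd.DataFrame, exclude: set[str] | None = None) -> pd.DataFrame:
    """Per participant x timepoint bias measurements over a cleaned log.

    Participants in `exclude` (e.g. the >20%-discard set) are dropped.
    Cells where either trial type has no retained trials yield NaN and a
    logged flag rather than an error, so one bad cell cannot halt a cohort.

    Returns columns participant_id, timepoint, mean_rt_congruent,
    mean_rt_incongruent, n_retained_congruent, n_retained_incongruent,
    bias_index.
    """
    exclude = exclude or set()
    kept = cleaned[~cleaned["discarded"] & ~cleaned["participant_id"].isin(exclude)]
    agg = (
        kept.groupby(["participant_id", "timepoint", "trial_type"])["rt_ms"]
        .agg(["mean", "size"])
        .unstack("trial_type")
    )
    rows = []
    for (pid, tp), row in agg.iterrows():
        mc = row.get(("mean", "congruent"), np.nan)
        mi = row.get(("mean", "incongruent"), np.nan)
        nc = row.get(("size", "congruent"), 0)
        ni = row.get(("size", "incongruent"), 0)
        if np.isnan(mc) or np.isnan(mi):
            logger.warning("bias undefined for participant %s at %s (empty cell)", pid, tp)
        rows.append(
            {
                "participant_id": pid,
                "timepoint": tp,
                "mean_rt_congruent": mc,
                "mean_rt_incongruent": mi,
                "n_retained_congruent": int(0 if np.isnan(nc) else nc),
                "n_retained_incongruent": int(0 if np.isnan(ni) else ni),
                "bias_index": mi - mc,
            }
        )
    return pd.DataFrame(rows)
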
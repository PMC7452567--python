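"""Bundled example inputs.

`baseline_summaries()` returns the published baseline characteristics of a
four-arm VR attentional-bias-modification trial (N = 95 retained
participants with elevated social anxiety): per-group sample size, mean and
SD for age, the pre-training dot-probe bias index and five questionnaire
totals, plus the categorical sex and tertiary-education counts. These
printed summaries are exactly the input the summary-statistics comparison
routines in :mod:`abmtrial.inference` are designed for, and serve as the
worked example throughout the documentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GROUPS = ["2D disgust", "2D neutral", "3D disgust", "3D neutral"]
GROUP_N = [22, 23, 25, 25]

_CONTINUOUS = {
    # measure: (means, sds) per group, in GROUPS order
    "age": ([40.23, 39.35, 35.92, 38.08], [13.53, 12.40, 10.88, 13.08]),
    "bias_index": ([9.47, -23.39, 9.11, -2.21], [37.29, 48.28, 37.72, 32.80]),
    "LSAS-SR": ([63.91, 62.22, 65.28, 67.72], [20.61, 18.15, 27.37, 23.52]),
    "PHQ-9": ([6.09, 5.74, 4.48, 5.48], [3.60, 3.43, 3.50, 4.10]),
    "GAD-7": ([4.64, 4.96, 4.68, 5.40], [4.11, 2.87, 4.07, 4.32]),
    "DERS-16": ([37.50, 31.74, 36.00, 39.76], [14.08, 8.32, 16.21, 15.75]),
    "BBQ": ([52.23, 43.61, 54.40, 46.84], [16.76, 16.12, 26.62, 18.65]),
}

_CATEGORICAL = {
    # measure: count with the attribute, per group (out of GROUP_N)
    "male": [8, 14, 11, 15],
    "tertiary_education": [16, 14, 13, 14],
}

#: measures whose group variances were heterogeneous at baseline, analysed
#: with Welch's ANOVA instead of the classical one-way ANOVA
WELCH_MEASURES = ("DERS-16", "BBQ")


def baseline_summaries() -> dict[str, pd.DataFrame]:
    """Per-measure group summary tables.

    Continuous measures map to a DataFrame with columns group, n, mean, sd;
    categorical measures to a 2 x 4 count table (attribute present/absent
    by group) ready for a chi-square test of independence.
    """
    out: dict[str, pd.DataFrame] = {}
    for measure, (means, sds) in _CONTINUOUS.items():
        out[measure] = pd.DataFrame(
            {"group": GROUPS, "n": GROUP_N, "mean": means, "sd": sds}
        )
    for measure, counts in _CATEGORICAL.items():
        counts = np.asarray(counts)
        out[measure] = pd.DataFrame(
            [counts, np.asarray(GROUP_N) - counts],
            index=[measure, f"not_{measure}"],
            columns=GROUPS,
        )
    return out
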
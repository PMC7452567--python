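"""Reliability machinery for the bias index and the questionnaires.

The bias index inherits the dot-probe task's notoriously low internal
consistency, so reliability is estimated by resampled split-half: for each
of n_splits random splits, every participant's retained congruent trials and
retained incongruent trials are independently halved (stratified, so both
halves contain both trial types), a bias index is computed per half, and the
Pearson correlation between half-1 and half-2 indices across participants is
recorded. The per-split correlations are averaged and Spearman-Brown
corrected (r_full = 2 r / (1 + r)) to full test length; negative split
correlations are retained in the average, since truncating them would bias
the estimate upward.

Questionnaire internal consistency uses Cronbach's alpha, and the standard
error of measurement SE_M = sd * sqrt(1 - r) feeds the reliable-change
threshold through S_diff = sqrt(2 * SE_M^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("abmtrial")


@dataclass
class ReliabilityEstimate:
    """A reliability coefficient with the metadata needed to reproduce it."""

    method: str  # splithalf_random | cronbach_alpha
    value: float
    n_splits: int | None = None
    seed: int | None = None
    correction_order: str | None = None


def spearman_brown(r: float, factor: float = 2.0) -> float:
    """Prophecy formula: reliability of a test `factor` times longer.

    Fixed points at 0 and 1; monotone increasing in r.
    """
    return factor * r / (1 + (factor - 1) * r)


def _column_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column pair of two (n, m) matrices,
    ignoring NaN rows per column."""
    valid = ~(np.isnan(a) | np.isnan(b))
    n = valid.sum(axis=0)
    a0 = np.where(valid, a, 0.0)
    b0 = np.where(valid, b, 0.0)
    ma = a0.sum(axis=0) / n
    mb = b0.sum(axis=0) / n
    da = np.where(valid, a - ma, 0.0)
    db = np.where(valid, b - mb, 0.0)
    cov = (da * db).sum(axis=0)
    denom = np.sqrt((da**2).sum(axis=0) * (db**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return cov / denom


def _masked_trimmed_mean(mask: np.ndarray, rt: np.ndarray, sd_multiplier: float | None
                         ) -> np.ndarray:
    """Mean RT of the masked trials per row, optionally after one SD-trim
    pass computed within the masked set of that row."""
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = (mask @ rt) / n
        if sd_multiplier is not None:
            sq = (mask @ rt**2) / n
            var = (sq - m**2) * n / np.maximum(n - 1, 1)
            s = np.sqrt(np.maximum(var, 0.0))
            keep = mask & (np.abs(rt[None, :] - m[:, None]) <= sd_multiplier * s[:, None])
            keep |= mask & (n[:, None] < 2)  # too few trials to trim
            n = keep.sum(axis=1)
            m = (keep @ rt) / n
        return np.where(n > 0, m, np.nan)


def _split_half_means(rt: np.ndarray, n_splits: int, rng: np.random.Generator,
                      sd_multiplier: float | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Mean RT of two random halves of one cell, for every split at once.

    Returns two length-n_splits vectors. Odd cardinality assigns the extra
    trial to a random half per split; a cell of size 1 leaves one half empty
    (NaN), and the caller drops that participant from that split. When
    sd_multiplier is given, the SD-outlier rule is re-applied within each
    half: trimming the pooled cell first and then splitting makes the two
    halves share the cell's sampling fluctuation, which inflates the
    half-half correlation well above zero even for a bias with no true
    between-person variance.
    """
    n = rt.size
    if n == 0:
        nan = np.full(n_splits, np.nan)
        return nan, nan
    # rank of each trial under a fresh random permutation, one row per split
    ranks = np.argsort(np.argsort(rng.random((n_splits, n)), axis=1), axis=1)
    k = n // 2 + (rng.random(n_splits) < 0.5) * (n % 2)
    in_half1 = ranks < k[:, None]
    m1 = _masked_trimmed_mean(in_half1, rt, sd_multiplier)
    m2 = _masked_trimmed_mean(~in_half1, rt, sd_multiplier)
    return m1, m2


def split_half_reliability(
    cleaned: pd.DataFrame,
    n_splits: int = 5000,
    seed: int = 0,
    correction_order: str = "average_then_correct",
    exclude: set[str] | None = None,
    sd_trim_within_half: bool = True,
    sd_multiplier: float = 2.0,
) -> ReliabilityEstimate:
    """Resampled, Spearman-Brown-corrected split-half reliability of the
    bias index over a cohort's cleaned trials (typically the pre-training
    measurement).

    By default (sd_trim_within_half) the error and absolute-bounds discards
    are honoured upstream but the sample-dependent SD-outlier rule is
    re-applied inside each random half: the SD rule couples every trial to
    its cell-mates, and splitting an already-trimmed cell leaves both halves
    sharing the cell's sampling fluctuation, which biases the estimate
    upward by ~0.2-0.4 even when the bias has no true between-person
    variance. With sd_trim_within_half=False the fully cleaned trials are
    split as-is (the convention some published pipelines use).

    Every retained participant needs >= 2 retained trials per trial type for
    both halves to be defined in every split; participants with a half left
    empty are dropped from that split's correlation and logged. Fewer than
    three contributing participants make the estimate undefined
    (ValueError).
    """
    if correction_order not in ("average_then_correct", "correct_then_average"):
        raise ValueError(f"unknown correction_order {correction_order!r}")
    exclude = exclude or set()
    if sd_trim_within_half:
        usable = cleaned["discard_reason"].isin(("none", "sd_outlier"))
    else:
        usable = ~cleaned["discarded"]
    kept = cleaned[usable & ~cleaned["participant_id"].isin(exclude)]
    rng = np.random.default_rng(seed)
    participants = kept["participant_id"].unique()
    if participants.size < 3:
        raise ValueError("split-half reliability undefined with < 3 participants")
    bias1 = np.empty((participants.size, n_splits))
    bias2 = np.empty((participants.size, n_splits))
    groups = kept.groupby(["participant_id", "trial_type"])["rt_ms"]
    for i, pid in enumerate(participants):
        try:
            con = groups.get_group((pid, "congruent")).to_numpy()
            inc = groups.get_group((pid, "incongruent")).to_numpy()
        except KeyError:
            con = np.empty(0)
            inc = np.empty(0)
        trim = sd_multiplier if sd_trim_within_half else None
        c1, c2 = _split_half_means(con, n_splits, rng, trim)
        i1, i2 = _split_half_means(inc, n_splits, rng, trim)
        bias1[i] = i1 - c1
        bias2[i] = i2 - c2
        if con.size < 2 or inc.size < 2:
            logger.warning(
                "participant %s has a trial type with < 2 retained trials; "
                "dropped from splits with an empty half", pid,
            )
    r = _column_pearson(bias1, bias2)
    if np.isnan(r).any():
        logger.warning("%d of %d splits had undefined correlations and were dropped",
                       int(np.isnan(r).sum()), n_splits)
        r = r[~np.isnan(r)]
    if correction_order == "average_then_correct":
        value = spearman_brown(float(r.mean()))
    else:
        value = float(np.mean([spearman_brown(float(x)) for x in r]))
    return ReliabilityEstimate(
        method="splithalf_random",
        value=value,
        n_splits=n_splits,
        seed=seed,
        correction_order=correction_order,
    )


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> ReliabilityEstimate:
    """Cronbach's alpha of a complete participants x items matrix:

        alpha = k/(k-1) * (1 - sum(item variances) / variance(total))

    with sample (n-1) variances. Undefined (ValueError) when the total score
    has zero variance.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("alpha needs >= 2 participants and >= 2 items")
    if np.isnan(x).any():
        raise ValueError("alpha requires a complete item matrix")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: total score has zero variance")
    item_var = x.var(axis=0, ddof=1).sum()
    return ReliabilityEstimate(method="cronbach_alpha", value=float(k / (k - 1) * (1 - item_var / total_var)))


def sem(sd_baseline: float, r: float) -> float:
    """Standard error of measurement, SE_M = sd * sqrt(1 - r).

    r >= 1 is degenerate (a perfectly reliable measure has no measurement
    error); returns 0 with a warning.
    """
    if sd_baseline <= 0:
        raise ValueError("sd_baseline must be positive")
    if r >= 1:
        if r > 1:
            warnings.warn("reliability > 1 is degenerate; SE_M set to 0")
        return 0.0
    return float(sd_baseline * np.sqrt(1 - r))


def sdiff(se_m: float) -> float:
    """Standard error of a difference score, S_diff = sqrt(2 * SE_M^2)."""
    return float(np.sqrt(2.0) * se_m)
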
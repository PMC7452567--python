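"""Synthetic trial data with the statistical structure the analysis assumes.

Three generators cover the trial's three data streams:

* block-pseudorandomised allocation of sessions to the four training groups
  (2D/3D stimuli x disgust/neutral condition), in blocks of 4, 8 or 12;
* trial-level dot-probe logs: each participant carries a latent mean reaction
  time mu_i and a latent attentional bias b_i; congruent trials centre on
  mu_i - b_i/2 and incongruent trials on mu_i + b_i/2, so the expected bias
  index (incongruent mean - congruent mean) equals b_i exactly. Within-trial
  noise is ex-Gaussian (Gaussian + exponential tail), the standard model for
  RT data; error responses and extreme-RT contamination are mixed in at
  configurable rates;
* longitudinal questionnaire totals following a linear mixed model with
  random intercepts and slopes per participant, missing follow-ups, and an
  optional item-level expansion that conserves the total exactly.

Default parameters emulate a 100-participant social-anxiety cohort measured
with 100 dot-probe trials per timepoint and four LSAS-SR assessments; the
dot-probe defaults put the split-half reliability of the bias index in the
low regime (~0.05-0.2) characteristic of the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError
from .io import LSAS_N_ITEMS

GROUPS = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (stimuli, condition) dummies


@dataclass
class RtGenModel:
    """Generative model for dot-probe reaction times (all times in ms).

    mu is the population mean of the Gaussian RT component; sigma_subj the
    between-participant SD of that mean; exgauss_sigma / exgauss_tau the
    within-participant Gaussian SD and exponential tail of trial noise.
    bias_mean_by_group gives the group-level mean of the latent bias b_i
    (a single float applies to all four groups); bias_sd its
    between-participant SD. Error trials occur with probability p_error;
    with probability p_outlier a trial's RT is replaced by a uniform draw
    from outlier_range, which must sit above the cleaning rt_max so that
    contamination is filterable.
    """

    mu: float = 600.0
    sigma_subj: float = 80.0
    exgauss_sigma: float = 150.0
    exgauss_tau: float = 150.0
    bias_mean_by_group: float | dict[tuple[int, int], float] = 0.0
    bias_sd: float = 12.0
    p_error: float = 0.05
    p_outlier: float = 0.02
    outlier_range: tuple[float, float] = (2100.0, 5000.0)
    n_trials_per_timepoint: int = 100

    def validate(self) -> None:
        for p in (self.p_error, self.p_outlier):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must be in [0, 1]")
        if self.outlier_range[0] >= self.outlier_range[1]:
            raise ConfigError("outlier_range must be increasing")
        if self.n_trials_per_timepoint < 2 or self.n_trials_per_timepoint % 2:
            raise ConfigError("n_trials_per_timepoint must be an even count >= 2")
        for v in (self.sigma_subj, self.exgauss_sigma, self.exgauss_tau, self.bias_sd):
            if v < 0:
                raise ConfigError("SD parameters must be non-negative")

    def bias_mean(self, stimuli: int, condition: int) -> float:
        if isinstance(self.bias_mean_by_group, dict):
            return float(self.bias_mean_by_group[(stimuli, condition)])
        return float(self.bias_mean_by_group)


@dataclass
class ScoreGenModel:
    """Generative linear mixed model for longitudinal questionnaire totals.

    total_it = gamma0 + u0i + (gamma_time + u1i) * t
               + gamma_cond * cond + gamma_stim * stim
               + gamma_tc * t * cond + gamma_ts * t * stim
               + gamma_cs * cond * stim + gamma_tcs * t * cond * stim
               + eps_it

    with (u0i, u1i) bivariate normal (SDs tau0, tau1, correlation rho) and
    eps ~ N(0, sigma_eps). t is the assessment index 0..3, cond is
    disgust=0 / neutral=1, stim is 2D=0 / 3D=1. Totals are rounded and
    clipped to the instrument range. Follow-up rows (t=2, t=3) are deleted
    independently with the stated probabilities, mirroring the attrition
    pattern of a 100-participant trial (9% and 7%).
    """

    gamma0: float = 67.56
    gamma_time: float = -4.57
    gamma_cond: float = -3.90
    gamma_stim: float = 1.66
    gamma_time_cond: float = 1.14
    gamma_time_stim: float = -0.52
    gamma_cond_stim: float = 5.92
    gamma_time_cond_stim: float = -0.36
    tau0: float = 20.0
    tau1: float = 5.0
    rho: float = -0.3
    sigma_eps: float = 7.0
    p_missing_fu1: float = 0.09
    p_missing_fu2: float = 0.07
    instrument: str = "LSAS-SR"
    score_range: tuple[int, int] = (0, 144)

    def validate(self) -> None:
        if not -1 <= self.rho <= 1:
            raise ConfigError("rho must be in [-1, 1]")
        for v in (self.tau0, self.tau1, self.sigma_eps):
            if v < 0:
                raise ConfigError("SD parameters must be non-negative")
        for p in (self.p_missing_fu1, self.p_missing_fu2):
            if not 0 <= p <= 1:
                raise ConfigError("missingness probabilities must be in [0, 1]")

    def fixed_mean(self, t: float, cond: int, stim: int) -> float:
        return (
            self.gamma0
            + self.gamma_time * t
            + self.gamma_cond * cond
            + self.gamma_stim * stim
            + self.gamma_time_cond * t * cond
            + self.gamma_time_stim * t * stim
            + self.gamma_cond_stim * cond * stim
            + self.gamma_time_cond_stim * t * cond * stim
        )


def allocate_blocks(
    n_sessions: int,
    block_sizes: tuple[int, ...] = (4, 8, 12),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Pseudorandomise sessions to the four groups in balanced blocks.

    Block sizes are drawn with replacement from `block_sizes` (each must be
    divisible by 4); within each block the four groups appear equally often
    in random order. The concatenated sequence is truncated to n_sessions,
    so the worst-case imbalance between group counts is bounded by the
    residual of the final block.
    """
    for b in block_sizes:
        if b % 4:
            raise ConfigError(f"block size {b} not divisible by 4")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows: list[tuple[int, int]] = []
    while len(rows) < n_sessions:
        b = int(rng.choice(block_sizes))
        block = GROUPS * (b // 4)
        order = rng.permutation(len(block))
        rows.extend(block[i] for i in order)
    rows = rows[:n_sessions]
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n_sessions)],
            "condition": [c for _, c in rows],
            "stimuli": [s for s, _ in rows],
        }
    )


def generate_trials(
    allocations: pd.DataFrame,
    model: RtGenModel | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate pre- and post-training dot-probe logs for every participant.

    Per participant x timepoint, n_trials_per_timepoint trials are generated
    with trial types balanced 50/50 and interleaved in random order. The
    latent bias b_i enters symmetrically (+-b_i/2) so trial cleaning cannot
    bias the index's expectation; b_i is drawn once per participant and
    shared by both timepoints (the training conditions emulated here do not
    shift bias).
    """
    model = model or RtGenModel()
    model.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    half = model.n_trials_per_timepoint // 2
    frames = []
    for row in allocations.itertuples(index=False):
        mu_i = model.mu + model.sigma_subj * rng.standard_normal()
        b_i = model.bias_mean(row.stimuli, row.condition) + model.bias_sd * rng.standard_normal()
        for timepoint in ("pre", "post"):
            types = np.repeat(["congruent", "incongruent"], half)
            rng.shuffle(types)
            centre = np.where(types == "congruent", mu_i - b_i / 2, mu_i + b_i / 2)
            rt = (
                centre
                + model.exgauss_sigma * rng.standard_normal(types.size)
                + rng.exponential(model.exgauss_tau, types.size)
            )
            rt = np.maximum(rt, 1.0)  # RTs are positive by definition
            is_outlier = rng.random(types.size) < model.p_outlier
            rt[is_outlier] = rng.uniform(*model.outlier_range, is_outlier.sum())
            correct = rng.random(types.size) >= model.p_error
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": row.participant_id,
                        "timepoint": timepoint,
                        "trial_type": types,
                        "correct": correct,
                        "rt_ms": rt,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out["discarded"] = False
    out["discard_reason"] = "none"
    return out


def _expand_items(total: int, n_items: int, item_max: int, rng: np.random.Generator,
                  dispersion: float) -> np.ndarray:
    """Decompose an integer total into n_items scores in {0..item_max}.

    Largest-remainder allocation of the total across items, with random
    positive weights controlling inter-item dispersion; any item pushed past
    item_max has its excess moved to the lowest items, so the sum is
    conserved exactly and every item stays in range.
    """
    if not 0 <= total <= n_items * item_max:
        raise ConfigError(f"total {total} not representable with {n_items} items of max {item_max}")
    w = rng.gamma(max(1e-6, 1.0 / max(dispersion, 1e-6)), size=n_items)
    w = w / w.sum()
    quota = total * w
    items = np.floor(quota).astype(int)
    remainder = total - items.sum()
    order = np.argsort(-(quota - items), kind="stable")
    items[order[:remainder]] += 1
    # repair range violations while conserving the sum
    while (items > item_max).any():
        hi = int(np.argmax(items))
        lo = int(np.argmin(items))
        excess = items[hi] - item_max
        room = item_max - items[lo]
        move = min(excess, room)
        items[hi] -= move
        items[lo] += move
    return items


def generate_scores(
    allocations: pd.DataFrame,
    model: ScoreGenModel | None = None,
    seed: int | np.random.Generator = 0,
    with_items: bool = False,
    item_dispersion: float = 1.0,
) -> pd.DataFrame:
    """Simulate the longitudinal questionnaire panel (assessments 0..3).

    Returns a long-format DataFrame; when with_items is set, each LSAS-SR
    total is expanded into 48 item ratings in {0..3} whose sum equals the
    total exactly.
    """
    model = model or ScoreGenModel()
    model.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cov = np.array(
        [
            [model.tau0**2, model.rho * model.tau0 * model.tau1],
            [model.rho * model.tau0 * model.tau1, model.tau1**2],
        ]
    )
    lo, hi = model.score_range
    n_items = LSAS_N_ITEMS
    item_max = 3
    rows = []
    for row in allocations.itertuples(index=False):
        u0, u1 = rng.multivariate_normal([0.0, 0.0], cov)  # svd method: PSD-safe
        for t in range(4):
            if t == 2 and rng.random() < model.p_missing_fu1:
                continue
            if t == 3 and rng.random() < model.p_missing_fu2:
                continue
            y = (
                model.fixed_mean(t, row.condition, row.stimuli)
                + u0
                + u1 * t
                + model.sigma_eps * rng.standard_normal()
            )
            total = int(np.clip(np.rint(y), lo, hi))
            rec = {
                "participant_id": row.participant_id,
                "assessment": t,
                "instrument": model.instrument,
                "total": total,
            }
            if with_items and model.instrument == "LSAS-SR":
                items = _expand_items(total, n_items, item_max, rng, item_dispersion)
                rec.update({f"item_{j + 1}": int(v) for j, v in enumerate(items)})
            rows.append(rec)
    return pd.DataFrame(rows)
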
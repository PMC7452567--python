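"""The trial's statistical tests.

Baseline group comparisons are computable both from raw data and from
printed summary statistics (n, mean, SD per group), since published
baseline tables report only summaries: one-way ANOVA, Welch's
heteroscedastic ANOVA, Pearson chi-square for categorical rows, and
Tukey-Kramer pairwise comparisons. Pre/post bias change uses a 2 x 4 mixed
between-within ANOVA. Longitudinal questionnaire change uses a linear
mixed-effects model with random intercepts and slopes per participant,
fixed effects for time (assessment 0..3), training condition
(disgust=0 / neutral=1), stimulus dimensionality (2D=0 / 3D=1) and all
interactions, fit by maximum likelihood so AIC and likelihood-ratio
comparisons across fixed-effect structures are valid. Model fit is
summarised by Nagelkerke's pseudo-r2 against the intercept-only model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger("abmtrial")


# ---------------------------------------------------------------------------
# summary-statistics group comparisons

def _as_summary(summary: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = summary["n"].to_numpy(dtype=float)
    m = summary["mean"].to_numpy(dtype=float)
    s = summary["sd"].to_numpy(dtype=float)
    if (n < 2).any():
        raise ValueError("every group needs n >= 2")
    if (s < 0).any():
        raise ValueError("negative SD")
    return n, m, s


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided t-based p-value; requires >= 3 complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("pearson_correlation needs >= 3 complete pairs")
    if x[ok].std() == 0 or y[ok].std() == 0:
        raise ValueError("correlation undefined with zero variance")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)


def oneway_anova_from_summary(summary: pd.DataFrame) -> dict:
    """One-way fixed-effects ANOVA from per-group (n, mean, sd).

    SS_between = sum n_i (m_i - grand mean)^2, SS_within = sum (n_i - 1) s_i^2;
    identical to a raw-data ANOVA because those two sums are sufficient.
    """
    n, m, s = _as_summary(summary)
    k = len(n)
    if k < 2:
        raise ValueError("need >= 2 groups")
    N = n.sum()
    grand = (n * m).sum() / N
    ss_b = (n * (m - grand) ** 2).sum()
    ss_w = ((n - 1) * s**2).sum()
    df1, df2 = k - 1, N - k
    if ss_w == 0:
        logger.warning("zero within-group variance: F is infinite")
        return {"F": np.inf, "df1": df1, "df2": df2, "p": 0.0, "msw": 0.0}
    F = (ss_b / df1) / (ss_w / df2)
    return {"F": float(F), "df1": int(df1), "df2": int(df2),
            "p": float(stats.f.sf(F, df1, df2)), "msw": float(ss_w / df2)}


def welch_anova_from_summary(summary: pd.DataFrame) -> dict:
    """Welch's heteroscedastic one-way ANOVA from per-group (n, mean, sd),
    with Welch-Satterthwaite fractional denominator df."""
    n, m, s = _as_summary(summary)
    if (s == 0).any():
        raise ValueError("Welch ANOVA requires positive group variances")
    k = len(n)
    w = n / s**2
    mw = (w * m).sum() / w.sum()
    a = ((1 / (n - 1)) * (1 - w / w.sum()) ** 2).sum()
    F = ((w * (m - mw) ** 2).sum() / (k - 1)) / (1 + 2 * (k - 2) / (k**2 - 1) * a)
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * a)
    return {"F": float(F), "df1": int(df1), "df2": float(df2),
            "p": float(stats.f.sf(F, df1, df2))}


def chisq_independence(table) -> dict:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    res = stats.chi2_contingency(obs, correction=False)
    return {"chi2": float(res.statistic), "df": int(res.dof), "p": float(res.pvalue)}


def tukey_kramer_from_summary(summary: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise comparisons by the studentized-range test with the
    Tukey-Kramer unequal-n standard error, from per-group (n, mean, sd).

    Returns one row per pair with q, p and a significance flag; the ANOVA
    MSW supplies the pooled error variance.
    """
    n, m, s = _as_summary(summary)
    k = len(n)
    labels = summary["group"].tolist() if "group" in summary else list(range(k))
    msw = oneway_anova_from_summary(summary)["msw"]
    df_w = n.sum() - k
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2 * (1 / n[i] + 1 / n[j]))
            q = abs(m[i] - m[j]) / se
            p = float(stats.studentized_range.sf(q, k, df_w))
            rows.append(
                {"group_a": labels[i], "group_b": labels[j], "diff": float(m[i] - m[j]),
                 "q": float(q), "p": p, "significant": p < alpha}
            )
    return pd.DataFrame(rows)


def levene_test(groups: list[np.ndarray], center: str = "median") -> dict:
    """Levene/Brown-Forsythe test of variance homogeneity on raw data
    (a one-way ANOVA on absolute deviations from the group center)."""
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    W, p = stats.levene(*groups, center=center)
    return {"W": float(W), "p": float(p)}


# ---------------------------------------------------------------------------
# 2 x 4 repeated-measures (mixed between-within) ANOVA

def rm_anova_2x4(bias: pd.DataFrame, allocations: pd.DataFrame) -> pd.DataFrame:
    """Mixed ANOVA on the bias index: four training groups between subjects,
    time (pre vs post) within. Participants missing either timepoint are
    dropped listwise and logged. With only two within levels sphericity
    holds trivially.

    Returns the pingouin mixed-ANOVA table (rows: group, time,
    group x time interaction).
    """
    df = bias.merge(allocations, on="participant_id")
    df["group"] = df["stimuli"].astype(str) + ":" + df["condition"].astype(str)
    counts = df.dropna(subset=["bias_index"]).groupby("participant_id")["timepoint"].nunique()
    complete = set(counts[counts == 2].index)
    dropped = set(df["participant_id"]) - complete
    if dropped:
        logger.warning("rm_anova_2x4: dropped %d participant(s) with incomplete pre/post pairs", len(dropped))
    df = df[df["participant_id"].isin(complete)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        table = pg.mixed_anova(
            data=df, dv="bias_index", within="timepoint", subject="participant_id", between="group"
        )
    return table


# ---------------------------------------------------------------------------
# linear mixed-effects model

MODEL_FORMULAS = {
    "full": "total ~ time * condition * stimuli",
    "main_effects": "total ~ time + condition + stimuli",
    "time_only": "total ~ time",
    "null": "total ~ 1",
}


@dataclass
class LmmResult:
    """A fitted mixed model: fixed-effect table, random-effect variances,
    likelihood and AIC, plus enough metadata for model comparison."""

    model_name: str
    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, df, t, p
    random_variances: dict[str, float]
    loglik: float
    k_params: int
    n_obs: int
    n_groups: int
    method: str  # ml | reml
    converged: bool
    singular: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params


def _containment_df(terms: list[str], n_obs: int, n_groups: int) -> dict[str, float]:
    """Denominator df per fixed-effect term under the containment convention:
    terms varying within participant (anything involving time) are tested
    against the residual stratum, purely between-participant terms against
    the participant stratum."""
    within = [t for t in terms if "time" in t]
    between = [t for t in terms if "time" not in t]
    df_within = n_obs - n_groups - len(within)
    df_between = n_groups - len(between)
    out = {t: float(df_within) for t in within}
    out.update({t: float(df_between) for t in between})
    return out


def fit_lmm(
    scores: pd.DataFrame,
    allocations: pd.DataFrame,
    model: str = "full",
    instrument: str = "LSAS-SR",
    method: str = "ml",
    random_slope: bool = True,
    df_method: str = "containment",
) -> LmmResult:
    """Fit the longitudinal mixed model for one instrument.

    `model` picks the fixed-effect structure ('full', 'main_effects',
    'time_only', 'null'); random effects are a per-participant intercept and
    (by default) a correlated time slope. ML is the default estimator so AIC
    and likelihood-ratio comparisons between fixed-effect structures are
    valid; REML is available for variance-component reporting. A singular
    random-effect covariance triggers an automatic refit with uncorrelated
    intercept and slope, recorded in `notes`.
    """
    if model not in MODEL_FORMULAS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_FORMULAS)}")
    panel = scores[scores["instrument"] == instrument]
    df = panel.merge(allocations, on="participant_id")
    df = df.rename(columns={"assessment": "time"})[
        ["participant_id", "time", "condition", "stimuli", "total"]
    ].dropna()
    reml = method == "reml"
    formula = MODEL_FORMULAS[model]
    notes: list[str] = []

    def _fit(re_formula, vc_formula):
        mod = smf.mixedlm(
            formula, df, groups=df["participant_id"], re_formula=re_formula, vc_formula=vc_formula
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mod.fit(reml=reml, method=["lbfgs", "cg", "powell"])

    res = _fit("~time" if random_slope else "1", None)
    singular = False
    if random_slope:
        cov_re = res.cov_re.to_numpy()
        eig = np.linalg.eigvalsh(cov_re)
        if eig.min() <= 1e-8 * max(eig.max(), 1.0):
            singular = True
            notes.append("singular random-effect covariance; refit with uncorrelated intercept and slope")
            logger.warning(notes[-1])
            res = _fit("1", {"time_slope": "0 + time"})
    if not res.converged:
        notes.append("optimizer did not report convergence; estimates may be unstable")
        logger.warning(notes[-1])

    fe = res.fe_params
    se = res.bse_fe
    terms = list(fe.index)
    n_obs = len(df)
    n_groups = df["participant_id"].nunique()
    if df_method == "containment":
        dfs = _containment_df(terms, n_obs, n_groups)
    else:
        dfs = {t: float(n_obs - len(terms)) for t in terms}
    tvals = fe / se
    pvals = {t: 2 * stats.t.sf(abs(tvals[t]), dfs[t]) for t in terms}
    table = pd.DataFrame(
        {
            "estimate": fe,
            "se": se,
            "df": pd.Series(dfs),
            "t": tvals,
            "p": pd.Series(pvals),
        }
    )

    rv = {"residual": float(res.scale)}
    if res.cov_re.size:
        names = list(res.cov_re.index)
        for i, a in enumerate(names):
            rv[f"var_{a}"] = float(res.cov_re.iloc[i, i])
        if len(names) == 2:
            rv["cov_intercept_slope"] = float(res.cov_re.iloc[0, 1])
    if res.k_vc:
        for name, v in zip(res.model.exog_vc.names, res.vcomp):
            rv[f"var_{name}"] = float(v)

    k_cov = res.k_re2 + res.k_vc  # random-effect covariance parameters
    k_params = len(terms) + k_cov + 1  # + residual variance
    return LmmResult(
        model_name=model,
        fixed_effects=table,
        random_variances=rv,
        loglik=float(res.llf),
        k_params=int(k_params),
        n_obs=n_obs,
        n_groups=n_groups,
        method=method,
        converged=bool(res.converged),
        singular=singular,
        notes=notes,
    )


def likelihood_ratio_test(full: LmmResult, reduced: LmmResult) -> dict:
    """LRT of two nested ML fits on the same observations."""
    if full.method != "ml" or reduced.method != "ml":
        raise ValueError("likelihood-ratio test requires ML fits")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fit on different observations")
    stat = 2.0 * (full.loglik - reduced.loglik)
    ddf = full.k_params - reduced.k_params
    if ddf <= 0:
        raise ValueError("'full' model must have more parameters than 'reduced'")
    return {"lr": float(stat), "df": int(ddf), "p": float(stats.chi2.sf(max(stat, 0.0), ddf))}


def nagelkerke_pseudo_r2(full: LmmResult, null: LmmResult, n_obs: int | None = None) -> float:
    """Nagelkerke's rescaled likelihood-ratio pseudo-r2 in [0, 1]:

        R2_CS = 1 - exp(2 (L0 - L1) / n);  R2_N = R2_CS / (1 - exp(2 L0 / n))

    where L0, L1 are the null and full log-likelihoods and n the number of
    observations entering the fit (configurable to participants instead).
    """
    if full.n_obs != null.n_obs:
        raise ValueError("models were fit on different observations")
    n = n_obs if n_obs is not None else full.n_obs
    l1, l0 = full.loglik, null.loglik
    if l1 < l0:
        warnings.warn("full model has lower likelihood than null; pseudo-r2 set to 0")
        return 0.0
    r2_cs = 1.0 - np.exp(2.0 * (l0 - l1) / n)
    denom = 1.0 - np.exp(2.0 * l0 / n)
    return float(r2_cs / denom)


def aic_compare(models: dict[str, LmmResult]) -> pd.DataFrame:
    """Rank models by AIC (= -2 logLik + 2 k), ascending. All fits must use
    the same estimator on the same observations; mixed REML/ML input is an
    error because those AICs are not comparable."""
    methods = {m.method for m in models.values()}
    if len(methods) > 1:
        raise ValueError("cannot compare AIC across REML and ML fits")
    n_obs = {m.n_obs for m in models.values()}
    if len(n_obs) > 1:
        raise ValueError("models were fit on different observations")
    rows = [
        {"model": name, "k": m.k_params, "loglik": m.loglik, "aic": m.aic}
        for name, m in models.items()
    ]
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["rank"] = out["aic"].rank(method="min").astype(int)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    return out
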
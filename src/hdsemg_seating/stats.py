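"""Chair-comparison statistics for region-of-activity RMS tables.

Implements the quantitative analysis of the crossover design: per-trial
percent changes between chairs, per-subject Wilcoxon signed-rank tests with
a Dunn (Bonferroni-type) family adjustment, the exact binomial sign
argument, a linear mixed model for RMS_ROA with chair and side as fixed
effects and subject/time as random factors, the centroid ANOVA, and the
correlation and normality helpers used to relate the EMG measures to the
questionnaire scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "percent_change_by_trial",
    "percent_change_table",
    "time_change",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "dunn_adjust",
    "sign_binomial_tail",
    "fit_rms_mixed_model",
    "centroid_anova",
    "spearman_corr",
    "pearson_corr",
    "ks_normality",
]


def percent_change_by_trial(rms_ss: float, rms_a: float) -> float:
    """Percent RMS_ROA change of the A-chair relative to the stool for one
    trial pair: 100 * (RMS_SS - RMS_A) / RMS_SS.  Positive values mean the
    A-chair produced lower activity."""
    if rms_ss <= 0:
        raise ValueError("stool RMS must be positive")
    return 100.0 * (rms_ss - rms_a) / rms_ss


def time_change(series: pd.Series | np.ndarray) -> float:
    """Signed percent change of an RMS series from its first to last trial:
    100 * (end - start) / start."""
    v = np.asarray(series, dtype=float)
    if v.size < 2 or not np.isfinite(v[[0, -1]]).all():
        raise ValueError("need the first and last trial values")
    if v[0] == 0:
        raise ValueError("starting value is zero")
    return 100.0 * (v[-1] - v[0]) / v[0]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p_two_sided: float
    p_one_sided: float  # alternative: differences are positive
    n_informative: int
    method: str


def _signed_rank_counts(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of twice the positive-rank sum over all sign patterns.

    ``ranks2`` are the doubled (hence integer, even with midranks) ranks of
    the absolute differences.  Returns counts[w] = number of the 2^n sign
    assignments whose doubled rank sum is w.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray | None = None, exact_limit: int = 25
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples (or on differences).

    Zero differences are dropped (Wilcoxon's original rule).  For up to
    ``exact_limit`` informative pairs the null distribution of the
    positive-rank sum is computed exactly (equivalent to enumerating all
    2^n sign assignments, midranks included); beyond that a normal
    approximation with tie correction and continuity correction is used.
    If every difference is zero the test is vacuous and p = 1 is returned
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; returning p = 1", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 1.0, 0, "degenerate")
    ranks = _sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_counts(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        p_ge = counts[w2:].sum() / total
        p_le = counts[: w2 + 1].sum() / total
        p_one = p_ge
        p_two = min(1.0, 2.0 * min(p_ge, p_le))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        sd = math.sqrt(var)
        z_ge = (w_plus - mean - 0.5) / sd
        z_le = (w_plus - mean + 0.5) / sd
        p_one = float(_sps.norm.sf(z_ge))
        p_two = float(min(1.0, 2.0 * min(_sps.norm.sf(z_ge), _sps.norm.cdf(z_le))))
        method = "normal-approx"
    return WilcoxonResult(w_plus, p_two, p_one, n, method)


def dunn_adjust(p_values: np.ndarray | list[float], family_size: int | None = None) -> np.ndarray:
    """Dunn's multiple-comparison adjustment (Bonferroni-type scaling):
    p_adj = min(1, m * p) with m the family size (defaults to the number of
    p-values supplied)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    return np.minimum(1.0, m * p)


def sign_binomial_tail(k: int, n: int) -> float:
    """Exact one-sided binomial tail P(X >= k | n, p = 1/2).

    This is the sign-test argument: the probability that at least k of n
    subjects show an effect in the same direction by chance alone.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    total = sum(math.comb(n, i) for i in range(k, n + 1))
    return total / 2**n


def percent_change_table(rms: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-subject chair comparison in the style of a crossover summary table.

    ``rms`` is a long table with columns (subject, chair, side, trial_index,
    rms_roa).  For every subject and side the per-trial percent changes
    100*(SS_i - A_i)/SS_i are averaged; the paired trials are compared with
    the exact Wilcoxon signed-rank test, and the p-values are Dunn-adjusted
    over the family of all (subject, side) tests.  The pooled rows report
    the mean over all subjects' trials per side.
    """
    required = {"subject", "chair", "side", "trial_index", "rms_roa"}
    if missing := required - set(rms.columns):
        raise ValueError(f"RMS table lacks columns {sorted(missing)}")
    if (rms["rms_roa"] <= 0).any():
        raise ValueError("rms_roa values must be positive")
    dup = rms.duplicated(["subject", "chair", "side", "trial_index"])
    if dup.any():
        raise ValueError("duplicate (subject, chair, side, trial) rows")

    rows = []
    for (subject, side), g in rms.groupby(["subject", "side"]):
        piv = g.pivot(index="trial_index", columns="chair", values="rms_roa")
        if not {"SS", "A"} <= set(piv.columns):
            continue
        piv = piv.dropna(subset=["SS", "A"])
        pct = 100.0 * (piv["SS"] - piv["A"]) / piv["SS"]
        res = wilcoxon_signed_rank(piv["SS"].to_numpy(), piv["A"].to_numpy())
        rows.append(
            {
                "subject": subject,
                "side": side,
                "n_trials": len(piv),
                "mean_pct_change": float(pct.mean()),
                "sd_pct_change": float(pct.std(ddof=1)),
                "wilcoxon_w": res.statistic,
                "p_value": res.p_two_sided,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no complete (subject, side) chair pairs found")
    table["p_dunn"] = dunn_adjust(table["p_value"].to_numpy())
    table["significant"] = (table["p_value"] < alpha) & (table["mean_pct_change"] > 0)

    pooled = []
    for side, g in rms.groupby("side"):
        piv = g.pivot(index=["subject", "trial_index"], columns="chair", values="rms_roa")
        piv = piv.dropna(subset=["SS", "A"]) if {"SS", "A"} <= set(piv.columns) else piv
        pct = 100.0 * (piv["SS"] - piv["A"]) / piv["SS"]
        pooled.append(
            {
                "subject": "Total",
                "side": side,
                "n_trials": len(piv),
                "mean_pct_change": float(pct.mean()),
                "sd_pct_change": float(pct.std(ddof=1)),
                "wilcoxon_w": np.nan,
                "p_value": np.nan,
                "p_dunn": np.nan,
                "significant": pd.NA,
            }
        )
    return pd.concat([table, pd.DataFrame(pooled)], ignore_index=True)


def fit_rms_mixed_model(rms: pd.DataFrame) -> dict:
    """Linear mixed model for RMS_ROA: chair and side as fixed effects,
    random intercepts for subject and a variance component for trial time.

    Returns Wald F (single-df, so F = z^2) and p for each fixed effect, a
    likelihood-ratio test of the subject random effect against the
    fixed-effects-only model, marginal/conditional R^2 and the residual SD.
    """
    for col in ("subject", "chair", "side", "time_min", "rms_roa"):
        if col not in rms.columns:
            raise ValueError(f"RMS table lacks column {col!r}")
    if rms["subject"].nunique() < 2:
        raise ValueError("mixed model needs at least two subjects")
    if rms["chair"].nunique() < 2 or rms["side"].nunique() < 2:
        raise ValueError("design is singular: both chairs and sides are required")
    df = rms.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "rms_roa ~ C(chair, Treatment('SS')) + C(side)",
            df,
            groups="subject",
            re_formula="1",
            vc_formula={"time": "0 + C(time_min)"},
        )
        res = model.fit(reml=True)
        ols = smf.ols("rms_roa ~ C(chair, Treatment('SS')) + C(side)", df).fit()
        lr = 2.0 * (
            model.fit(reml=False).llf - ols.llf
        )
    lr = max(lr, 0.0)
    # 50:50 mixture of chi2(0) and chi2(1) for a variance on the boundary
    p_subject = 0.5 * float(_sps.chi2.sf(lr, 1)) if lr > 0 else 1.0

    out: dict = {"fixed": {}, "subject_random_effect": {"lr_stat": float(lr), "p": p_subject}}
    names = {"chair": "C(chair, Treatment('SS'))[T.A]", "side": "C(side)[T.R]"}
    for term, coef_name in names.items():
        z = res.params[coef_name] / res.bse[coef_name]
        out["fixed"][term] = {
            "coef": float(res.params[coef_name]),
            "F": float(z**2),
            "p": float(2 * _sps.norm.sf(abs(z))),
        }
    var_fixed = float(np.var(res.predict(df)))
    var_subject = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
    var_time = float(sum(res.vcomp)) if len(res.vcomp) else 0.0
    var_resid = float(res.scale)
    denom = var_fixed + var_subject + var_time + var_resid
    out["r2_marginal"] = var_fixed / denom
    out["r2_conditional"] = (var_fixed + var_subject + var_time) / denom
    out["residual_sd"] = math.sqrt(var_resid)
    out["n_obs"] = int(len(df))
    return out


def centroid_anova(track: pd.DataFrame) -> dict:
    """Two-way ANOVA of the ROA centroid coordinates.

    One model per coordinate (x_cm_mm, y_cm_mm): chair and side are the
    factors of interest; subject and trial time enter as blocking factors
    absorbing the repeated-measures structure.  Returns F and p for chair
    and side per coordinate.
    """
    for col in ("subject", "chair", "side", "trial_index", "x_cm_mm", "y_cm_mm"):
        if col not in track.columns:
            raise ValueError(f"centroid table lacks column {col!r}")
    cells = track.groupby(["chair", "side"]).size()
    if len(cells) < 4:
        raise ValueError("incomplete factorial design: need both chairs on both sides")
    out = {}
    for coord in ("x_cm_mm", "y_cm_mm"):
        model = smf.ols(
            f"{coord} ~ C(chair) + C(side) + C(subject) + C(trial_index)", data=track
        ).fit()
        tbl = anova_lm(model, typ=2)
        out[coord] = {
            "chair": {"F": float(tbl.loc["C(chair)", "F"]), "p": float(tbl.loc["C(chair)", "PR(>F)"])},
            "side": {"F": float(tbl.loc["C(side)", "F"]), "p": float(tbl.loc["C(side)", "PR(>F)"])},
        }
    return out


def _fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    if n < 4 or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = _sps.norm.ppf(0.5 + conf / 2)
    return (math.tanh(z - crit * se), math.tanh(z + crit * se))


def spearman_corr(x: np.ndarray, y: np.ndarray) -> dict:
    """Spearman rank correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no rank correlation")
    rho, p = _sps.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "ci95": _fisher_ci(float(rho), x.size)}


def pearson_corr(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson correlation with its exact confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no correlation")
    res = _sps.pearsonr(x, y)
    ci = res.confidence_interval()
    return {"r": float(res.statistic), "p": float(res.pvalue), "ci95": (float(ci.low), float(ci.high))}


def ks_normality(x: np.ndarray) -> dict:
    """Kolmogorov-Smirnov normality check with estimated mean/SD
    (Lilliefors correction for the estimated parameters)."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    d, p = lilliefors(x, dist="norm")
    return {"D": float(d), "p": float(p)}
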
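"""Scoring and comparison of the comfort/discomfort instruments.

Three questionnaire families are supported, each completed once per
subject-session (chair):

* **GCR** -- General Comfort Rating, a single 1-10 score from 1 "relaxed"
  to 10 "in pain"; compared between chairs with a one-way ANOVA and
  summarized by the per-chair modal score.
* **HZc / HZd** -- Helander-Zhang comfort (7 statements) and discomfort
  (9 statements), each rated 1 "do not agree" to 10 "totally agree";
  compared per statement with paired t-tests, and summarized as a
  min-max-normalized percentage of the subscale sum.
* **BPD** -- Body Part Discomfort: 10 body parts each rated 0 "no pain or
  discomfort" to 10 "extreme pain or agony"; compared between chairs with
  a mixed model treating body part as a random factor.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sps
import statsmodels.formula.api as smf

__all__ = [
    "GCR_LABELS",
    "BPD_BODY_PARTS",
    "QuestionnaireSet",
    "score_gcr",
    "hz_item_test",
    "hz_percent",
    "bpd_compare",
]

GCR_LABELS = {
    1: "relaxed",
    2: "comfortable",
    3: "quite comfortable",
    4: "not very comfortable",
    5: "uncomfortable",
    6: "restless",
    7: "tight",
    8: "stiff",
    9: "numb",
    10: "in pain",
}

#: Default body-part vocabulary for the BPD scale.  The instrument covers 10
#: regions relevant to seated playing; this particular list is a package
#: choice and can be replaced via configuration.
BPD_BODY_PARTS = (
    "neck",
    "shoulders",
    "upper back",
    "lower back",
    "buttocks",
    "thighs",
    "knees",
    "lower legs",
    "arms",
    "wrists/hands",
)

N_HZC_ITEMS = 7
N_HZD_ITEMS = 9


def _check_range(values, lo: int, hi: int, what: str) -> np.ndarray:
    v = np.asarray(values)
    if v.size == 0:
        raise ValueError(f"{what}: empty responses")
    if np.any((v < lo) | (v > hi)):
        raise ValueError(f"{what}: scores must lie in [{lo}, {hi}]")
    return v.astype(float)


@dataclass
class QuestionnaireSet:
    """One subject-session's responses across all four instruments."""

    subject_id: int
    chair: str
    gcr: int
    hzc: dict[str, int]
    hzd: dict[str, int]
    bpd: dict[str, int]

    def __post_init__(self) -> None:
        _check_range([self.gcr], 1, 10, "GCR")
        if len(self.hzc) != N_HZC_ITEMS:
            raise ValueError(f"HZc needs {N_HZC_ITEMS} statements, got {len(self.hzc)}")
        if len(self.hzd) != N_HZD_ITEMS:
            raise ValueError(f"HZd needs {N_HZD_ITEMS} statements, got {len(self.hzd)}")
        if len(self.bpd) != len(BPD_BODY_PARTS):
            raise ValueError(f"BPD needs {len(BPD_BODY_PARTS)} body parts, got {len(self.bpd)}")
        _check_range(list(self.hzc.values()), 1, 10, "HZc")
        _check_range(list(self.hzd.values()), 1, 10, "HZd")
        _check_range(list(self.bpd.values()), 0, 10, "BPD")


def score_gcr(scores_by_chair: dict[str, np.ndarray]) -> dict:
    """Per-chair modal General Comfort Rating with its label, plus a
    one-way ANOVA across chairs treating the scores as continuous."""
    if len(scores_by_chair) < 2:
        raise ValueError("need scores for at least two chairs")
    cleaned = {
        chair: _check_range(v, 1, 10, f"GCR[{chair}]") for chair, v in scores_by_chair.items()
    }
    for chair, v in cleaned.items():
        if v.size < 2:
            raise ValueError(f"need at least 2 subjects per chair (chair {chair})")
    modes = {
        chair: int(_sps.mode(v.astype(int), keepdims=False).mode) for chair, v in cleaned.items()
    }
    f, p = _sps.f_oneway(*cleaned.values())
    return {
        "mode": modes,
        "mode_label": {c: GCR_LABELS[m] for c, m in modes.items()},
        "anova_F": float(f),
        "anova_p": float(p),
    }


def hz_item_test(a_scores: np.ndarray, ss_scores: np.ndarray) -> dict:
    """Paired t-test of one Helander-Zhang statement between chairs.

    ``mean_decrease`` is mean(A) - mean(SS): positive when the statement was
    endorsed more strongly on the A-chair.  The 95% CI reported is for
    mean(SS) - mean(A), matching the convention in which a positive
    decrease corresponds to a negative interval.
    """
    a = _check_range(a_scores, 1, 10, "HZ (A-chair)")
    s = _check_range(ss_scores, 1, 10, "HZ (stool)")
    if a.size != s.size:
        raise ValueError("paired scores must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired responses")
    mean_decrease = float(a.mean() - s.mean())
    d = s - a
    if np.ptp(d) == 0:
        t, p = (0.0, 1.0) if d[0] == 0 else (np.inf * np.sign(d[0]), 0.0)
        ci = (float(d[0]), float(d[0]))
    else:
        res = _sps.ttest_rel(s, a)
        t, p = float(res.statistic), float(res.pvalue)
        lo, hi = res.confidence_interval()
        ci = (float(lo), float(hi))
    return {"mean_decrease": mean_decrease, "t": t, "p": p, "ci95": ci}


def hz_percent(scores: np.ndarray, n_items: int | None = None) -> float:
    """Min-max normalized subscale percentage.

    With items rated 1..10, the subscale sum is mapped affinely to 0-100%:
    100 * (sum - n_items) / (9 * n_items).  All-minimum responses give 0%,
    all-maximum 100%.
    """
    v = _check_range(scores, 1, 10, "HZ subscale")
    n = v.size if n_items is None else n_items
    if v.size != n:
        raise ValueError(f"expected {n} items, got {v.size}")
    return float(100.0 * (v.sum() - n) / (9.0 * n))


def bpd_compare(bpd: pd.DataFrame) -> dict:
    """Chair comparison of Body Part Discomfort scores.

    ``bpd`` is long-format with columns (subject, chair, item, score), one
    row per body part.  A linear mixed model with chair as the fixed effect
    and body part as the random grouping factor yields the chair-effect
    test; the per-part chair mean differences (SS - A) are reported
    alongside.
    """
    for col in ("subject", "chair", "item", "score"):
        if col not in bpd.columns:
            raise ValueError(f"BPD table lacks column {col!r}")
    _check_range(bpd["score"].to_numpy(), 0, 10, "BPD")
    counts = bpd.groupby(["subject", "chair"])["item"].nunique()
    if counts.nunique() != 1:
        raise ValueError("every subject-session must score the same body parts")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "score ~ C(chair, Treatment('SS'))", bpd, groups="item", re_formula="1"
        )
        res = model.fit(reml=True)
    coef_name = "C(chair, Treatment('SS'))[T.A]"
    z = res.params[coef_name] / res.bse[coef_name]
    per_part = (
        bpd.pivot_table(index="item", columns="chair", values="score", aggfunc="mean")
        .assign(difference=lambda t: t["SS"] - t["A"])
    )
    return {
        "chair_coef": float(res.params[coef_name]),
        "chair_p": float(2 * _sps.norm.sf(abs(z))),
        "mean_difference": float(per_part["difference"].mean()),
        "per_part_means": per_part,
    }
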
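"""Cohort-level diagnostic statistics for preterm-birth prediction.

Covers the analysis-set accounting, two-sample t-tests from summary
statistics, the empirical (Mann-Whitney) AUC with DeLong confidence
intervals, and sensitivity/specificity at the elasticity cutoff with exact
Clopper-Pearson binomial intervals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .cohortgen import (DEVELOPMENT, EXCLUDED_LOST, EXCLUDED_NO_SHOW,
                        EXCLUDED_OPERATOR, INDICATED, SPTB, TERM)


class StatsError(ValueError):
    pass


class AccountingError(ValueError):
    """Cohort accounting fields do not sum consistently."""


# ---------------------------------------------------------------- analysis set

def filter_analysis_set(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Reduce the enrolled cohort to the sPTB/term analysis set.

    Removes non-attenders, lost-to-follow-up, operator-error recordings,
    development-phase subjects and indicated-preterm births. Returns the
    analysis subjects together with an enrolled-to-analyzed accounting report
    and raises if the category counts do not add up.
    """
    if "group" not in cohort.columns:
        raise StatsError("cohort table lacks a 'group' column")
    counts = cohort["group"].value_counts().to_dict()
    known = {SPTB, TERM, INDICATED, DEVELOPMENT,
             EXCLUDED_NO_SHOW, EXCLUDED_LOST, EXCLUDED_OPERATOR}
    unknown = set(counts) - known
    if unknown:
        raise StatsError(f"unknown group labels: {sorted(unknown)}")
    accounting = {
        "enrolled": len(cohort),
        "excluded_no_show": counts.get(EXCLUDED_NO_SHOW, 0),
        "excluded_lost_followup": counts.get(EXCLUDED_LOST, 0),
        "excluded_operator_error": counts.get(EXCLUDED_OPERATOR, 0),
        "development_phase": counts.get(DEVELOPMENT, 0),
        "validation": counts.get(SPTB, 0) + counts.get(TERM, 0) + counts.get(INDICATED, 0),
        "indicated_preterm": counts.get(INDICATED, 0),
        "sptb": counts.get(SPTB, 0),
        "term": counts.get(TERM, 0),
    }
    accounting["analyzed"] = accounting["sptb"] + accounting["term"]
    total = (accounting["excluded_no_show"] + accounting["excluded_lost_followup"]
             + accounting["excluded_operator_error"] + accounting["development_phase"]
             + accounting["validation"])
    if total != accounting["enrolled"]:
        raise AccountingError(
            f"accounting categories sum to {total}, expected {accounting['enrolled']}")
    analysis = cohort[cohort["group"].isin([SPTB, TERM])].reset_index(drop=True)
    if len(analysis) != accounting["analyzed"]:
        raise AccountingError("analysis subset size disagrees with accounting")
    return analysis, accounting


# ---------------------------------------------------------------- t-tests

@dataclass(frozen=True)
class GroupComparison:
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    method: str


def pooled_t_test(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int,
                  method: str = "pooled") -> GroupComparison:
    """Two-sample t-test from summary statistics.

    ``method="pooled"`` is the classic equal-variance Student t with
    ``df = n1 + n2 - 2``; ``method="welch"`` uses the Welch-Satterthwaite
    correction. Identical groups with zero variance give ``t=0, p=1``; zero
    variance with unequal means is undefined and raises.
    """
    if n1 < 2 or n2 < 2:
        raise StatsError("each group needs at least two observations")
    if s1 < 0 or s2 < 0:
        raise StatsError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            df = n1 + n2 - 2 if method == "pooled" else float("nan")
            return GroupComparison(m1, s1, n1, m2, s2, n2, 0.0, df, 1.0, method)
        raise StatsError("zero variance with unequal means: t undefined")
    if method == "pooled":
        t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
        df = float(n1 + n2 - 2)
    elif method == "welch":
        t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(m1, s1, n1, m2, s2, n2, float(t), float(df), float(p), method)


# ---------------------------------------------------------------- ROC / AUC

def _check_binary(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise StatsError("scores and labels must be equal-length 1-D arrays")
    if labels.all() or not labels.any():
        raise StatsError("both classes must be present")
    return scores, labels


def empirical_auc(scores, labels) -> float:
    """Empirical AUC (Mann-Whitney pair counting; ties count one half).

    ``labels`` marks the positive class (sPTB); scores must be oriented so
    that higher values indicate the positive class — pass negated elasticity.
    """
    scores, labels = _check_binary(np.asarray(scores), np.asarray(labels))
    return float(roc_auc_score(labels, scores))


@dataclass(frozen=True)
class DeLongResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_value_vs_chance: float
    alpha: float
    degenerate: bool


def delong_ci(scores, labels, alpha: float = 0.05) -> DeLongResult:
    """DeLong variance and Wald CI for the empirical AUC.

    Structural components: for each positive, the mean of the Mann-Whitney
    kernel against all negatives (and vice versa); the AUC variance is
    ``var(V10)/m + var(V01)/n``. The CI is clipped to [0, 1]; the p-value
    tests AUC = 0.5 under the same normal approximation. Perfectly separated
    data has zero estimated variance and is returned with a degeneracy flag.
    """
    scores, labels = _check_binary(np.asarray(scores), np.asarray(labels))
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) < 2 or len(neg) < 2:
        raise StatsError("DeLong variance needs at least two cases per class")
    # Mann-Whitney kernel matrix psi(x_i, y_j)
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # one structural component per positive
    v01 = psi.mean(axis=0)  # one per negative
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    se = float(np.sqrt(var))
    degenerate = se == 0.0
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    ci_low = float(np.clip(auc - z * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + z * se, 0.0, 1.0))
    if degenerate:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    return DeLongResult(auc, se, ci_low, ci_high, p, alpha, degenerate)


# ---------------------------------------------------------------- cutoff metrics

@dataclass(frozen=True)
class CutoffResult:
    cutoff_kpa_mm: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    tp: int
    fn: int
    tn: int
    fp: int


def sens_spec_at_cutoff(elasticities, labels, cutoff: float = 1.0,
                        alpha: float = 0.05) -> CutoffResult:
    """Sensitivity/specificity of the rule "predict sPTB when E < cutoff".

    The inequality is strict: an elasticity exactly at the cutoff is
    classified negative. Confidence intervals are exact binomial
    (Clopper-Pearson).
    """
    elasticities, labels = _check_binary(np.asarray(elasticities), np.asarray(labels))
    predicted = elasticities < cutoff
    tp = int(np.count_nonzero(predicted & labels))
    fn = int(np.count_nonzero(~predicted & labels))
    tn = int(np.count_nonzero(~predicted & ~labels))
    fp = int(np.count_nonzero(predicted & ~labels))

    def exact_ci(k: int, n: int) -> tuple[float, float]:
        ci = sps.binomtest(k, n).proportion_ci(confidence_level=1 - alpha, method="exact")
        return (float(ci.low), float(ci.high))

    return CutoffResult(
        cutoff_kpa_mm=float(cutoff),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        sens_ci=exact_ci(tp, tp + fn),
        spec_ci=exact_ci(tn, tn + fp),
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


# ---------------------------------------------------------------- group table

#: (row label, column stem, kind) — mirrors the printed characteristics table.
CHARACTERISTICS_ROWS = [
    ("Maternal age, years", "maternal_age_years", "continuous"),
    ("Height, cm", "height_cm", "continuous"),
    ("Weight, kg", "weight_kg", "continuous"),
    ("Parous women", "parity", "count"),
    ("Prior history of PTB", "prior_ptb", "count"),
    ("Gestational age at CM examination, days", "ga_exam_days", "continuous"),
    ("Gestational age at birth, days", "ga_birth_days", "continuous"),
    ("Anterior cervical length, mm", "length_anterior_mm", "continuous"),
    ("Posterior cervical length, mm", "length_posterior_mm", "continuous"),
    ("Average cervical length, mm", "length_avg_mm", "continuous"),
    ("Anterior cervical elasticity, kPa/mm", "elasticity_anterior_kpa_mm", "continuous"),
    ("Posterior cervical elasticity, kPa/mm", "elasticity_posterior_kpa_mm", "continuous"),
    ("Average cervical elasticity, kPa/mm", "elasticity_avg_kpa_mm", "continuous"),
]


def summarize_characteristics(analysis: pd.DataFrame, method: str = "pooled") -> pd.DataFrame:
    """Group means +- SD and pooled t-test p-values, one row per characteristic.

    Count variables (parity, prior preterm birth) are reported as counts with
    no test, matching the printed table. Characteristics absent from the
    input are listed with a note instead of failing.
    """
    groups = {name: analysis[analysis["group"] == name] for name in (SPTB, TERM)}
    if any(len(g) < 2 for g in groups.values()):
        raise StatsError("need at least two subjects per group")
    rows = []
    for label, col, kind in CHARACTERISTICS_ROWS:
        if col not in analysis.columns:
            rows.append({"characteristic": label, "note": "missing"})
            continue
        a = groups[SPTB][col].dropna().astype(float)
        b = groups[TERM][col].dropna().astype(float)
        if kind == "count":
            rows.append({
                "characteristic": label,
                "preterm": f"{int(a.sum())} ({100 * a.mean():.0f}%)",
                "term": f"{int(b.sum())} ({100 * b.mean():.0f}%)",
                "p_value": np.nan,
            })
        else:
            cmp = pooled_t_test(a.mean(), a.std(ddof=1), len(a),
                                b.mean(), b.std(ddof=1), len(b), method=method)
            rows.append({
                "characteristic": label,
                "preterm": f"{a.mean():.2f} +- {a.std(ddof=1):.2f}",
                "term": f"{b.mean():.2f} +- {b.std(ddof=1):.2f}",
                "p_value": cmp.p_value,
            })
    return pd.DataFrame(rows)
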
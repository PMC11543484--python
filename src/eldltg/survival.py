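"""Survival and discrimination battery for lipid markers.

Implements the comparison design used to rank candidate risk markers
in a prospective cohort: Kaplan-Meier curves over marker quantile
strata compared with the Gehan-Breslow generalized Wilcoxon chi-square
(weights = number at risk, which emphasizes early events), Cox
proportional-hazards hazard ratios (per 1-SD of a standardized marker
or per threshold indicator, unadjusted or covariate-adjusted, Efron
tie handling, Wald 95% CIs on the log-HR scale), and single-marker
ROC AUC against the event indicator.

Estimation is delegated to lifelines (Kaplan-Meier, weighted k-sample
tests, Cox PH) and scikit-learn (AUC); this module fixes the designs
and the reporting surface.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import roc_auc_score

from .classification import quantile_strata

#: Covariate presets used for adjusted hazard-ratio models: the
#: guideline-style nonlipid set, and the same plus BMI.
ADJUSTMENT_GUIDELINE = ("age", "sex", "race", "sbp", "bp_treated", "diabetes", "smoker")
ADJUSTMENT_GUIDELINE_BMI = ADJUSTMENT_GUIDELINE + ("bmi",)


@dataclass
class WilcoxonResult:
    chisq: float
    df: int
    p_value: float


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve; columns ``time`` and ``survival``.

    Right censoring is handled; the curve starts at S(0) = 1. A sample
    with no events yields a flat curve at 1 and a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if not events.any():
        warnings.warn("no events: survival curve is identically 1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def wilcoxon_chisq(times, events, groups) -> WilcoxonResult:
    """Gehan-Breslow generalized Wilcoxon k-sample test.

    Weights each event time by the number at risk, so differences in
    early survival count more than late ones. Returns the chi-square
    statistic with k-1 degrees of freedom.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 strata")
    if (counts == 0).any():
        raise ValueError("empty stratum")
    res = multivariate_logrank_test(times, groups, events, weightings="wilcoxon")
    return WilcoxonResult(
        chisq=float(res.test_statistic), df=int(labels.size - 1),
        p_value=float(res.p_value),
    )


def cox_fit(
    df: pd.DataFrame,
    duration_col: str = "follow_up",
    event_col: str = "event",
    covariates: tuple[str, ...] | list[str] = (),
    standardize: tuple[str, ...] | list[str] = (),
) -> pd.DataFrame:
    """Cox proportional-hazards HRs with Wald 95% CIs.

    ``standardize`` lists covariates to z-score first, so their hazard
    ratios read per 1-SD. Categorical covariates (e.g. sex, race) are
    dummy-coded. Efron tie handling. Warns when events < 10 per
    covariate. Returns a table indexed by covariate with columns
    ``coef, hr, ci_lower, ci_upper, se, p``.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    work = df[[duration_col, event_col] + covariates].copy()
    work[event_col] = work[event_col].astype(int)
    for c in standardize:
        v = work[c].astype(float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"covariate {c} is constant; cannot standardize")
        work[c] = (v - v.mean()) / sd
    cat = [c for c in covariates if work[c].dtype == object or work[c].dtype.name == "category"]
    if cat:
        work = pd.get_dummies(work, columns=cat, drop_first=True, dtype=float)
    n_events = int(work[event_col].sum())
    n_cov = work.shape[1] - 2
    if n_events < 10 * n_cov:
        warnings.warn(
            f"only {n_events} events for {n_cov} covariates; estimates may be unstable"
        )
    cph = CoxPHFitter()
    cph.fit(work, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )


def roc_auc(marker, outcome) -> float:
    """Area under the ROC curve of a single marker against the event
    indicator; equals the Mann-Whitney concordance (ties count half)."""
    marker = np.asarray(marker, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if np.unique(outcome).size < 2:
        raise ValueError("both outcome classes must be present")
    return float(roc_auc_score(outcome, marker))


def marker_battery(
    df: pd.DataFrame,
    markers: list[str],
    duration_col: str = "follow_up",
    event_col: str = "event",
    k: int = 5,
) -> pd.DataFrame:
    """Per-marker quantile-strata Wilcoxon chi-square and ROC AUC,
    ranked by chi-square.

    Reproduces the marker-comparison design on any cohort: each marker
    is cut into k quantile strata (default quintiles), survival across
    strata is tested with the generalized Wilcoxon, and the marker's
    single-variable AUC against the event indicator is reported. A
    failing marker gets NaNs and an ``error`` note rather than
    aborting the battery.
    """
    rows = []
    for m in markers:
        row: dict = {"marker": m}
        try:
            sub = df[[m, duration_col, event_col]].dropna()
            labels, _ = quantile_strata(sub[m].to_numpy(), k)
            w = wilcoxon_chisq(
                sub[duration_col].to_numpy(), sub[event_col].to_numpy(), labels
            )
            row.update(wilcoxon_chisq=w.chisq, df=w.df, p=w.p_value)
            row["auc"] = roc_auc(sub[m].to_numpy(), sub[event_col].to_numpy())
        except Exception as exc:  # propagate per-marker failure as data
            row.update(wilcoxon_chisq=np.nan, auc=np.nan, error=str(exc))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("marker")
    return out.sort_values("wilcoxon_chisq", ascending=False)
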
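"""Survival association of editing sites.

Each site's editing levels are dichotomized at the median across all
samples with survival data; the over-editing group (strictly above the
median) is compared with the under-editing group by a univariate Cox
proportional-hazards model (Efron tie handling) and a log-rank test.
A site is prognosis-related when the log-rank p < 0.05, and its risk
direction is called *consistent* when it matches the site's resistance
direction: over-editing DESs should be risk factors (HR > 1), and
under-editing DESs protective (HR < 1), if editing mediates resistance
and resistance worsens outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

log = logging.getLogger(__name__)


@dataclass
class SurvivalResult:
    site_id: str
    hr: float  # hazard ratio, over-editing vs under-editing group
    cox_p: float  # Wald p for the group coefficient
    logrank_p: float
    n_over: int
    n_under: int
    converged: bool = True  # False when the fit needed a ridge penalty


def binarize_by_median(levels: pd.Series) -> pd.Series:
    """Split samples into over/under-editing groups at the median.

    Values strictly above the median form the over-editing group; values
    at or below it go to the under-editing group, so ties at the median
    are resolved deterministically. Missing values are excluded. A
    constant vector cannot be split and raises.
    """
    vals = levels.dropna()
    if len(vals) < 2:
        raise ValueError("need >= 2 non-missing values to binarize")
    if vals.nunique() == 1:
        raise ValueError("all editing levels identical: no median split possible")
    med = vals.median()
    groups = pd.Series(np.where(vals > med, "over", "under"), index=vals.index)
    if (groups == "over").sum() == 0:
        raise ValueError("median split produced an empty over-editing group")
    return groups


def cox_univariate(groups: pd.Series, survival: pd.DataFrame,
                   site_id: str = "") -> SurvivalResult:
    """Univariate Cox regression of survival on the over-editing indicator.

    ``groups`` maps sample -> {"over", "under"}; ``survival`` has
    columns (sample, time, event). HR = exp(coefficient) of the
    over-editing indicator. The log-rank p between the two groups is
    reported alongside the Wald p. With complete separation the fit is
    retried with a small ridge penalty and flagged.
    """
    surv = survival.set_index("sample")
    shared = groups.index.intersection(surv.index)
    df = pd.DataFrame(
        {
            "time": surv.loc[shared, "time"].astype(float),
            "event": surv.loc[shared, "event"].astype(int),
            "over": (groups.loc[shared] == "over").astype(int),
        }
    )
    n_over = int(df["over"].sum())
    n_under = int(len(df) - n_over)
    if n_over == 0 or n_under == 0:
        raise ValueError("both editing groups must be nonempty")
    if df["event"].sum() == 0:
        raise ValueError("no events observed: Cox model is unidentifiable")
    converged = True
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError:
            log.warning("cox_univariate: separation for %s, refitting with ridge", site_id)
            converged = False
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["over"]))
    cox_p = float(cph.summary.loc["over", "p"])
    over = df[df["over"] == 1]
    under = df[df["over"] == 0]
    lr = logrank_test(
        over["time"], under["time"],
        event_observed_A=over["event"], event_observed_B=under["event"],
    )
    return SurvivalResult(
        site_id=site_id, hr=hr, cox_p=cox_p, logrank_p=float(lr.p_value),
        n_over=n_over, n_under=n_under, converged=converged,
    )


def site_survival_scan(
    profile_levels: pd.DataFrame, survival: pd.DataFrame, sites: list[str] | None = None
) -> pd.DataFrame:
    """Run the median-split Cox/log-rank analysis for every site.

    Sites whose levels cannot be split (constant, too few values) are
    skipped with a log line. Binarization uses all samples with survival
    data, not only a condition's labeled samples.
    """
    if sites is None:
        sites = list(profile_levels.index)
    samples = [s for s in profile_levels.columns if s in set(survival["sample"])]
    rows = []
    for site in sites:
        try:
            groups = binarize_by_median(profile_levels.loc[site, samples])
            res = cox_univariate(groups, survival, site_id=site)
        except ValueError as exc:
            log.info("site_survival_scan: skipped %s (%s)", site, exc)
            continue
        rows.append(
            (site, res.hr, res.cox_p, res.logrank_p, res.n_over, res.n_under,
             res.converged)
        )
    return pd.DataFrame(
        rows,
        columns=["site_id", "hr", "cox_p", "logrank_p", "n_over", "n_under", "converged"],
    ).set_index("site_id")


def consistency_with_resistance(
    survival_results: pd.DataFrame, des_records: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, float]:
    """Flag sites whose risk direction matches their resistance direction.

    Consistent means (direction == "over" and HR > 1) or
    (direction == "under" and HR < 1). Sites with HR exactly 1 are
    indeterminate and excluded from the proportion, which is computed
    over prognosis-related sites only (log-rank p < ``alpha``).
    Returns the flag table and the consistent fraction.
    """
    shared = survival_results.index.intersection(des_records.index)
    out = survival_results.loc[shared, ["hr", "logrank_p"]].copy()
    out["direction"] = des_records.loc[shared, "direction"]
    hr = out["hr"]
    out["consistent"] = (
        ((out["direction"] == "over") & (hr > 1))
        | ((out["direction"] == "under") & (hr < 1))
    ).astype("boolean")
    out.loc[hr == 1, "consistent"] = pd.NA
    prognostic = out[(out["logrank_p"] < alpha) & out["consistent"].notna()]
    proportion = float(prognostic["consistent"].mean()) if len(prognostic) else float("nan")
    return out, proportion
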
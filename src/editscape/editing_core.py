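"""Core editing-level statistics.

Overall editing levels (OEL), their regression on ADAR-like expression,
differential editing-site (DES) calling between resistant and sensitive
samples, over/under-editing pattern summaries, rank-based differential
expression and the Meet/Min (Simpson) overlap index.

A DES is a site with a two-sided Wilcoxon rank-sum p < 0.05 and an
absolute group-mean difference |Diff| >= 5%, where
Diff = mean(resistant) - mean(sensitive). "Over-editing" means Diff > 0
(higher editing in resistant samples).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Condition, EditingProfile

log = logging.getLogger(__name__)


@dataclass
class OELResult:
    """Per-sample overall editing level; optionally split by region."""

    overall: pd.Series  # sample -> mean editing level over non-missing sites
    by_region: pd.DataFrame | None = None  # region x sample


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


@dataclass
class PatternSummary:
    """Per-condition over/under-editing split and its ADAR relationship."""

    table: pd.DataFrame  # condition, n_over, n_under, prop_over, adar_log2fc
    regression: RegressionResult | None  # prop_over ~ adar_log2fc across conditions


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum wrapper


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``mode`` is "exact", "asymptotic" or "auto". Auto uses the exact null
    distribution when both groups have <= 25 observations and the pooled
    values carry no ties, and otherwise the normal approximation with
    continuity and tie correction — the default behaviour of standard
    statistical environments. p-values near the 0.05 cut can flip between
    modes, so the choice is explicit and logged at debug level.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # no information: identical constant groups
    if mode == "auto":
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown Wilcoxon mode: {mode!r}")
    log.debug("wilcoxon_rank_sum: method=%s n=(%d,%d)", method, len(x), len(y))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# OEL


def compute_oel(
    profile: EditingProfile, annotation: pd.DataFrame | None = None
) -> OELResult:
    """Per-sample mean editing level over non-missing sites.

    Samples with no non-missing values are omitted (with a warning), not
    reported as zero. With an annotation, per-region means are computed
    over each region's sites as well.
    """
    levels = profile.levels
    if levels.empty:
        raise ValueError("empty editing profile")
    counts = levels.notna().sum(axis=0)
    empty = counts[counts == 0].index
    if len(empty):
        log.warning("compute_oel: %d samples with no observed sites omitted", len(empty))
    overall = levels.mean(axis=0, skipna=True).drop(index=empty)
    by_region = None
    if annotation is not None:
        regions = annotation.loc[levels.index, "region"]
        rows = {}
        for region, sites in levels.groupby(regions.values):
            rows[region] = sites.mean(axis=0, skipna=True)
        by_region = pd.DataFrame(rows).T.drop(columns=empty, errors="ignore")
    return OELResult(overall=overall, by_region=by_region)


def regress_oel_on_expression(
    oel: pd.Series, expression: pd.Series
) -> RegressionResult:
    """OLS of OEL on expression over shared samples; returns R2 and F-test p."""
    shared = oel.index.intersection(expression.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 paired samples, got {len(shared)}")
    x = expression.loc[shared].to_numpy(dtype=float)
    y = oel.loc[shared].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError("constant regressor: R^2 undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=len(shared),
    )


def compare_oel_groups(
    oel: OELResult, condition: Condition, mode: str = "auto"
) -> float:
    """Two-sided Wilcoxon rank-sum p for resistant vs sensitive OELs."""
    res = oel.overall.loc[oel.overall.index.intersection(condition.resistant)]
    sen = oel.overall.loc[oel.overall.index.intersection(condition.sensitive)]
    if res.empty or sen.empty:
        raise ValueError("both groups need at least one sample with an OEL")
    return wilcoxon_rank_sum(res.to_numpy(), sen.to_numpy(), mode=mode)


# ---------------------------------------------------------------------------
# DES calling


def find_informative_sites(
    profile: EditingProfile, condition: Condition, min_per_group: int = 3
) -> list[str]:
    """Sites with >= ``min_per_group`` non-missing values in each group."""
    levels = profile.levels
    res_cols = [s for s in levels.columns if s in condition.resistant]
    sen_cols = [s for s in levels.columns if s in condition.sensitive]
    n_res = levels[res_cols].notna().sum(axis=1)
    n_sen = levels[sen_cols].notna().sum(axis=1)
    keep = (n_res >= min_per_group) & (n_sen >= min_per_group)
    return list(levels.index[keep])


def call_des(
    profile: EditingProfile,
    condition: Condition,
    alpha: float = 0.05,
    min_diff: float = 0.05,
    min_per_group: int = 3,
    mode: str = "auto",
    sites: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call differential editing sites for one condition.

    Returns ``(des, full)``: ``full`` holds every informative site with
    its p, Diff, group counts and BH-adjusted q (for volcano plots and
    transparency); ``des`` is the subset with p < ``alpha`` and
    |Diff| >= ``min_diff``, with a direction column ("over" if Diff > 0).
    The BH q-value is reported but never used for filtering.
    """
    if sites is None:
        sites = find_informative_sites(profile, condition, min_per_group)
    sites = list(sites)
    levels = profile.levels
    res_cols = [s for s in levels.columns if s in condition.resistant]
    sen_cols = [s for s in levels.columns if s in condition.sensitive]
    rows = []
    for site in sites:
        res_vals = levels.loc[site, res_cols].dropna().to_numpy(dtype=float)
        sen_vals = levels.loc[site, sen_cols].dropna().to_numpy(dtype=float)
        p = wilcoxon_rank_sum(res_vals, sen_vals, mode=mode)
        diff = float(res_vals.mean() - sen_vals.mean())
        rows.append((site, p, diff, len(res_vals), len(sen_vals)))
    full = pd.DataFrame(rows, columns=["site_id", "p", "diff", "n_res", "n_sen"])
    if len(full):
        full["bh_q"] = stats.false_discovery_control(full["p"].to_numpy())
        full["direction"] = np.where(full["diff"] > 0, "over", "under")
    else:
        full["bh_q"] = pd.Series(dtype=float)
        full["direction"] = pd.Series(dtype=str)
    full = full.set_index("site_id")
    des = full[(full["p"] < alpha) & (full["diff"].abs() >= min_diff)].copy()
    return des, full


def summarize_patterns(
    des_tables: Mapping[str, pd.DataFrame],
    adar_log2fc: Mapping[str, float],
) -> PatternSummary:
    """Over/under-editing proportions per condition and their ADAR link.

    For each condition the counts and proportion of over-editing DESs are
    tabulated; across conditions the proportion is regressed (OLS) on the
    ADAR log2 fold change of resistant vs sensitive expression. Conditions
    with zero DESs are kept in the table with an undefined proportion but
    excluded from the regression.
    """
    rows = []
    for cond, des in des_tables.items():
        n_over = int((des["direction"] == "over").sum())
        n_under = int((des["direction"] == "under").sum())
        total = n_over + n_under
        prop = n_over / total if total else float("nan")
        rows.append((cond, n_over, n_under, prop, adar_log2fc.get(cond, float("nan"))))
    table = pd.DataFrame(
        rows, columns=["condition", "n_over", "n_under", "prop_over", "adar_log2fc"]
    ).set_index("condition")
    usable = table.dropna(subset=["prop_over", "adar_log2fc"])
    regression = None
    if len(usable) >= 3 and usable["adar_log2fc"].nunique() > 1:
        fit = stats.linregress(usable["adar_log2fc"], usable["prop_over"])
        regression = RegressionResult(
            slope=float(fit.slope), intercept=float(fit.intercept),
            r2=float(fit.rvalue**2), p=float(fit.pvalue), n=len(usable),
        )
    return PatternSummary(table=table, regression=regression)


def log2_fold_change(
    values: pd.Series, condition: Condition, pseudocount: float = 0.0
) -> float:
    """log2 of mean(resistant) / mean(sensitive) for one feature.

    A zero denominator (or numerator) with ``pseudocount`` 0 is an error
    rather than a silent shift, because pseudocounts can change the sign
    of the fold change near zero.
    """
    res = values.loc[values.index.intersection(condition.resistant)]
    sen = values.loc[values.index.intersection(condition.sensitive)]
    num = float(res.mean()) + pseudocount
    den = float(sen.mean()) + pseudocount
    if num <= 0 or den <= 0:
        raise ValueError(
            "zero group mean with pseudocount 0; set a pseudocount explicitly"
        )
    return math.log2(num / den)


def rank_de(
    expression: pd.DataFrame,
    condition: Condition,
    mode: str = "auto",
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Rank-based differential expression between resistant and sensitive.

    Per feature: two-sided Wilcoxon rank-sum p and log2 fold change of
    group means. Features constant across both groups get p = 1 by
    convention (logged). Requires >= 3 samples per group.
    """
    res_cols = [s for s in expression.columns if s in condition.resistant]
    sen_cols = [s for s in expression.columns if s in condition.sensitive]
    if len(res_cols) < 3 or len(sen_cols) < 3:
        raise ValueError("need >= 3 samples per group for differential expression")
    rows = []
    for feat in expression.index:
        res_vals = expression.loc[feat, res_cols].to_numpy(dtype=float)
        sen_vals = expression.loc[feat, sen_cols].to_numpy(dtype=float)
        pooled = np.concatenate([res_vals, sen_vals])
        if np.all(pooled == pooled[0]):
            log.info("rank_de: feature %s constant in both groups, p = 1", feat)
            p = 1.0
        else:
            p = wilcoxon_rank_sum(res_vals, sen_vals, mode=mode)
        lfc = log2_fold_change(
            pd.Series(pooled, index=res_cols + sen_cols), condition, pseudocount
        )
        rows.append((feat, p, lfc))
    return pd.DataFrame(rows, columns=["feature_id", "p", "log2fc"]).set_index("feature_id")


# ---------------------------------------------------------------------------
# Meet/Min (Simpson) overlap


def meet_min(set_a: Iterable, set_b: Iterable) -> float:
    """Meet/Min (Simpson) index |A n B| / min(|A|, |B|) for nonempty sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("meet_min requires nonempty sets")
    return len(a & b) / min(len(a), len(b))


def meet_min_matrix(named_sets: Mapping[str, Iterable]) -> pd.DataFrame:
    """Pairwise Meet/Min matrix over named sets (DESs, genes or terms)."""
    names = list(named_sets)
    sets = {k: set(v) for k, v in named_sets.items()}
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            val = meet_min(sets[a], sets[b])
            mat.loc[a, b] = val
            mat.loc[b, a] = val
    return mat
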
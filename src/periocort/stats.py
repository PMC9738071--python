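"""Cohort statistics: normality-gated group comparisons, simple regression,
longitudinal summaries and median group tables with high/low flagging.

The testing policy mirrors standard clinical-radiology practice: each
group (or paired difference) is screened with Shapiro-Wilk at alpha = 0.05
and, across unpaired groups, Levene's variance-homogeneity test; when the
gate passes, means are compared with Student's t test / one-way ANOVA,
otherwise medians are compared with Wilcoxon-family rank tests
(Mann-Whitney U for independent groups, signed-rank for paired data,
Kruskal-Wallis for three or more groups). Group tables report medians and
flag the significantly highest (H) and lowest (L) option when the omnibus
p-value falls below the flag alpha. p-values are per-comparison (no
multiplicity correction) by default; an optional Holm adjustment is
available on the group tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (
    CohortRecord,
    DESIGN_FEATURES,
    NUMERIC_COVARIATES,
    PROSTHETIC_FEATURES,
    records_to_frame,
)
from .errors import InsufficientDataError, SchemaError
from .io import TIMEPOINTS

__all__ = [
    "GroupSummary",
    "GroupComparisonResult",
    "RegressionResult",
    "LongitudinalSummary",
    "choose_test",
    "compare_groups",
    "simple_regression",
    "longitudinal_summary",
    "design_feature_table",
    "covariate_relations",
    "mbl_prevalence",
]


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    median: float


@dataclass
class GroupComparisonResult:
    """Outcome of a (possibly multi-) group comparison.

    ``test_used`` is one of ``t`` (Student), ``W`` (Wilcoxon family),
    ``anova`` or ``kruskal_wallis``. ``flags`` maps each group label to
    ``'H'``, ``'L'`` or ``None``; flags are assigned only when
    ``p_value < alpha``, to the groups with the highest and lowest median.
    """

    test_used: str
    statistic: float
    p_value: float
    group_summaries: list[GroupSummary]
    flags: dict[str, str | None]
    paired: bool = False


@dataclass
class RegressionResult:
    """Least-squares simple regression with Pearson CC and R^2 in percent."""

    cc: float
    r_squared_pct: float
    p_value: float
    slope: float
    intercept: float
    n: int
    undefined: bool = False


def _clean(sample) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    return arr[~np.isnan(arr)]


def choose_test(
    groups: Sequence[Sequence[float]], paired: bool = False, alpha: float = 0.05
) -> str:
    """Pick the comparison test from normality and variance screening.

    Shapiro-Wilk per group (on the differences for paired data) at the
    given alpha, plus Levene's test across unpaired groups; any failure —
    including groups too small to screen (n < 3) or with zero spread —
    routes to the rank-based test.
    """
    samples = [_clean(g) for g in groups]
    if len(samples) < 2:
        raise InsufficientDataError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise InsufficientDataError("every group must have at least 2 observations")
    if paired:
        if len(samples) != 2 or len(samples[0]) != len(samples[1]):
            raise InsufficientDataError("paired comparison needs two equal-length groups")
        screened = [samples[1] - samples[0]]
    else:
        screened = samples

    normal = True
    for s in screened:
        if len(s) < 3 or np.ptp(s) == 0:
            normal = False
            break
        if sps.shapiro(s).pvalue < alpha:
            normal = False
            break
    if normal and not paired:
        if sps.levene(*samples).pvalue < alpha:
            normal = False

    if len(samples) == 2:
        return "t" if normal else "W"
    return "anova" if normal else "kruskal_wallis"


def compare_groups(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    paired: bool = False,
) -> GroupComparisonResult:
    """Run the screened test and attach medians and H/L flags."""
    samples = [_clean(g) for g in groups]
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(len(samples))]
    if len(labels) != len(samples):
        raise InsufficientDataError("labels must match groups")
    test = choose_test(samples, paired=paired, alpha=alpha)

    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        statistic, p_value = 0.0, 1.0
    elif test == "t":
        res = sps.ttest_rel(samples[0], samples[1]) if paired else sps.ttest_ind(
            samples[0], samples[1], equal_var=True
        )
        statistic, p_value = float(res.statistic), float(res.pvalue)
    elif test == "W":
        if paired:
            diffs = samples[1] - samples[0]
            if np.all(diffs == 0):
                statistic, p_value = 0.0, 1.0
            else:
                res = sps.wilcoxon(samples[0], samples[1], zero_method="wilcox")
                statistic, p_value = float(res.statistic), float(res.pvalue)
        else:
            res = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
            statistic, p_value = float(res.statistic), float(res.pvalue)
    elif test == "anova":
        res = sps.f_oneway(*samples)
        statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        res = sps.kruskal(*samples)
        statistic, p_value = float(res.statistic), float(res.pvalue)

    summaries = [
        GroupSummary(
            label=lab,
            n=len(s),
            mean=float(s.mean()),
            sd=float(s.std(ddof=1)) if len(s) > 1 else 0.0,
            median=float(np.median(s)),
        )
        for lab, s in zip(labels, samples)
    ]
    flags: dict[str, str | None] = {lab: None for lab in labels}
    if p_value < alpha:
        medians = [g.median for g in summaries]
        if max(medians) > min(medians):
            flags[summaries[int(np.argmax(medians))].label] = "H"
            flags[summaries[int(np.argmin(medians))].label] = "L"
        else:  # tied medians: fall back to means for the direction
            means = [g.mean for g in summaries]
            flags[summaries[int(np.argmax(means))].label] = "H"
            flags[summaries[int(np.argmin(means))].label] = "L"
    return GroupComparisonResult(
        test_used=test,
        statistic=statistic,
        p_value=p_value,
        group_summaries=summaries,
        flags=flags,
        paired=paired,
    )


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares line of y on x with Pearson CC and R^2 (percent).

    Missing values are dropped pairwise. A constant variable yields an
    ``undefined`` result rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"regression needs n >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        nan = float("nan")
        return RegressionResult(nan, nan, nan, nan, nan, n, undefined=True)
    res = sps.linregress(x, y)
    cc = float(res.rvalue)
    return RegressionResult(
        cc=cc,
        r_squared_pct=100.0 * cc * cc,
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=n,
    )


@dataclass
class LongitudinalSummary:
    """Per-timepoint CI/MBL summary plus paired timepoint comparisons.

    ``table`` has one row per populated timepoint (n, mean, SD for CI and
    MBL, and the CI-vs-MBL regression); ``paired_tests`` maps consecutive
    timepoint pairs to the paired CI and MBL comparisons over implants
    observed at both timepoints.
    """

    table: pd.DataFrame
    paired_tests: dict[tuple[str, str], dict[str, GroupComparisonResult | None]] = field(
        default_factory=dict
    )


def longitudinal_summary(records: Sequence[CohortRecord]) -> LongitudinalSummary:
    """Summarize CI and MBL over the follow-up timepoints."""
    if not records:
        raise InsufficientDataError("empty cohort")
    df = records_to_frame(records)
    rows = []
    present: list[str] = []
    for tp in TIMEPOINTS:
        ci = _clean(df[f"ci_{tp}"])
        mbl = _clean(df[f"mbl_{tp}"])
        if len(ci) == 0 and len(mbl) == 0:
            continue
        present.append(tp)
        pair_mask = ~(df[f"ci_{tp}"].isna() | df[f"mbl_{tp}"].isna())
        row: dict = {
            "timepoint": tp,
            "n_ci": len(ci),
            "ci_mean": float(ci.mean()) if len(ci) else float("nan"),
            "ci_sd": float(ci.std(ddof=1)) if len(ci) > 1 else float("nan"),
            "n_mbl": len(mbl),
            "mbl_mean": float(mbl.mean()) if len(mbl) else float("nan"),
            "mbl_sd": float(mbl.std(ddof=1)) if len(mbl) > 1 else float("nan"),
            "n_pairs": int(pair_mask.sum()),
        }
        if pair_mask.sum() >= 3:
            try:
                reg = simple_regression(
                    df.loc[pair_mask, f"mbl_{tp}"], df.loc[pair_mask, f"ci_{tp}"]
                )
                row.update(
                    cc=reg.cc, r_squared_pct=reg.r_squared_pct, reg_p=reg.p_value
                )
            except InsufficientDataError:
                pass
        rows.append(row)
    if not rows or all(r["n_ci"] == 0 for r in rows):
        raise InsufficientDataError("no CI data at any timepoint")
    table = pd.DataFrame(rows)

    paired_tests: dict[tuple[str, str], dict[str, GroupComparisonResult | None]] = {}
    for t0, t1 in zip(present[:-1], present[1:]):
        entry: dict[str, GroupComparisonResult | None] = {}
        for metric in ("ci", "mbl"):
            a = df[f"{metric}_{t0}"]
            b = df[f"{metric}_{t1}"]
            both = ~(a.isna() | b.isna())
            if both.sum() >= 3:
                entry[metric] = compare_groups(
                    [a[both].to_numpy(), b[both].to_numpy()],
                    labels=[t0, t1],
                    paired=True,
                )
            else:
                entry[metric] = None
        paired_tests[(t0, t1)] = entry
    return LongitudinalSummary(table=table, paired_tests=paired_tests)


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    order = np.argsort(pvals)
    m = len(pvals)
    adj = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def design_feature_table(
    records: Sequence[CohortRecord],
    feature: str,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Median MBL and CI per design-feature option and timepoint with flags.

    ``feature`` must be an implant design column or a prosthetic column.
    For each timepoint and metric the options are compared with the
    screened multi-group test; when significant, the option with the
    highest median is flagged ``H`` and the lowest ``L``. ``holm=True``
    applies a Holm adjustment over the comparisons of this table before
    flagging.
    """
    valid = DESIGN_FEATURES + PROSTHETIC_FEATURES
    if feature not in valid:
        raise SchemaError(f"unknown grouping feature {feature!r}; use one of {valid}")
    df = records_to_frame(records)
    options = sorted(o for o in df[feature].dropna().unique())
    if len(options) < 2:
        raise InsufficientDataError(
            f"feature {feature!r} has fewer than two populated options"
        )

    comparisons: list[tuple[str, str, GroupComparisonResult | None]] = []
    for tp in TIMEPOINTS:
        for metric in ("mbl", "ci"):
            col = f"{metric}_{tp}"
            grouped = [(_clean(df.loc[df[feature] == o, col]), o) for o in options]
            testable = [(g, o) for g, o in grouped if len(g) >= 3]
            result = None
            if len(testable) >= 2:
                try:
                    result = compare_groups(
                        [g for g, _ in testable],
                        labels=[o for _, o in testable],
                        alpha=alpha,
                    )
                except InsufficientDataError:
                    result = None
            comparisons.append((tp, metric, result))

    if holm:
        tested = [c for c in comparisons if c[2] is not None]
        adj = _holm([c[2].p_value for c in tested])
        for (tp, metric, result), p_adj in zip(tested, adj):
            result.p_value = p_adj
            if p_adj >= alpha:
                result.flags = {k: None for k in result.flags}

    rows = []
    for tp, metric, result in comparisons:
        flags = result.flags if result is not None else {}
        p_value = result.p_value if result is not None else float("nan")
        for o in options:
            vals = _clean(df.loc[df[feature] == o, f"{metric}_{tp}"])
            rows.append(
                {
                    "feature": feature,
                    "option": o,
                    "metric": metric,
                    "timepoint": tp,
                    "n": len(vals),
                    "median": float(np.median(vals)) if len(vals) else float("nan"),
                    "p_value": p_value,
                    "flag": flags.get(o) or "",
                }
            )
    return pd.DataFrame(rows)


def covariate_relations(
    records: Sequence[CohortRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of each numeric covariate with CI per timepoint.

    The ``relation`` column reports ``direct`` / ``inverse`` for
    significant positive / negative correlations and ``none`` otherwise.
    """
    df = records_to_frame(records)
    rows = []
    for cov in NUMERIC_COVARIATES:
        for tp in TIMEPOINTS:
            x = df[cov].to_numpy(dtype=float)
            y = df[f"ci_{tp}"].to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y))
            n = int(keep.sum())
            if n < 3 or np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
                rows.append(
                    {
                        "covariate": cov,
                        "timepoint": tp,
                        "n": n,
                        "cc": float("nan"),
                        "p_value": float("nan"),
                        "relation": "none",
                    }
                )
                continue
            cc, p = sps.pearsonr(x[keep], y[keep])
            relation = "none"
            if p < alpha:
                relation = "direct" if cc > 0 else "inverse"
            rows.append(
                {
                    "covariate": cov,
                    "timepoint": tp,
                    "n": n,
                    "cc": float(cc),
                    "p_value": float(p),
                    "relation": relation,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PrevalenceResult:
    """Zero / positive MBL split at one timepoint."""

    fraction_zero: float
    fraction_positive: float
    mean_positive: float
    sd_positive: float
    n: int


def mbl_prevalence(records: Sequence[CohortRecord], timepoint: str) -> PrevalenceResult:
    """Fractions of unaffected (MBL = 0) and affected implants, with the
    conditional mean and SD of MBL in the affected subgroup."""
    if timepoint not in TIMEPOINTS:
        raise SchemaError(f"unknown timepoint {timepoint!r}")
    df = records_to_frame(records)
    vals = _clean(df[f"mbl_{timepoint}"])
    if len(vals) == 0:
        raise InsufficientDataError(f"no MBL data at timepoint {timepoint!r}")
    positive = vals[vals > 0]
    frac_pos = len(positive) / len(vals)
    if len(positive) == 0:
        mean_pos, sd_pos = float("nan"), float("nan")
    else:
        mean_pos = float(positive.mean())
        sd_pos = float(positive.std(ddof=1)) if len(positive) > 1 else 0.0
    return PrevalenceResult(
        fraction_zero=1.0 - frac_pos,
        fraction_positive=frac_pos,
        mean_positive=mean_pos,
        sd_positive=sd_pos,
        n=len(vals),
    )
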
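"""Cohort-level statistics: paired comparisons, correlations, repeated-measures
ANOVA with Tukey correction, fold summaries, and the summary table.

The study design is fully paired — every subject is scanned with both
tracers — so tracer contrasts are paired t-tests (or Wilcoxon signed-rank
where normality is not asserted), tracer/organ agreement is Pearson
correlation, and multi-condition contrasts use a within-subject one-way
ANOVA with Tukey's HSD on the condition means (Prism-style, using the ANOVA
error term).  Normality is asserted by configuration, never inferred.

Fold differences between organs are reported in both conventions — mean ±
SD of per-subject ratios, and the ratio of cohort means — because the two
differ and published fold statements mix them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "PairedTestResult",
    "CorrelationResult",
    "AnovaResult",
    "TukeyPair",
    "FoldSummary",
    "paired_compare",
    "correlate",
    "rm_anova_tukey",
    "fold_summary",
    "build_summary_table",
    "significance_marker",
]


@dataclass(frozen=True)
class PairedSample:
    subject_ids: tuple
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if len(self.subject_ids) != a.size or a.size != b.size:
            raise ValueError("subject ids and both value arrays must have equal length")
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise ValueError("missing pairs are not allowed")

    @property
    def n(self) -> int:
        return self.a.size


@dataclass(frozen=True)
class PairedTestResult:
    method: str
    statistic: float
    p_value: float
    mean_diff: float  # mean(a - b)
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TukeyPair:
    cond_a: str
    cond_b: str
    mean_diff: float
    q: float
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_cond: int
    df_error: int
    p_value: float
    ms_error: float
    tukey: tuple


def paired_compare(sample: PairedSample, method: str = "t") -> PairedTestResult:
    """Two-sided paired comparison of condition A vs condition B."""
    if method not in ("t", "wilcoxon"):
        raise ValueError("method must be 't' or 'wilcoxon'")
    if sample.n < 3:
        raise ValueError("need at least 3 pairs")
    diff = sample.a - sample.b
    mean_diff = float(np.mean(diff))
    if np.allclose(np.std(diff), 0.0):
        # all differences identical: the test statistic is undefined unless
        # the common difference is itself zero
        if np.allclose(diff, 0.0):
            return PairedTestResult(method, 0.0, 1.0, 0.0, sample.n, degenerate=True)
        return PairedTestResult(method, np.inf * np.sign(mean_diff), np.nan, mean_diff, sample.n, degenerate=True)
    if method == "t":
        res = stats.ttest_rel(sample.a, sample.b)
        return PairedTestResult("t", float(res.statistic), float(res.pvalue), mean_diff, sample.n)
    res = stats.wilcoxon(sample.a, sample.b)
    return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue), mean_diff, sample.n)


def correlate(sample: PairedSample) -> CorrelationResult:
    """Pearson correlation with two-sided p; r^2 is the determination coefficient."""
    if sample.n < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(np.std(sample.a), 0.0) or np.allclose(np.std(sample.b), 0.0):
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(sample.a, sample.b)
    r = float(res.statistic)
    return CorrelationResult(r=r, r2=r * r, p_value=float(res.pvalue), n=sample.n)


def rm_anova_tukey(data: pd.DataFrame, subject: str = "subject", condition: str = "condition", value: str = "value") -> AnovaResult:
    """Within-subject one-way ANOVA plus Tukey HSD pairwise comparisons.

    Requires a complete subject x condition design.  The pairwise tests use
    the studentized range on condition means with the repeated-measures
    error mean square, i.e. Tukey correction sharing the ANOVA error term.
    """
    wide = data.pivot(index=subject, columns=condition, values=value)
    if wide.isna().any().any():
        raise ValueError("incomplete design: every subject needs every condition")
    conds = list(wide.columns)
    k = len(conds)
    n = wide.shape[0]
    if k < 3:
        raise ValueError("need >= 3 conditions")
    x = wide.to_numpy()
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = max(ss_err / df_err, 0.0)
    if ms_err == 0.0:
        f = 0.0 if ms_cond == 0 else np.inf
        p = 1.0 if ms_cond == 0 else 0.0
    else:
        f = ms_cond / ms_err
        p = float(stats.f.sf(f, df_cond, df_err))
    se = np.sqrt(ms_err / n)
    pairs = []
    means = x.mean(axis=0)
    for i in range(k):
        for j in range(i + 1, k):
            d = means[i] - means[j]
            if se == 0.0:
                q = 0.0 if d == 0 else np.inf
                pq = 1.0 if d == 0 else 0.0
            else:
                q = abs(d) / se
                pq = float(stats.studentized_range.sf(q, k, df_err))
            pairs.append(TukeyPair(str(conds[i]), str(conds[j]), float(d), float(q), pq))
    return AnovaResult(f=float(f), df_cond=df_cond, df_error=df_err, p_value=p, ms_error=float(ms_err), tukey=tuple(pairs))


@dataclass(frozen=True)
class FoldSummary:
    mean_of_ratios: float
    sd_of_ratios: float
    ratio_of_means: float
    n: int


def fold_summary(numerator: np.ndarray, denominator: np.ndarray) -> FoldSummary:
    """Both fold conventions for paired per-subject values (e.g. cortex vs
    myocardium K1): mean +/- SD of per-subject ratios, and ratio of means."""
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape or num.ndim != 1 or num.size == 0:
        raise ValueError("need matching non-empty 1-D arrays")
    if np.any(den <= 0):
        raise ValueError("denominators must be positive")
    ratios = num / den
    if np.mean(den) <= 0:
        raise ValueError("mean denominator must be positive")
    return FoldSummary(
        mean_of_ratios=float(np.mean(ratios)),
        sd_of_ratios=float(np.std(ratios, ddof=1)) if num.size > 1 else 0.0,
        ratio_of_means=float(np.mean(num) / np.mean(den)),
        n=num.size,
    )


def significance_marker(p: float) -> str:
    """Published significance tiers: * <=0.05, ** <=0.01, *** <=0.001."""
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def build_summary_table(
    metrics: pd.DataFrame,
    reference_tracer: str = "ac",
    method: str = "t",
) -> pd.DataFrame:
    """Cohort summary keyed by (organ, metric, tracer): mean, SD, n, and a
    significance marker vs the reference tracer from a paired test.

    ``metrics`` is tidy: columns subject_id, organ, metric, tracer, value.
    Metrics present for only one tracer (MBF, MVO2, second-peak stats) get no
    marker.  With a single subject SDs are reported as NaN and no tests run.
    """
    required = {"subject_id", "organ", "metric", "tracer", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(required)}")
    tracers = set(metrics["tracer"].unique())
    if reference_tracer not in tracers:
        raise ValueError(f"missing reference tracer arm {reference_tracer!r}")

    rows = []
    for (organ, metric), grp in metrics.groupby(["organ", "metric"], sort=False):
        by_tracer = {tr: g.sort_values("subject_id") for tr, g in grp.groupby("tracer")}
        for tracer, g in by_tracer.items():
            vals = g["value"].to_numpy(dtype=float)
            p_val = np.nan
            if (
                tracer != reference_tracer
                and reference_tracer in by_tracer
                and len(by_tracer[reference_tracer]) == len(g) >= 3
            ):
                ref = by_tracer[reference_tracer]
                sample = PairedSample(
                    tuple(g["subject_id"]), vals, ref["value"].to_numpy(dtype=float)
                )
                res = paired_compare(sample, method=method)
                p_val = res.p_value
            rows.append(
                {
                    "organ": organ,
                    "metric": metric,
                    "tracer": tracer,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                    "n": int(vals.size),
                    "p_vs_ref": p_val,
                    "marker": significance_marker(p_val) if np.isfinite(p_val) else "",
                }
            )
    return pd.DataFrame(rows)
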
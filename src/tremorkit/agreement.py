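"""Paired-method agreement and group-comparison statistics.

Pearson correlation, Bland-Altman bias/limits of agreement, Lin's
concordance correlation coefficient, two-way random-effects ICC with
absolute agreement, and adjacent-group t-tests with Holm step-down
adjustment plus noncentral-t post-hoc power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "ScoreComparison",
    "pearson",
    "bland_altman",
    "concordance_ccc",
    "icc_absolute",
    "holm_adjust",
    "contiguous_score_tests",
    "agreement_report",
    "agreement_table",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class AgreementReport:
    """Paired-method comparison for one measure."""

    r: float
    p: float
    bias: float
    sd_diff: float
    loa: tuple[float, float]
    ccc: float
    n: int


@dataclass(frozen=True)
class ScoreComparison:
    """Adjacent ordinal-score comparisons with Holm adjustment."""

    labels: list[str]
    t_stats: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    post_hoc_power: np.ndarray
    alpha: float = 0.05


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p-value."""
    x, y = _paired(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(x, y) -> tuple[float, float, tuple[float, float]]:
    """Bias, sample SD of differences, and 95% limits of agreement."""
    x, y = _paired(x, y, 2)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, (bias - 1.96 * sd, bias + 1.96 * sd)


def concordance_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (biased 1/n moments)."""
    x, y = _paired(x, y, 3)
    vx = float(np.var(x))
    vy = float(np.var(y))
    if vx == 0 and vy == 0:
        raise ValueError("both inputs constant: CCC undefined")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    return 2.0 * sxy / (vx + vy + (float(x.mean()) - float(y.mean())) ** 2)


def agreement_report(x, y) -> AgreementReport:
    """Full paired-method comparison: r, p, bias, SD, LoA, CCC."""
    x, y = _paired(x, y, 3)
    r, p = pearson(x, y)
    bias, sd, loa = bland_altman(x, y)
    return AgreementReport(
        r=r, p=p, bias=bias, sd_diff=sd, loa=loa, ccc=concordance_ccc(x, y), n=x.size
    )


def icc_absolute(ratings, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Single-rater two-way random-effects ICC with absolute agreement.

    ``ratings`` is a complete raters x subjects table.  The F-based
    confidence interval follows the standard two-way ANOVA construction
    (McGraw & Wong's ICC(A,1)).
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2:
        raise ValueError("ratings must be a 2-D raters x subjects table")
    if not np.isfinite(table).all():
        raise ValueError("ratings table must be complete and finite")
    k, n = table.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n < 5:
        raise ValueError("need at least 5 subjects")

    grand = table.mean()
    subj_means = table.mean(axis=0)
    rater_means = table.mean(axis=1)
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_rater = n * float(np.sum((rater_means - grand) ** 2))
    ss_total = float(np.sum((table - grand) ** 2))
    ss_err = ss_total - ss_subj - ss_rater

    msr = ss_subj / (n - 1)  # between-subjects
    msc = ss_rater / (k - 1)  # between-raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    # Satterthwaite df for the CI on the rater/error combination
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    else:
        v = (n - 1) * (k - 1)
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return float(icc), (float(lower), float(upper))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def _posthoc_power(a: np.ndarray, b: np.ndarray, alpha: float) -> float:
    """Two-sided power at the observed effect size via the noncentral t."""
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        return 1.0 if a.mean() != b.mean() else float(alpha)
    d = abs(a.mean() - b.mean()) / np.sqrt(sp2)
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def contiguous_score_tests(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> ScoreComparison:
    """t-tests between adjacent ordinal groups, Holm-adjusted at ``alpha``.

    ``groups`` is ordered by score; each needs n >= 2.  The default test is
    the pooled-variance two-sample t; ``equal_var=False`` selects Welch.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has n={g.size} < 2")
    if labels is None:
        labels = [f"{i}-{i + 1}" for i in range(len(groups) - 1)]

    t_stats, p_raw, power = [], [], []
    for a, b in zip(groups[:-1], groups[1:]):
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stats.append(float(res.statistic))
        p_raw.append(float(res.pvalue))
        power.append(_posthoc_power(a, b, alpha))
    p_raw = np.asarray(p_raw)
    p_adj = holm_adjust(p_raw)
    return ScoreComparison(
        labels=list(labels),
        t_stats=np.asarray(t_stats),
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=p_adj < alpha,
        post_hoc_power=np.asarray(power),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Table-level pipeline
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "metric",
    "task",
    "thresholded",
    "n",
    "r",
    "p",
    "bias",
    "sd",
    "ccc",
    "insufficient",
]


def agreement_table(
    device_df: pd.DataFrame,
    reference_df: pd.DataFrame,
    metric_names: list[str] | None = None,
    threshold_mm: float | None = 1.0,
    by_task: bool = True,
) -> pd.DataFrame:
    """Per-metric, per-task agreement between two metric tables.

    Rows are matched on (trial_id, axis).  When ``threshold_mm`` is given, a
    second set of rows is produced restricted to pairs whose *reference*
    RMS reaches the threshold (p-values are recomputed on the reduced n).
    Cells with fewer than 3 surviving pairs are flagged ``insufficient``
    rather than fabricated.
    """
    if metric_names is None:
        from .metrics import METRIC_NAMES

        metric_names = list(METRIC_NAMES)
    keys = ["trial_id", "axis"]
    merged = device_df.merge(
        reference_df, on=keys, suffixes=("_dev", "_ref"), how="inner"
    )
    if merged.empty:
        raise ValueError("no trial_id/axis pairs shared between the tables")
    task_col = "task_dev" if "task_dev" in merged.columns else "task"
    tasks = sorted(merged[task_col].unique()) if by_task else ["all"]

    thresholds: list[tuple[bool, pd.DataFrame]] = [(False, merged)]
    if threshold_mm is not None:
        thresholds.append((True, merged[merged["rms_ref"] >= threshold_mm]))

    rows = []
    for thresholded, frame in thresholds:
        for metric in metric_names:
            for task in tasks:
                sub = frame if not by_task else frame[frame[task_col] == task]
                x = sub[f"{metric}_dev"].to_numpy()
                y = sub[f"{metric}_ref"].to_numpy()
                row = {
                    "metric": metric,
                    "task": task,
                    "thresholded": thresholded,
                    "n": x.size,
                    "insufficient": False,
                }
                try:
                    rep = agreement_report(x, y)
                    row.update(
                        r=rep.r, p=rep.p, bias=rep.bias, sd=rep.sd_diff, ccc=rep.ccc
                    )
                except ValueError:
                    row.update(
                        r=np.nan, p=np.nan, bias=np.nan, sd=np.nan, ccc=np.nan,
                        insufficient=True,
                    )
                rows.append(row)
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def bland_altman_plot(x, y, ax=None, label: str = ""):
    """Difference-vs-mean scatter with bias and 95% limits of agreement."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x, y = _paired(x, y, 2)
    bias, sd, (lo, hi) = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2.0, x - y, s=12, alpha=0.7)
    for yv, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(yv, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlabel(f"mean of methods {label}".strip())
    ax.set_ylabel("difference between methods")
    return ax
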
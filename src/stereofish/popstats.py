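"""Comparison of sampled vs image-estimated size/weight distributions.

Implements the reporting conventions used for the field comparison:
percentage mean difference between the two approaches, per-group
Shapiro-Wilk normality, Levene homogeneity of variances, Welch (or
pooled) test of mean equality with the decision recorded, matched
quantile pairs for q-q plotting, and 1-cm-bin histograms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DistributionComparison",
    "mean_difference_pct",
    "compare_distributions",
    "qq_pairs",
    "histogram_1cm",
]


@dataclass
class TestResult:
    statistic: float | None
    p_value: float | None
    applicable: bool = True
    note: str = ""


@dataclass
class DistributionComparison:
    """Full comparison of a sampled vs an estimated distribution.

    ``mean_equality`` reports a Welch test when Levene rejects variance
    homogeneity at ``alpha`` and a pooled-variance test otherwise; the
    branch taken is recorded in ``variance_branch``.  The mean-equality
    statistic is the F form (squared t), the convention under which
    two-group Welch results are reported in this context.
    """

    n_sampled: int
    n_estimated: int
    mean_sampled: float
    mean_estimated: float
    sd_sampled: float
    sd_estimated: float
    mean_difference_pct: float
    shapiro_sampled: TestResult
    shapiro_estimated: TestResult
    levene: TestResult
    mean_equality: TestResult
    variance_branch: str
    alpha: float
    qq: list[tuple[float, float]] = field(repr=False, default_factory=list)
    histogram_sampled: dict[int, int] = field(repr=False, default_factory=dict)
    histogram_estimated: dict[int, int] = field(repr=False, default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        def tr(t: TestResult) -> dict:
            return {"statistic": t.statistic, "p_value": t.p_value, "applicable": t.applicable, "note": t.note}

        payload = json.dumps(
            {
                "n_sampled": self.n_sampled,
                "n_estimated": self.n_estimated,
                "mean_sampled": self.mean_sampled,
                "mean_estimated": self.mean_estimated,
                "sd_sampled": self.sd_sampled,
                "sd_estimated": self.sd_estimated,
                "mean_difference_pct": self.mean_difference_pct,
                "shapiro_sampled": tr(self.shapiro_sampled),
                "shapiro_estimated": tr(self.shapiro_estimated),
                "levene": tr(self.levene),
                "mean_equality": tr(self.mean_equality),
                "variance_branch": self.variance_branch,
                "alpha": self.alpha,
                "qq": self.qq,
                "histogram_sampled": {str(k): v for k, v in self.histogram_sampled.items()},
                "histogram_estimated": {str(k): v for k, v in self.histogram_estimated.items()},
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def mean_difference_pct(sampled_mean: float, estimated_mean: float) -> float:
    """Percentage difference between the two approaches' means.

    Defined as |sampled - estimated| / estimated * 100, i.e. relative to
    the image-estimated mean.  Round to one decimal for reporting.
    """
    if estimated_mean == 0:
        raise ZeroDivisionError("estimated mean must be nonzero")
    if estimated_mean < 0:
        raise ValueError("estimated mean must be positive")
    return abs(sampled_mean - estimated_mean) / estimated_mean * 100


def qq_pairs(sampled, estimated) -> list[tuple[float, float]]:
    """Matched quantile pairs for a two-sample q-q plot.

    Both samples are evaluated at the plotting positions of the smaller
    sample, p_i = (i - 1) / (n - 1), with linear (type-7) interpolation;
    the smaller sample's quantiles at its own plotting positions are its
    order statistics.  Points on the identity line indicate a common
    distribution.
    """
    x = np.sort(np.asarray(sampled, dtype=float))
    y = np.sort(np.asarray(estimated, dtype=float))
    n = min(x.size, y.size)
    if n < 1:
        raise ValueError("both samples must be non-empty")
    if n == 1:
        probs = np.array([0.5])
    else:
        probs = np.arange(n) / (n - 1)
    qx = np.quantile(x, probs, method="linear")
    qy = np.quantile(y, probs, method="linear")
    return list(zip(qx.tolist(), qy.tolist()))


def histogram_1cm(lengths) -> dict[int, int]:
    """Counts in half-open 1-cm bins [k, k+1), keyed by the left edge."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one length")
    lo = int(np.floor(arr.min()))
    hi = int(np.floor(arr.max())) + 1
    edges = np.arange(lo, hi + 1)
    counts, _ = np.histogram(arr, bins=edges)
    return {int(edges[i]): int(counts[i]) for i in range(len(counts))}


def compare_distributions(
    sampled,
    estimated,
    alpha: float = 0.05,
    levene_center: str = "median",
) -> DistributionComparison:
    """Run the full sampled-vs-estimated comparison cascade.

    Shapiro-Wilk per group, then Levene (Brown-Forsythe median-centred
    by default) across groups; the mean comparison uses the Welch test
    when Levene rejects homogeneity at ``alpha`` and the pooled-variance
    test otherwise.  Constant groups make the tests inapplicable and are
    flagged rather than raised.
    """
    x = np.asarray(sampled, dtype=float)
    y = np.asarray(estimated, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")

    def shapiro(arr: np.ndarray) -> TestResult:
        if np.ptp(arr) == 0:
            return TestResult(None, None, False, "constant sample; normality test not applicable")
        w, p = stats.shapiro(arr)
        return TestResult(float(w), float(p))

    sh_x, sh_y = shapiro(x), shapiro(y)

    if np.ptp(x) == 0 and np.ptp(y) == 0:
        levene = TestResult(None, None, False, "both groups constant")
        equal_var = True
    else:
        w, p = stats.levene(x, y, center=levene_center)
        levene = TestResult(float(w), float(p))
        equal_var = p >= alpha

    if np.ptp(x) == 0 and np.ptp(y) == 0:
        mean_eq = TestResult(None, None, False, "zero variance in both groups")
        branch = "not_applicable"
    else:
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
        # report the F form (t^2), matching two-group Welch-ANOVA conventions
        mean_eq = TestResult(float(t) ** 2, float(p))
        branch = "pooled" if equal_var else "welch"

    return DistributionComparison(
        n_sampled=int(x.size),
        n_estimated=int(y.size),
        mean_sampled=float(x.mean()),
        mean_estimated=float(y.mean()),
        sd_sampled=float(x.std(ddof=1)),
        sd_estimated=float(y.std(ddof=1)),
        mean_difference_pct=mean_difference_pct(float(x.mean()), float(y.mean())),
        shapiro_sampled=sh_x,
        shapiro_estimated=sh_y,
        levene=levene,
        mean_equality=mean_eq,
        variance_branch=branch,
        alpha=alpha,
        qq=qq_pairs(x, y),
        histogram_sampled=histogram_1cm(x),
        histogram_estimated=histogram_1cm(y),
    )
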
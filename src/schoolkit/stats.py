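"""Normality-routed hypothesis tests for real-vs-mock comparisons.

Real samples are small (one value per trial) and are tested for normality
with Shapiro-Wilk; mock samples can be much larger (one value per mock group)
and use a Kolmogorov-Smirnov test against a normal with the sample's own mean
and SD (a Lilliefors-style check: the estimated parameters make it slightly
conservative, which is logged, not corrected).  If both samples pass, the
two groups are compared with Student's t; otherwise with Mann-Whitney U.
Mock-corrected per-trial statistics are tested against zero with a one-sample
t-test when normal, a Wilcoxon signed-rank test otherwise.  All tests are
two-sided at alpha = 0.05; summaries report means for normal samples and
medians otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "RoutingDecision",
    "StatResult",
    "normality_route",
    "two_sample_compare",
    "one_sample_vs_zero",
    "dunn_posthoc",
]

ALPHA = 0.05


@dataclass(frozen=True)
class RoutingDecision:
    real_normal: bool
    mock_normal: bool | None
    real_p: float
    mock_p: float | None
    alpha: float = ALPHA

    @property
    def normal_route(self) -> bool:
        if self.mock_normal is None:
            return self.real_normal
        return self.real_normal and self.mock_normal


@dataclass
class StatResult:
    metric: str
    test: str
    statistic: float
    p: float
    n_real: int
    n_mock: int | None
    direction: str            # 'real < mock', 'real > mock', '> 0', ...
    summary_real: float       # mean if normal route, median otherwise
    summary_mock: float | None
    routing: RoutingDecision
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p < self.routing.alpha


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # degenerate constant sample: treat as non-normal
    return float(sps.shapiro(x).pvalue)


def _ks_normal_p(x: np.ndarray) -> float:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return 0.0
    logger.debug("KS normality uses sample-estimated mean/SD (Lilliefors caveat)")
    return float(sps.kstest(x, "norm", args=(np.mean(x), sd)).pvalue)


def normality_route(real, mock=None, alpha: float = ALPHA) -> RoutingDecision:
    """Shapiro-Wilk on the real sample, KS-vs-normal on the mock sample."""
    real = np.asarray(real, dtype=float)
    if len(real) < 3:
        raise ValueError("need at least 3 real values")
    real_p = _shapiro_p(real)
    if mock is None:
        return RoutingDecision(real_p > alpha, None, real_p, None, alpha)
    mock = np.asarray(mock, dtype=float)
    if len(mock) < 3:
        raise ValueError("need at least 3 mock values")
    mock_p = _ks_normal_p(mock)
    return RoutingDecision(real_p > alpha, mock_p > alpha, real_p, mock_p, alpha)


def _summaries(x, normal: bool) -> float:
    return float(np.mean(x)) if normal else float(np.median(x))


def two_sample_compare(real, mock, alpha: float = ALPHA,
                       metric: str = "") -> StatResult:
    """Real vs mock: Student's t if both normal, else Mann-Whitney U."""
    real = np.asarray(real, dtype=float)
    mock = np.asarray(mock, dtype=float)
    if len(real) == 0 or len(mock) == 0:
        raise ValueError("empty sample")
    routing = normality_route(real, mock, alpha=alpha)
    degenerate = False
    if routing.normal_route:
        test = "t"
        stat, p = sps.ttest_ind(real, mock)
    else:
        test = "mannwhitneyu"
        if np.ptp(np.concatenate([real, mock])) == 0:
            stat, p, degenerate = float(len(real) * len(mock) / 2), 1.0, True
        else:
            res = sps.mannwhitneyu(real, mock, alternative="two-sided")
            stat, p = res.statistic, res.pvalue
    sr = _summaries(real, routing.normal_route)
    sm = _summaries(mock, routing.normal_route)
    direction = "real < mock" if sr < sm else ("real > mock" if sr > sm else "real = mock")
    return StatResult(metric=metric, test=test, statistic=float(stat),
                      p=float(p), n_real=len(real), n_mock=len(mock),
                      direction=direction, summary_real=sr, summary_mock=sm,
                      routing=routing, degenerate=degenerate)


def one_sample_vs_zero(values, alpha: float = ALPHA,
                       metric: str = "") -> StatResult:
    """Mock-corrected per-trial values vs zero: t-test if normal, else Wilcoxon."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    routing = normality_route(values, None, alpha=alpha)
    degenerate = False
    if np.all(values == 0):
        test, stat, p, degenerate = "degenerate", 0.0, 1.0, True
    elif routing.real_normal:
        test = "t"
        stat, p = sps.ttest_1samp(values, 0.0)
    else:
        test = "wilcoxon"
        stat, p = sps.wilcoxon(values)
    summary = _summaries(values, routing.real_normal)
    direction = "> 0" if summary > 0 else ("< 0" if summary < 0 else "= 0")
    return StatResult(metric=metric, test=test, statistic=float(stat),
                      p=float(p), n_real=len(values), n_mock=None,
                      direction=direction, summary_real=summary,
                      summary_mock=None, routing=routing, degenerate=degenerate)


def dunn_posthoc(samples: dict, p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based post-hoc test for pairwise follow-up of Kruskal-Wallis.

    ``samples`` maps group label -> 1-D array.  Z statistics use the pooled
    ranks with the standard tie correction; p-values are two-sided, optionally
    Bonferroni-adjusted.
    """
    labels = list(samples)
    arrays = [np.asarray(samples[k], dtype=float) for k in labels]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for label, arr in zip(labels, arrays):
        mean_ranks[label] = float(np.mean(ranks[start:start + len(arr)]))
        sizes[label] = len(arr)
        start += len(arr)
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        if p_adjust == "bonferroni":
            p = min(1.0, p * m)
        elif p_adjust is not None and p_adjust != "none":
            raise ValueError(f"unknown adjustment {p_adjust!r}")
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p": float(p)})
    return pd.DataFrame(rows)
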
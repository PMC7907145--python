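"""Channelwise group-difference statistics with multiplicity correction.

Two-sided Welch t-tests per channel on subject-level features, with
Benjamini-Hochberg (step-up FDR) and Bonferroni significance flags.  The
step procedures are implemented directly so they can be cross-checked
against worked examples and library routines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["StatMap", "t_map", "correct_fdr", "correct_bonferroni", "pearson_r"]


@dataclass
class StatMap:
    channel_labels: Optional[Sequence[str]]
    t: np.ndarray
    p: np.ndarray
    fdr_significant: np.ndarray
    bonferroni_significant: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    alpha: float

    def to_dict(self) -> dict:
        return {
            "channel_labels": list(self.channel_labels) if self.channel_labels else None,
            "t": self.t.tolist(),
            "p": self.p.tolist(),
            "fdr_significant": self.fdr_significant.tolist(),
            "bonferroni_significant": self.bonferroni_significant.tolist(),
            "mean_a": self.mean_a.tolist(),
            "mean_b": self.mean_b.tolist(),
            "alpha": self.alpha,
        }


def correct_fdr(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up flags: reject H(1)..H(k) for the largest k
    with p(k) <= k*q/m."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = (np.arange(1, m + 1) * q) / m
    below = ranked <= thresholds
    flags = np.zeros(m, dtype=bool)
    if np.any(below):
        k = int(np.max(np.nonzero(below)[0]))
        flags[order[: k + 1]] = True
    return flags


def correct_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return p <= alpha / p.size


def t_map(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = 0.05,
    channel_labels: Optional[Sequence[str]] = None,
) -> StatMap:
    """Two-sided Welch t-test per channel between two subject x channel matrices."""
    a = np.atleast_2d(np.asarray(group_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(group_b, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"channel mismatch: {a.shape[1]} vs {b.shape[1]}")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    if channel_labels is not None and len(channel_labels) != a.shape[1]:
        raise ValueError("channel_labels length mismatch")
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.asarray(t)
    p = np.asarray(p)
    # identical degenerate columns yield nan; treat as "no difference"
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    p[bad] = 1.0
    return StatMap(
        channel_labels=channel_labels,
        t=t,
        p=p,
        fdr_significant=correct_fdr(p, alpha),
        bonferroni_significant=correct_bonferroni(p, alpha),
        mean_a=a.mean(axis=0),
        mean_b=b.mean(axis=0),
        alpha=alpha,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]):
    """Pearson correlation with two-sided p value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
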
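"""Group comparison and reporting conventions.

Two-group comparisons default to the unpaired two-tailed Student's t-test
(pooled variance), with Welch and Wilcoxon rank-sum variants selectable by
tag, a D'Agostino-Pearson normality pre-check on each group, and the
control-normalized percent-change reporting convention used throughout the
figures (test vs control mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    percent_change: float
    normality_p: tuple[float, float]  # D'Agostino-Pearson p per group (NaN if n < 8)
    degenerate: bool = False

    def summary(self) -> str:
        return (f"{self.test}: t={self.statistic:.3f}, p={self.p:.3g}; "
                f"a: {self.mean_a:.4g} ± {self.sem_a:.2g} (n={self.n_a}), "
                f"b: {self.mean_b:.4g} ± {self.sem_b:.2g} (n={self.n_b}); "
                f"change {self.percent_change:+.1f}%")


def percent_change(mean_control: float, mean_test: float) -> float:
    """100 x (mean_test - mean_control) / mean_control."""
    if mean_control == 0:
        raise ValueError("control mean must be nonzero")
    return 100.0 * (mean_test - mean_control) / mean_control


def _normality_p(x: np.ndarray) -> float:
    # D'Agostino-Pearson needs n >= 8 for the kurtosis test
    if len(x) < 8 or np.ptp(x) == 0:
        return float("nan")
    return float(sps.normaltest(x).pvalue)


def compare_groups(a, b, test: str = "student") -> GroupComparison:
    """Unpaired two-group comparison with the study's reporting conventions.

    ``test``: "student" (pooled-variance t, default), "welch", or
    "ranksum" (Wilcoxon rank-sum / Mann-Whitney for non-normal data).
    Both groups identical and constant is a degenerate case flagged with
    p = 1. Percent change is computed with group a as the control.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    sem_a = float(sps.sem(a))
    sem_b = float(sps.sem(b))
    norm_p = (_normality_p(a), _normality_p(b))
    pc = percent_change(mean_a, mean_b) if mean_a != 0 else float("nan")

    degenerate = a.std() == 0 and b.std() == 0
    if degenerate:
        stat, p = (0.0, 1.0) if mean_a == mean_b else (float("inf"), 0.0)
    elif test == "student":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    elif test == "welch":
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    elif test == "ranksum":
        stat, p = sps.ranksums(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")

    return GroupComparison(test=test, statistic=float(stat), p=float(p),
                           mean_a=mean_a, mean_b=mean_b, sem_a=sem_a,
                           sem_b=sem_b, n_a=len(a), n_b=len(b),
                           percent_change=pc, normality_p=norm_p,
                           degenerate=degenerate)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p values for per-bin panels."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * len(p), 1.0)
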
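"""Statistical primitives: Welch's two-tailed t-test and descriptives.

All group-contrast P-values in the pipeline come from Welch's unequal-
variance two-sample t-test (Satterthwaite degrees of freedom), two-tailed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Welch's two-tailed two-sample t-test.

    ``t = (x̄ - ȳ) / sqrt(s²x/n1 + s²y/n2)`` with Welch–Satterthwaite
    degrees of freedom.  When both samples are degenerate (zero variance)
    and equal in mean, returns ``t=0, P=1`` instead of dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        mean_eq = math.isclose(x.mean(), y.mean(), rel_tol=0, abs_tol=0)
        t = 0.0 if mean_eq else math.inf * np.sign(x.mean() - y.mean())
        return TTestResult(
            t=t,
            df=float(len(x) + len(y) - 2),
            p=1.0 if mean_eq else 0.0,
            mean_x=float(x.mean()),
            mean_y=float(y.mean()),
            n_x=len(x),
            n_y=len(y),
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        n_x=len(x),
        n_y=len(y),
    )


def describe(sample: Sequence[float]) -> tuple[float, float, int]:
    """``(mean, sample SD, n)``; SD is 0 for n = 1."""
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)
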
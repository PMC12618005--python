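"""Group-comparison statistics from their closed-form definitions.

One-way ANOVA, the unpaired two-sample t-test (pooled or Welch) and
mean ± SEM summaries are implemented directly from sums of squares so each
result is checkable by hand and against library oracles; scipy supplies only
the F and t tail probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "AnovaResult",
    "TTestResult",
    "one_way_anova",
    "unpaired_t_test",
    "summarize_groups",
]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def _as_groups(samples: Mapping[str, Sequence[float]]) -> list[np.ndarray]:
    groups = [np.asarray(v, dtype=float) for v in samples.values()]
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    return groups


def one_way_anova(samples: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    With zero within-group variance and unequal group means the F statistic
    is infinite with p = 0; identical single observations (no residual
    degrees of freedom) are an error.
    """
    groups = _as_groups(samples)
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n = sum(g.size for g in groups)
    if n <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    dfb, dfw = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("all observations identical: F undefined")
        return AnovaResult(F=float("inf"), df_between=dfb, df_within=dfw, p=0.0)
    F = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(F=float(F), df_between=dfb, df_within=dfw, p=float(_st.f.sf(F, dfb, dfw)))


def unpaired_t_test(a: Sequence[float], b: Sequence[float], welch: bool = True) -> TTestResult:
    """Two-sided unpaired t-test, Welch (default) or pooled-variance Student.

    Zero variance in both samples with equal means gives t = 0, p = 1.
    """
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if welch:
        sx2, sy2 = vx / x.size, vy / y.size
        se2 = sx2 + sy2
        if se2 == 0.0:
            return _degenerate_t(diff)
        df = se2**2 / (sx2**2 / (x.size - 1) + sy2**2 / (y.size - 1))
    else:
        df = x.size + y.size - 2
        sp2 = ((x.size - 1) * vx + (y.size - 1) * vy) / df
        se2 = sp2 * (1 / x.size + 1 / y.size)
        if se2 == 0.0:
            return _degenerate_t(diff, df)
    t = diff / np.sqrt(se2)
    return TTestResult(t=float(t), df=float(df), p=float(2 * _st.t.sf(abs(t), df)))


def _degenerate_t(diff: float, df: float = float("nan")) -> TTestResult:
    if diff == 0.0:
        return TTestResult(t=0.0, df=df, p=1.0)
    return TTestResult(t=float(np.sign(diff)) * float("inf"), df=df, p=0.0)


def summarize_groups(samples: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-group mean, SEM (sample sd / sqrt(n)) and n.

    SEM uses the n-1 denominator and is NaN for singleton groups.
    """
    rows = []
    for label, values in samples.items():
        g = np.asarray(values, dtype=float)
        if g.size == 0:
            raise ValueError(f"group {label!r} is empty")
        sem = float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else float("nan")
        rows.append({"group": label, "mean": float(g.mean()), "sem": sem, "n": int(g.size)})
    return pd.DataFrame(rows)
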
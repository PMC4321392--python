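"""Two-sample Student's t-test used for group comparisons.

Classical pooled-variance form by default (Welch available via a flag): the
statistic is ``(mean_a - mean_b) / (s_p * sqrt(1/n_a + 1/n_b))`` with the
pooled standard deviation s_p, and the two-sided p-value comes from the t
distribution with ``n_a + n_b - 2`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

__all__ = ["TTestResult", "ttest_two_sample"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    #: set when both groups are exactly constant (zero pooled variance)
    degenerate: bool = False


def ttest_two_sample(group_a, group_b, *, welch: bool = False) -> TTestResult:
    """Two-sided two-sample t-test.

    With zero pooled variance the test is degenerate: equal means give
    ``t = 0, p = 1``; unequal means give an infinite statistic and ``p = 0``,
    both flagged via ``degenerate``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("observations must be finite")
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)) \
            if se2 > 0 else float(na + nb - 2)
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1 / na + 1 / nb)
        df = float(na + nb - 2)
    if se2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, p=1.0, df=df, degenerate=True)
        return TTestResult(t=float(np.sign(diff)) * np.inf, p=0.0, df=df, degenerate=True)
    t_stat = diff / np.sqrt(se2)
    p = 2.0 * float(t_dist.sf(abs(t_stat), df))
    return TTestResult(t=float(t_stat), p=min(p, 1.0), df=df)
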
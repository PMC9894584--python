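"""Group-level inference: t tests, Wilcoxon signed-rank, Spearman correlation.

All p-values are two-sided and uncorrected.  The Wilcoxon test is offered as
the non-parametric counterpart of the one-sample t test; exact null for small
samples without zeros or ties, normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupStatResult:
    statistic: float
    df: int | None
    p_value: float
    test_name: str
    n: int


def _check(x: np.ndarray, min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, float)
    if x.ndim != 1 or x.size < min_n:
        raise ValueError(f"need a 1-D sample of at least {min_n} values")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    return x


def one_sample_t(x, popmean: float = 0.0) -> GroupStatResult:
    x = _check(x)
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(x, popmean)
    return GroupStatResult(float(res.statistic), x.size - 1,
                           float(res.pvalue), "one-sample t", x.size)


def paired_t(x, y) -> GroupStatResult:
    """One-sample t test on paired differences.

    Degenerate zero-variance differences are resolved by their mean: equal
    samples give t = 0, p = 1; a constant nonzero shift gives an infinite
    statistic with p = 0.
    """
    x, y = _check(x), _check(y)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.std(d, ddof=1) == 0:
        stat = 0.0 if d[0] == 0 else float(np.sign(d[0]) * np.inf)
        return GroupStatResult(stat, x.size - 1, 1.0 if d[0] == 0 else 0.0,
                               "paired t", x.size)
    out = one_sample_t(d, 0.0)
    out.test_name = "paired t"
    return out


def wilcoxon_signed_rank(x, popmean: float = 0.0) -> GroupStatResult:
    """Signed-rank test of symmetry about ``popmean``.

    Exact distribution for n <= 25 with no zero differences or ties; normal
    approximation otherwise.
    """
    x = _check(x, min_n=5)
    d = x - popmean
    if np.all(d == 0):
        raise ValueError("all differences zero: signed-rank test undefined")
    nz = d[d != 0]
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())  # sum of positive ranks
    exact_ok = nz.size <= 25 and nz.size == np.unique(np.abs(nz)).size
    res = sps.wilcoxon(d, method="exact" if exact_ok else "approx")
    return GroupStatResult(w_plus, None, float(res.pvalue),
                           "wilcoxon signed-rank", x.size)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with t-approximation p."""
    x, y = _check(x, 3), _check(y, 3)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
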
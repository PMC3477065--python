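"""Independent reference implementations used only by the test-suite.

Each oracle re-derives a statistic from its textbook definition through a
different code path than the package uses: the t-test from the closed-form
statistic and the incomplete-beta tail, BH from the literal step-up rule,
the hypergeometric tail by exact combinatorial summation, and the
chi-squared statistic and tail from their defining formulas.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import special


def t_test_closed_form(d) -> tuple[float, float]:
    """One-sample t of d against 0: t = mean/(sd/sqrt(n)), two-sided p via
    the incomplete beta function P = I_{df/(df+t^2)}(df/2, 1/2)."""
    d = np.asarray(d, dtype=float)
    n = d.size
    mean = d.sum() / n
    var = ((d - mean) ** 2).sum() / (n - 1)
    t = mean / math.sqrt(var / n)
    df = n - 1
    p = special.betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, float(p)


def bh_step_up(p_values) -> np.ndarray:
    """Literal BH step-up: q(i) = min over j >= i of p(j) * m / j (sorted),
    capped at 1, mapped back to the input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        running_min = min(running_min, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = running_min
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by exact rational
    enumeration of the tail."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for kk in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, kk) * math.comb(N - K, n - kk), total)
    return float(acc)


def chi_squared_gof(observed, expected=None) -> tuple[float, float, float]:
    """Goodness-of-fit chi2 = sum (o - e)^2 / e with equal expected counts
    by default; tail probability from the regularized upper incomplete
    gamma function Q(df/2, x/2). Returns (chi2, dof, p)."""
    obs = np.asarray(observed, dtype=float)
    if expected is None:
        expected = np.full(obs.size, obs.sum() / obs.size)
    exp = np.asarray(expected, dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    dof = obs.size - 1
    p = float(special.gammaincc(dof / 2.0, chi2 / 2.0))
    return chi2, dof, p
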
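"""Statistical primitives for sponge-lncRNA inference.

The pipeline composes four tests: a one-tailed hypergeometric (Fisher's
exact) test for shared miRNA-family enrichment, a one-tailed Pearson
correlation test for positive co-expression, Fisher's method for combining
the two p-values, and Benjamini-Hochberg FDR over the full pair list.
Differential expression between disease states uses the two-tailed
Mann-Whitney U test.

All p-values are floored at the smallest positive representable double so
that log-transforms (Fisher's method) remain finite; a p-value of exactly
zero is never returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "fisher_share_test",
    "pearson_one_tailed",
    "fishers_method",
    "bh_fdr",
    "mann_whitney_two_tailed",
    "ConstantVectorError",
    "P_FLOOR",
]

#: Smallest positive double; p-values are clipped to [P_FLOOR, 1].
P_FLOOR = np.nextafter(0.0, 1.0)


class ConstantVectorError(ValueError):
    """Correlation is undefined for a constant expression vector."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    Attributes
    ----------
    statistic : float
        Test statistic (shared count k, Pearson r, or Mann-Whitney U).
    p_value : float
        p-value in (0, 1].
    tail : str
        ``"one_sided_greater"`` or ``"two_sided"``.
    n : int
        Sample/problem size the statistic was computed on.
    """

    statistic: float
    p_value: float
    tail: str
    n: int


def _clip_p(p: float) -> float:
    return float(min(1.0, max(P_FLOOR, p)))


def fisher_share_test(k_shared: int, m_lnc: int, n_pcg: int, N_universe: int) -> TestResult:
    """One-tailed Fisher's exact test for shared miRNA-family enrichment.

    Tests whether a lncRNA targeted by ``m_lnc`` families and a
    protein-coding gene targeted by ``n_pcg`` families, out of a universe
    of ``N_universe`` families, share more families (``k_shared``) than
    expected by chance.  The p-value is the upper hypergeometric tail
    ``P(X >= k_shared)`` with ``X ~ Hypergeom(N_universe, n_pcg, m_lnc)``,
    which equals the one-tailed 2x2 Fisher exact test on target /
    non-target membership.
    """
    if not (0 <= k_shared <= min(m_lnc, n_pcg) and max(m_lnc, n_pcg) <= N_universe):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k_shared}, m={m_lnc}, "
            f"n={n_pcg}, N={N_universe}"
        )
    if k_shared == 0:
        p = 1.0
    else:
        # sf(k-1) = P(X >= k)
        p = float(sps.hypergeom.sf(k_shared - 1, N_universe, n_pcg, m_lnc))
    return TestResult(statistic=float(k_shared), p_value=_clip_p(p), tail="one_sided_greater", n=N_universe)


def pearson_r_to_p_greater(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """Upper-tail p-value for H1: rho > 0 from a sample Pearson r at size n.

    Uses the exact t transform t = r * sqrt((n-2) / (1-r^2)) on n-2
    degrees of freedom.  Vectorized over r.
    """
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = np.clip(sps.t.sf(t, df=n - 2), P_FLOOR, 1.0)
    if p.ndim == 0:
        return float(p)
    return p


def pearson_one_tailed(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """One-tailed Pearson correlation test (H1: rho > 0).

    Raises
    ------
    ConstantVectorError
        If either vector is constant; the caller is expected to skip the
        gene pair with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"correlation requires n >= 3, got n={n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    p = float(np.asarray(pearson_r_to_p_greater(r, n)))
    return TestResult(statistic=r, p_value=_clip_p(p), tail="one_sided_greater", n=n)


def fishers_method(p1: float, p2: float) -> tuple[float, float]:
    """Combine two independent p-values by Fisher's method.

    chi2 = -2 (ln p1 + ln p2) is chi-square distributed with 4 degrees of
    freedom under the joint null; for df = 4 the upper tail has the closed
    form exp(-chi2/2) * (1 + chi2/2).

    Returns
    -------
    (chi2, p_combined)
    """
    if not (0.0 < p1 <= 1.0) or not (0.0 < p2 <= 1.0):
        raise ValueError(f"p-values must lie in (0, 1], got p1={p1}, p2={p2}")
    chi2 = -2.0 * (math.log(p1) + math.log(p2))
    p_comb = math.exp(-chi2 / 2.0) * (1.0 + chi2 / 2.0)
    return chi2, _clip_p(p_comb)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_two_tailed(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed Mann-Whitney U test between two samples.

    Uses the exact null distribution when min(|a|, |b|) <= 8 and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    and continuity corrections.  The statistic is U for sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=_clip_p(float(res.pvalue)),
        tail="two_sided",
        n=int(a.size + b.size),
    )
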
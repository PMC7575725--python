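"""Statistical primitives used by every screening stage.

The four evidence gates of the ceRNA screen all reduce to a handful of
classical statistics: a two-sample t-test on log2 expression, the Pearson
correlation with its Student-t significance transform, the hypergeometric
upper-tail probability for shared miRNA-target enrichment, and the
Benjamini-Hochberg step-up adjustment for multiplicity.

Conventions
-----------
* t-tests and correlation p-values are two-sided.
* The hypergeometric tail is one-sided and *inclusive*: ``P(X >= k)`` for
  ``X ~ Hypergeometric(N, K, n)``.  An enrichment question ("do these two
  RNAs share an unexpectedly high number of miRNAs?") is inherently
  one-sided, and including the observed count keeps ``k = 0 -> p = 1``
  exact.
* The tail sum is accumulated with log-gamma arithmetic so universes of
  1e5 miRNAs do not overflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError, ZeroVarianceError

__all__ = [
    "TestResult",
    "HypergeomParams",
    "two_sample_t",
    "pearson_r",
    "correlation_p",
    "hypergeom_upper_tail",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided location or correlation test.

    Attributes
    ----------
    statistic : float
        t (or r) statistic; sign follows ``mean(x) - mean(y)``.
    df : float
        Degrees of freedom of the reference distribution.
    p : float
        Two-sided p-value in [0, 1].
    degenerate : bool
        True when the inputs were flagged (e.g. both groups constant and
        equal, where ``p = 1`` is returned by convention).
    """

    statistic: float
    df: float
    p: float
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0) or self.df < 0:
            raise InvalidInputError(
                f"invalid TestResult: p={self.p}, df={self.df}"
            )


@dataclass(frozen=True)
class HypergeomParams:
    """Parameters of the shared-target hypergeometric test.

    ``N`` distinct miRNAs form the universe; the seed lncRNA targets ``K``
    of them, the candidate gene targets ``n``, and ``k`` are shared.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self):
        if self.N < 1:
            raise InvalidInputError(f"universe size N={self.N} must be >= 1")
        if not (0 <= self.K <= self.N):
            raise InvalidInputError(f"K={self.K} outside [0, N={self.N}]")
        if not (0 <= self.n <= self.N):
            raise InvalidInputError(f"n={self.n} outside [0, N={self.N}]")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise InvalidInputError(
                f"k={self.k} outside [0, min(K={self.K}, n={self.n})]"
            )


def _as_1d(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def two_sample_t(x, y, variant: str = "pooled") -> TestResult:
    """Two-sided two-sample t-test for a difference in means.

    Parameters
    ----------
    x, y : array-like
        The two groups (each at least 2 observations).
    variant : {"pooled", "welch"}
        ``pooled`` assumes equal variances (df = nx + ny - 2); ``welch``
        uses the Satterthwaite approximation.

    Returns
    -------
    TestResult
        Statistic signed as ``mean(x) - mean(y)``.  When both groups have
        zero variance and equal means the comparison is vacuous and
        ``p = 1`` is returned with ``degenerate=True``.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise InvalidInputError("each group needs at least 2 observations")
    if variant not in ("pooled", "welch"):
        raise InvalidInputError(f"unknown variant {variant!r}")

    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vx == 0.0 and vy == 0.0:
        if np.mean(x) == np.mean(y):
            df = len(x) + len(y) - 2 if variant == "pooled" else 0.0
            return TestResult(0.0, float(df), 1.0, degenerate=True)
        # Zero noise but distinct means: evidence is infinitely strong.
        sign = math.copysign(1.0, float(np.mean(x) - np.mean(y)))
        df = len(x) + len(y) - 2 if variant == "pooled" else 0.0
        return TestResult(sign * math.inf, float(df), 0.0, degenerate=True)

    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors.

    Raises
    ------
    ZeroVarianceError
        If either vector is constant (the correlation is undefined;
        screening callers skip such genes with a warning).
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) != len(y):
        raise InvalidInputError("x and y must have equal length")
    if len(x) < 3:
        raise InvalidInputError("correlation needs at least 3 paired samples")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    # guard against tiny numerical excursions outside [-1, 1]
    return min(1.0, max(-1.0, r))


def correlation_p(r: float, n_samples: int) -> float:
    """Two-sided p-value for the null hypothesis of zero correlation.

    Uses the exact finite-sample transform ``t = r * sqrt(n-2) / sqrt(1-r^2)``
    referred to a Student-t distribution with ``n - 2`` degrees of freedom.

    ``|r| = 1`` is degenerate (the t statistic diverges); ``p = 0`` is
    returned with a warning.
    """
    if n_samples < 3:
        raise InvalidInputError("correlation test needs n_samples >= 3")
    if not -1.0 <= r <= 1.0:
        raise InvalidInputError(f"correlation r={r} outside [-1, 1]")
    if abs(r) == 1.0:
        warnings.warn(
            "|r| = 1: degenerate (perfectly collinear) input, returning p = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    df = n_samples - 2
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df))


def _log_comb(a: float, b: float) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeom_upper_tail(params: HypergeomParams) -> float:
    """Inclusive upper-tail probability ``P(X >= k)`` of a hypergeometric draw.

    ``X`` counts the overlap when ``n`` items are drawn without replacement
    from a universe of ``N`` containing ``K`` marked items.  The tail is
    summed in log space (log-gamma binomials), which is stable for
    universes up to at least 1e5 miRNAs.
    """
    N, K, n, k = params.N, params.K, params.n, params.k
    if k == 0:
        return 1.0
    denom = _log_comb(N, n)
    hi = min(K, n)
    # Largest index with a non-zero PMF is hi; smallest is max(0, n-(N-K)).
    total = 0.0
    for j in range(k, hi + 1):
        if n - j > N - K:
            continue
        total += math.exp(_log_comb(K, j) + _log_comb(N - K, n - j) - denom)
    return min(1.0, max(0.0, total))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Missing entries (NaN) are excluded from the adjustment and restored as
    NaN in the output.  Values outside [0, 1] raise.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.sum() > 0:
        _, q, _, _ = multipletests(p[mask], method="fdr_bh")
        out[mask] = q
    return out
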
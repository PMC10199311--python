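"""Coupon-collector statistics for signature-gene detection.

The detection model: a sample assigns ``k`` reads to a set of ``n``
signature genes, each read landing on each gene with equal probability
(after gene-length normalization) and independently of the other reads.
The number of *distinct* genes observed, ``D``, then follows a variant of
the coupon collector's problem:

    P(D = d | k, n) = C(n, d) * S(k, d) * d! / n**k

where ``S(k, d)`` is the Stirling number of the second kind (the number of
ways to partition the k reads into d non-empty groups).  Everything here is
evaluated in log space, so the probabilities remain exact to floating
precision for any ``k`` up to the large-``k`` cutoff where the tail is
degenerate anyway.

The cumulative left tail ``P(D <= d)`` is the per-sample quality-control
statistic: a sample whose observed number of unique signature genes is
improbably low, given how many reads it assigned to the set, carries a
skewed gene representation (e.g. strain-level gene absence).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "log_stirling2",
    "ccp_pmf",
    "ccp_pmf_all",
    "ccp_cdf",
    "ccp_pvalue",
    "ccp_bootstrap",
    "ccp_bootstrap_cdf",
    "bootstrap_pmf_grid",
    "p_zero",
    "expected_unique",
    "LARGE_K_CUTOFF",
    "DEFAULT_BOOTSTRAP_SEED",
    "DEFAULT_BOOTSTRAP_ITERATIONS",
]

#: Above this read count the left tail is degenerate: observing fewer than
#: n distinct genes out of n is (numerically) impossible under the null,
#: so P(D = n) ~ 1 and the cumulative probability of any d < n is ~ 0.
LARGE_K_CUTOFF = 3000

#: Fixed default seed for the bootstrap backend, so that bootstrap results
#: are reproducible without configuration.
DEFAULT_BOOTSTRAP_SEED = 20230508

DEFAULT_BOOTSTRAP_ITERATIONS = 100_000


class _StirlingTable:
    """Memoized triangular table of log S(k, d).

    Built by the standard recurrence S(k, d) = d*S(k-1, d) + S(k-1, d-1)
    with S(0, 0) = 1, evaluated as a log-sum-exp so that entries never
    overflow.  The table grows geometrically on demand and only up to the
    largest d ever requested: the recurrence for column d touches columns
    <= d only, so a rectangular (k, d) slab is self-contained.
    """

    def __init__(self) -> None:
        self._table = np.zeros((1, 1))  # log S(0,0) = 0

    def ensure(self, max_k: int, max_d: int) -> np.ndarray:
        have_k, have_d = self._table.shape
        if max_k < have_k and max_d < have_d:
            return self._table
        # Grow each dimension only when it is actually exceeded (doubling
        # the k axis to amortize rebuilds).
        new_k = have_k if max_k < have_k else max(max_k + 1, 2 * have_k)
        new_d = have_d if max_d < have_d else max_d + 1
        table = np.full((new_k, new_d), -np.inf)
        table[0, 0] = 0.0
        with np.errstate(divide="ignore"):
            log_d = np.log(np.arange(new_d))
        for k in range(1, new_k):
            prev = table[k - 1]
            # S(k,0) = 0 for k > 0; column 0 stays -inf.
            table[k, 1:] = np.logaddexp(log_d[1:] + prev[1:], prev[:-1])
        self._table = table
        return table

    def row(self, k: int, max_d: int) -> np.ndarray:
        return self.ensure(k, max_d)[k, : max_d + 1]


_TABLE = _StirlingTable()


def _check_int(value, name: str, minimum: int) -> int:
    if not float(value).is_integer():
        raise ValueError(f"{name} must be an integer, got {value!r}")
    value = int(value)
    if value < minimum:
        raise ValueError(f"{name} must be >= {minimum}, got {value}")
    return value


def log_stirling2(k: int, d: int) -> float:
    """Return log S(k, d), the log Stirling number of the second kind.

    Total function: returns ``-inf`` whenever S(k, d) = 0 (d > k, or d = 0
    with k > 0).
    """
    k = _check_int(k, "k", 0)
    d = _check_int(d, "d", 0)
    if d > k:
        return -np.inf
    return float(_TABLE.ensure(k, d)[k, d])


def _log_pmf_row(k: int, n: int) -> np.ndarray:
    """log P(D = d | k, n) for d = 0..min(k, n), as a vector."""
    d_max = min(k, n)
    d = np.arange(d_max + 1)
    log_s = _TABLE.row(k, d_max)
    # log C(n,d) + log d! = gammaln(n+1) - gammaln(n-d+1)
    return gammaln(n + 1) - gammaln(n - d + 1) + log_s - k * np.log(n)


def ccp_pmf(d: int, k: int, n: int) -> float:
    """Probability of seeing exactly ``d`` distinct genes in ``k`` uniform
    draws with replacement from ``n`` genes."""
    n = _check_int(n, "n", 1)
    k = _check_int(k, "k", 0)
    d = _check_int(d, "d", 0)
    if d > min(k, n):
        return 0.0
    return float(np.exp(_log_pmf_row(k, n)[d]))


def ccp_pmf_all(k: int, n: int) -> np.ndarray:
    """Vector of P(D = d | k, n) over d = 0..min(k, n)."""
    n = _check_int(n, "n", 1)
    k = _check_int(k, "k", 0)
    return np.exp(_log_pmf_row(k, n))


def ccp_cdf(d: int, k: int, n: int) -> float:
    """Cumulative left tail P(D <= d | k, n)."""
    n = _check_int(n, "n", 1)
    k = _check_int(k, "k", 0)
    d = _check_int(d, "d", 0)
    if d >= min(k, n):
        return 1.0
    row = _log_pmf_row(k, n)
    total = np.exp(row[: d + 1]).sum()
    return float(min(total, 1.0))


def ccp_pvalue(d_obs: int, k: int, n_test: int = 95) -> float:
    """Per-sample QC tail probability P(D <= d_obs | k, n_test).

    Observing at least ``n_test`` unique genes can never be evidence of
    depletion, so the p-value is 1 whenever ``d_obs >= n_test``.  For
    ``k >= LARGE_K_CUTOFF`` the tail is degenerate and the left tail of any
    d_obs < n_test is ~0.  Observations with ``d_obs > k`` are impossible
    (each read detects at most one new gene) and raise.
    """
    n_test = _check_int(n_test, "n_test", 1)
    k = _check_int(k, "k", 0)
    d_obs = _check_int(d_obs, "d_obs", 0)
    if d_obs > k:
        raise ValueError(
            f"impossible observation: d_obs={d_obs} unique genes from k={k} reads"
        )
    if d_obs >= n_test:
        return 1.0
    if k >= LARGE_K_CUTOFF:
        return 0.0
    return ccp_cdf(d_obs, k, n_test)


def ccp_bootstrap(
    d: int,
    k: int,
    n: int,
    iterations: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> float:
    """Monte-Carlo estimate of P(D = d | k, n).

    Draws ``k`` gene indices uniformly with replacement, ``iterations``
    times, and returns the fraction of iterations yielding exactly ``d``
    distinct genes.  Deterministic for a fixed seed.
    """
    n = _check_int(n, "n", 1)
    k = _check_int(k, "k", 0)
    d = _check_int(d, "d", 0)
    iterations = _check_int(iterations, "iterations", 1)
    if k == 0:
        return 1.0 if d == 0 else 0.0
    rng = np.random.default_rng(seed)
    hits = 0
    # Chunk to bound memory at ~16 MB regardless of k * iterations.
    chunk = max(1, 2_000_000 // k)
    done = 0
    while done < iterations:
        size = min(chunk, iterations - done)
        draws = np.sort(rng.integers(0, n, size=(size, k)), axis=1)
        uniques = 1 + (np.diff(draws, axis=1) > 0).sum(axis=1)
        hits += int((uniques == d).sum())
        done += size
    return hits / iterations


def ccp_bootstrap_cdf(
    d: int,
    k: int,
    n: int,
    iterations: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> float:
    """Monte-Carlo estimate of the left tail P(D <= d | k, n)."""
    n = _check_int(n, "n", 1)
    k = _check_int(k, "k", 0)
    d = _check_int(d, "d", 0)
    iterations = _check_int(iterations, "iterations", 1)
    if k == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, 2_000_000 // k)
    done = 0
    while done < iterations:
        size = min(chunk, iterations - done)
        draws = np.sort(rng.integers(0, n, size=(size, k)), axis=1)
        uniques = 1 + (np.diff(draws, axis=1) > 0).sum(axis=1)
        hits += int((uniques <= d).sum())
        done += size
    return hits / iterations


def bootstrap_pmf_grid(
    n: int,
    max_k: int,
    iterations: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> np.ndarray:
    """Bootstrap pmf of D for every k = 0..max_k at once.

    Runs ``iterations`` draw chains, extending each by one read per step,
    so the marginal distribution at step k is exactly that of k uniform
    draws.  Returns an array of shape (max_k+1, n+1) whose row k is the
    empirical pmf over d.
    """
    n = _check_int(n, "n", 1)
    max_k = _check_int(max_k, "max_k", 0)
    iterations = _check_int(iterations, "iterations", 1)
    rng = np.random.default_rng(seed)
    seen = np.zeros((iterations, n), dtype=bool)
    d = np.zeros(iterations, dtype=np.int64)
    rows = np.arange(iterations)
    out = np.zeros((max_k + 1, n + 1))
    out[0, 0] = 1.0
    for k in range(1, max_k + 1):
        idx = rng.integers(0, n, size=iterations)
        d += ~seen[rows, idx]
        seen[rows, idx] = True
        out[k] = np.bincount(d, minlength=n + 1) / iterations
    return out


def p_zero(k: int, n: int) -> tuple[float, float]:
    """(P0, P1): probability a given gene is missed / detected by k reads.

    P0 = ((n-1)/n)**k under uniform independent mapping; P1 = 1 - P0.
    """
    n = _check_int(n, "n", 1)
    k = _check_int(k, "k", 0)
    p0 = ((n - 1) / n) ** k
    return p0, 1.0 - p0


def expected_unique(k, n: int):
    """Expected number of distinct genes detected by ``k`` uniform reads.

    E[D] = n * (1 - ((n-1)/n)**k).  ``k`` may be a scalar or an array;
    the result matches its shape.
    """
    n = _check_int(n, "n", 1)
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("k must be >= 0")
    result = n * (1.0 - ((n - 1) / n) ** k_arr)
    if np.isscalar(k) or k_arr.ndim == 0:
        return float(result)
    return result
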
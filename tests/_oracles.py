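"""Independent oracles for the coupon-collector distribution.

Both are derived without Stirling numbers, so they can certify the
analytic pmf: a birthday-style Markov chain on the number of distinct
items seen, and literal enumeration of all n**k equally likely draw
sequences.
"""

import numpy as np

_POPCOUNT = np.array([bin(i).count("1") for i in range(256)], dtype=np.int64)


def chain_pmf(k: int, n: int) -> np.ndarray:
    """Distribution of distinct items after k draws, via the exact Markov
    chain: from d distinct, the next draw repeats with probability d/n and
    discovers a new item with probability (n-d)/n."""
    p = np.zeros(n + 1)
    p[0] = 1.0
    d = np.arange(n + 1)
    for _ in range(k):
        q = p * d / n
        q[1:] += p[:-1] * (n - d[:-1]) / n
        p = q
    return p


def enum_pmf(k: int, n: int, chunk: int = 1 << 20) -> np.ndarray:
    """Distribution of distinct items by brute-force enumeration of all
    n**k draw sequences (each equally likely), counted in chunks via an
    occupancy bitmask.  Feasible for n <= 6, k <= 10."""
    if n > 8:
        raise ValueError("enumeration oracle limited to n <= 8")
    total = n**k
    counts = np.zeros(n + 1, dtype=np.int64)
    powers = n ** np.arange(k)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        mask = np.zeros(idx.shape, dtype=np.uint8)
        for j in range(k):
            digit = (idx // powers[j]) % n
            mask |= (1 << digit).astype(np.uint8)
        counts += np.bincount(_POPCOUNT[mask], minlength=n + 1)
    return counts / total
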
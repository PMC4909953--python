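"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exact rational
arithmetic for the hypergeometric enumeration and a direct O(m^2)
transcription of the Benjamini-Hochberg step-up definition.
"""

from fractions import Fraction
from math import comb

import numpy as np

#: relative tie tolerance shared with the implementation's definition
TIE = Fraction(10_000_001, 10_000_000)  # 1 + 1e-7


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration in exact fractions."""
    N, K, n = a + b + c + d, a + c, a + b
    if N == 0:
        return 1.0
    denom = comb(N, n)
    lo, hi = max(0, n + K - N), min(n, K)
    pmf = {k: Fraction(comb(K, k) * comb(N - K, n - k), denom) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    total = sum(p for p in pmf.values() if p <= p_obs * TIE)
    return float(min(total, Fraction(1)))


def bh_step_up_naive(p_values) -> np.ndarray:
    """BH adjusted q-values by the literal definition, O(m^2)."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [
        min(min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0)
        for i in range(m)
    ]
    q = np.empty(m)
    for rank, idx in enumerate(order):
        q[idx] = q_sorted[rank]
    return q


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))
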
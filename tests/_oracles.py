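"""Independent brute-force oracles used to validate the package's statistics.

These deliberately avoid the package's own code paths: the Fisher oracle
enumerates hypergeometric point masses with exact integer combinatorics, and
the essentialome oracle counts per-gene calls directly off the raw matrix.
"""

from math import comb

import numpy as np

#: integer-arithmetic version of the 1e-7 relative tie tolerance:
#: include x iff mass(x) * 1e7 <= mass(k) * (1e7 + 1)
_TIE_NUM = 10**7


def fisher_oracle(N: int, K: int, n: int, k: int) -> float:
    """Two-sided Fisher p by exact integer enumeration (minimum-likelihood rule)."""
    if n == 0 or K == 0 or K == N or n == N:
        return 1.0
    lo, hi = max(0, n + K - N), min(n, K)
    masses = [comb(K, x) * comb(N - K, n - x) for x in range(lo, hi + 1)]
    mk = masses[k - lo]
    total = sum(m for m in masses if m * _TIE_NUM <= mk * (_TIE_NUM + 1))
    return total / comb(N, n)


def essentialome_oracle(calls: np.ndarray, fraction: float = 0.95):
    """(total, core, majority) gene-index sets by direct per-gene counting.

    ``calls`` is a gene x line array of 0/1/NaN.  A gene is in a line's
    essentialome iff its call is exactly 1; missing never counts.
    """
    import math

    n_genes, n_lines = calls.shape
    cutoff = math.ceil(fraction * n_lines)
    total, core, majority = set(), set(), set()
    for g in range(n_genes):
        row = calls[g]
        ones = int(np.nansum(row == 1.0))
        if ones >= 1:
            total.add(g)
        if ones == n_lines:
            core.add(g)
        if ones >= cutoff:
            majority.add(g)
    return total, core, majority
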
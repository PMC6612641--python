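"""Independent brute-force oracles shared by the test modules."""

import math
from fractions import Fraction


def running_sum_oracle(positions, n):
    """Sup deviations between the gene set's and the universe's cumulative
    step functions, enumerated in exact rational arithmetic, normalized so
    the extremes are +/-1."""
    t = len(positions)
    members = set(positions)
    H = [Fraction(0)] * (n + 1)
    for i in range(1, n + 1):
        H[i] = H[i - 1] + (Fraction(1, t) if i in members else Fraction(0))
    a = max(H[i] - Fraction(i - 1, n) for i in range(1, n + 1))
    b = max(Fraction(i, n) - H[i - 1] for i in range(1, n + 1))
    if a > b:
        raw = a
    elif b > a:
        raw = -b
    else:
        raw = Fraction(0)
    return float(raw / Fraction(n - t + 1, n))


def binomial_two_sided_oracle(k, n):
    """Exact enumeration of the two-sided binomial test at p = 0.5."""
    pk = math.comb(n, k) * 0.5**n
    return min(
        1.0,
        sum(
            math.comb(n, i) * 0.5**n
            for i in range(n + 1)
            if math.comb(n, i) * 0.5**n <= pk + 1e-12
        ),
    )


def hypergeom_tail_oracle(k, M, K, N):
    """Direct summation of the hypergeometric upper tail P(X >= k)."""
    return sum(
        math.comb(K, i) * math.comb(M - K, N - i) / math.comb(M, N)
        for i in range(k, min(K, N) + 1)
    )
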
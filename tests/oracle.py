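"""Independent brute-force oracles used by the tests.

Exact-rational evaluation of the urn-product pmf with ``fractions``:
slow, but free of floating-point error, and written directly from the
defining product rather than any code path it checks.
"""

from fractions import Fraction
from math import comb


def pmf_exact(m: int, n: int, alpha, beta, d) -> Fraction:
    """Defining product of the extended family, in exact arithmetic."""
    alpha, beta, d = Fraction(alpha), Fraction(beta), Fraction(d)
    num = Fraction(1)
    for i in range(m):
        num *= alpha + i * d
    for j in range(n - m):
        num *= beta + j * d
    den = Fraction(1)
    for k in range(n):
        den *= alpha + beta + k * d
    return comb(n, m) * num / den


def params_valid(n: int, alpha, beta, d) -> bool:
    """All denominator factors positive and no negative urn factor."""
    alpha, beta, d = Fraction(alpha), Fraction(beta), Fraction(d)
    if any(alpha + beta + k * d <= 0 for k in range(n)):
        return False
    first_zero_a = next((i for i in range(n) if alpha + i * d == 0), n)
    first_zero_b = next((j for j in range(n) if beta + j * d == 0), n)
    if any(alpha + i * d < 0 for i in range(first_zero_a)):
        return False
    if any(beta + j * d < 0 for j in range(first_zero_b)):
        return False
    return True


def shape_to_rational(ai, q, n):
    """(alpha, beta, d) as Fractions for exact shape-parameterised checks."""
    ai, q = Fraction(ai), Fraction(q)
    return ai, 1 - ai, (q - 1) / (n - q)
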
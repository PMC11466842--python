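"""Independent numeric oracles used by several test modules."""

import math
from decimal import Decimal, localcontext


def exact_binomial_tail(c: int, n: int, e: float) -> float:
    """P(X >= c) for X ~ Binomial(n, e) by direct pmf summation in
    60-digit decimal arithmetic (ascending recursion from the first term,
    no cancellation, no float underflow)."""
    if c == 0:
        return 1.0
    if e == 0.0:
        return 0.0
    if e == 1.0:
        return 1.0
    with localcontext() as ctx:
        ctx.prec = 60
        ctx.Emin = -(10**7)
        ctx.Emax = 10**7
        ed = Decimal(str(e))
        q = 1 - ed
        pmf = Decimal(math.comb(n, c)) * ed**c * q ** (n - c)
        total = pmf
        for k in range(c, n):
            pmf = pmf * (n - k) / (k + 1) * ed / q
            total += pmf
            if pmf < total * Decimal("1e-45"):
                break
        return float(total)
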
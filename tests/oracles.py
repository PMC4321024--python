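"""Independent brute-force oracles used by the test suite.

Everything here is computed with the Python standard library (math.lgamma,
plain loops) so it shares no code path with the vectorized scipy
implementation it checks.
"""

import math


def nb_pmf_oracle(y: int, mean: float, phi: float) -> float:
    """Closed-form NB mass with variance mean + phi*mean**2."""
    if phi == 0.0:
        return math.exp(-mean + y * math.log(mean) - math.lgamma(y + 1))
    r = 1.0 / phi
    p = r / (r + mean)
    return (
        math.exp(math.lgamma(y + r) - math.lgamma(r) - math.lgamma(y + 1))
        * p ** r * (1.0 - p) ** y
    )


def conditional_exact_oracle(y1: int, y2: int, n1: float, n2: float, bcv: float) -> float:
    """Exhaustive enumeration of the conditional two-sided exact p-value."""
    s = y1 + y2
    if s == 0:
        return 1.0
    p_hat = s / (n1 + n2)
    m1, m2 = p_hat * n1, p_hat * n2
    phi = bcv * bcv
    weights = [nb_pmf_oracle(y, m1, phi) * nb_pmf_oracle(s - y, m2, phi) for y in range(s + 1)]
    total = sum(weights)
    cond = [w / total for w in weights]
    observed = cond[y1]
    p = sum(w for w in cond if w <= observed * (1.0 + 1e-7))
    return min(1.0, p)


def bh_oracle(pvalues: list[float]) -> list[float]:
    """Step-up BH adjustment by direct definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted
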
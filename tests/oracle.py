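"""Independent brute-force evaluation of the 2×2 disproportionality
statistics, used only as a cross-check oracle.

Deliberately written against the algebraic definitions with exact rational
arithmetic (``fractions.Fraction``) for every ratio, converting to float
only at the final transcendental step — a different code path from the
pipeline's float evaluation.
"""
from __future__ import annotations

import math
from fractions import Fraction as F


def oracle_stats(a: int, b: int, c: int, d: int,
                 z2: float = 1.96, z1: float = 1.64,
                 alpha1: int = 1, alpha2: int = 1,
                 beta1: int = 1, beta2: int = 1,
                 gamma11: int = 1) -> dict:
    """All statistics for one all-positive-cell table."""
    assert min(a, b, c, d) > 0
    n = a + b + c + d
    out = {}

    ror = F(a * d, b * c)
    se = math.sqrt(float(F(1, a) + F(1, b) + F(1, c) + F(1, d)))
    out["ror"] = float(ror)
    out["ror_ci_low"] = math.exp(math.log(float(ror)) - z2 * se)
    out["ror_ci_high"] = math.exp(math.log(float(ror)) + z2 * se)

    out["prr"] = float(F(a * (c + d), c * (a + b)))
    out["chi2"] = float(F((a * d - b * c) ** 2 * n,
                          (a + b) * (a + c) * (c + d) * (b + d)))

    ebgm = F(a * n, (a + b) * (a + c))
    out["ebgm"] = float(ebgm)
    out["ebgm05"] = math.exp(math.log(float(ebgm)) - z1 * se)

    alpha = alpha1 + alpha2
    beta = beta1 + beta2
    row = a + b + alpha1
    col = a + c + beta1
    out["ic"] = math.log2(float(ebgm))
    gamma = F(gamma11 * (n + alpha) * (n + beta), row * col)
    eic_arg = F((a + gamma11) * (n + alpha) * (n + beta)) / (
        (n + gamma) * row * col)
    out["eic"] = math.log2(float(eic_arg))
    vic_rational = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (n + 1 + gamma))
        + F(n - a - b + alpha - alpha1, row * (n + 1 + alpha))
        + F(n - a - c + beta - beta1, col * (n + 1 + beta)))
    vic = float(vic_rational) / math.log(2.0) ** 2
    out["vic"] = vic
    out["ic025"] = out["eic"] - z2 * math.sqrt(vic)
    out["ic975"] = out["eic"] + z2 * math.sqrt(vic)
    return out


def random_tables(rng, n_tables: int, lo: int = 1, hi: int = 10 ** 6):
    """Log-uniform random tables with every cell in [lo, hi]."""
    import numpy as np

    cells = np.floor(10 ** rng.uniform(
        math.log10(lo), math.log10(hi + 1), size=(n_tables, 4))).astype(int)
    cells = np.clip(cells, lo, hi)
    return [tuple(int(x) for x in row) for row in cells]
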
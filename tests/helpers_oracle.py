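"""Independent brute-force oracle for the piecewise Guinier-Porod terms.

This deliberately avoids the closed-form crossover/scale formulas used by
the package: crossovers are found by numeric root-finding on the branch
log-slope conditions, and the joining scales follow from evaluating the
neighbouring branch at the crossover. Used to cross-check the forward
model to tight relative tolerance.
"""

import numpy as np
from scipy.optimize import brentq


def gp1_oracle(G, Rg, d, q):
    """One-level Guinier-Porod by numeric crossover construction."""

    def guinier(x):
        return G * np.exp(-(x ** 2) * Rg ** 2 / 3.0)

    # slope-matching: d ln(guinier)/d ln q = -2 q^2 Rg^2 / 3 equals -d
    q1 = brentq(lambda x: 2.0 * x * x * Rg * Rg / 3.0 - d, 1e-9 / Rg, 1e9 / Rg)
    D = guinier(q1) * q1 ** d  # value continuity
    q = np.asarray(q, dtype=float)
    return np.where(q <= q1, guinier(q), D * q ** (-d))


def cylinder_oracle(G1, Rg1, Rg2, d, q):
    """Two-level cylinder Guinier-Porod by numeric crossover construction."""

    def rod(x):
        return G1 / x * np.exp(-(x ** 2) * Rg1 ** 2 / 2.0)

    # rod branch log-slope is -1 - q^2 Rg1^2; Porod crossover where it hits -d
    q1 = brentq(lambda x: 1.0 + x * x * Rg1 * Rg1 - d, 1e-9 / Rg1, 1e9 / Rg1)
    D = rod(q1) * q1 ** d
    # low-q crossover as defined from the radii of gyration
    q2 = ((2.0 / 3.0) * Rg2 ** 2 - Rg1 ** 2) ** -0.5
    G2 = rod(q2) * np.exp(q2 ** 2 * Rg2 ** 2 / 3.0)  # value continuity

    def guinier(x):
        return G2 * np.exp(-(x ** 2) * Rg2 ** 2 / 3.0)

    q = np.asarray(q, dtype=float)
    return np.where(q <= q2, guinier(q), np.where(q <= q1, rod(q), D * q ** (-d)))


def draw_gp1_params(rng):
    G = 10.0 ** rng.uniform(-2, 4)
    Rg = 10.0 ** rng.uniform(0.5, 2)
    d = rng.uniform(1.51, 4.0)
    return G, Rg, d


def draw_cylinder_params(rng):
    G1 = 10.0 ** rng.uniform(-2, 2)
    Rg1 = 10.0 ** rng.uniform(-0.5, 0.7)
    d = rng.uniform(1.51, 4.0)
    # q2 < q1 requires (2/3) Rg2^2 - Rg1^2 > Rg1^2 / (d - 1)
    min_ratio = np.sqrt(1.5 * (1.0 + 1.0 / (d - 1.0)))
    Rg2 = Rg1 * min_ratio * (1.05 + rng.uniform(0, 9))
    return G1, Rg1, Rg2, d
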
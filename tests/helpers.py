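"""Shared independent oracles for the test suite.

These deliberately avoid the package's own integration path: the RK4
stepper below is a plain fixed-step scheme used to cross-check the adaptive
solver, and the arithmetic oracles use exact rational arithmetic.
"""

from fractions import Fraction

import numpy as np


def rk4_integrate(rhs, y0, t_end, dt, sample_times):
    """Fixed-step classic Runge-Kutta; returns states at ``sample_times``.

    ``sample_times`` must be multiples of ``dt`` (within dt/2).
    """
    y = np.array(y0, dtype=float)
    n = int(round(t_end / dt))
    out = []
    sample = list(sample_times)
    next_idx = 0
    t = 0.0
    if sample and abs(sample[0] - 0.0) < dt / 2:
        out.append(y.copy())
        next_idx = 1
    for k in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (k + 1) * dt
        if next_idx < len(sample) and abs(t - sample[next_idx]) < dt / 2:
            out.append(y.copy())
            next_idx += 1
    assert next_idx == len(sample), "sample times not all hit"
    return np.array(out)


def exact_monod_quarter(mu_max, S, K_s):
    """Exact value of mu_max*S/(K_s+S)*(1/2)*(1/2) via rational arithmetic."""
    mu = Fraction(mu_max) * Fraction(S) / (Fraction(K_s) + Fraction(S))
    return float(mu / 4)


def exact_qpcr(dna_conc, genome_size, copies_16s, avogadro=Fraction(602214076) * 10**15):
    """Exact copies/mL: N_A * c * n16S / (genome * 660)."""
    val = (avogadro * Fraction(dna_conc) * copies_16s
           / (Fraction(genome_size) * 660))
    return float(val)
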
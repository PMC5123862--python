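"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own solution paths:
the two-species oracle solves the mass balance by root bracketing on
the complex concentration (not the quadratic), the three-species
oracle scans free receptor on a refined grid (not brentq on the same
residual the package uses... the residual is forced by mass balance,
but the search strategy is independent), and the ladder oracle runs a
molecule-level Monte-Carlo of the insertion chain.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq


def mass_balance_bound(rt: float, lt: float, kd: float) -> float:
    """Two-species bound complex by bracketing the mass balance
    (rt - c)(lt - c) = kd * c on c in [0, min(rt, lt)]."""
    hi = min(rt, lt)
    if hi == 0:
        return 0.0

    def f(c):
        return (rt - c) * (lt - c) - kd * c

    return brentq(f, 0.0, hi, xtol=1e-18, rtol=8.9e-16, maxiter=300)


def grid_search_bound_labeled(rt, lt, it, kd_l, kd_i, n_grid=20000):
    """Three-species bound labeled ligand by iterated grid refinement
    over free receptor (no derivative/bracketing solver)."""
    lo, hi = 0.0, rt
    for _ in range(8):
        grid = np.linspace(lo, hi, n_grid)
        resid = np.abs(grid * (1 + lt / (kd_l + grid) + it / (kd_i + grid)) - rt)
        k = int(np.argmin(resid))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, n_grid - 1)]
    rf = 0.5 * (lo + hi)
    return lt * rf / (kd_l + rf)


def ternary_exact_ic50(rt, lt, kd_l, ki):
    """Competitor concentration at which bound labeled ligand is half
    its competitor-free value, from the exact ternary equilibrium."""

    def bound(it):
        rf = brentq(
            lambda r: r * (1 + lt / (kd_l + r) + it / (ki + r)) - rt,
            0.0, rt, xtol=1e-15, rtol=8.9e-16)
        return lt * rf / (kd_l + rf)

    b0 = bound(0.0)
    return brentq(lambda it: bound(it) - 0.5 * b0, 1e-9, 1e12,
                  xtol=1e-9, rtol=1e-13)


def monte_carlo_ladder(p_i: dict, n_molecules: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Molecule-level simulation of the insertion chain.

    Each engaged molecule inserts nucleotide 1, then at each step i
    continues with probability P_i. Returns counts per final position
    (index j = 0..max step; j=0 stays 0 as all molecules are engaged).
    """
    jmax = max(p_i)
    counts = np.zeros(jmax + 1, dtype=int)
    for _ in range(n_molecules):
        j = 1
        while True:
            p_next = p_i.get(j + 1, 0.0)
            if rng.random() < p_next:
                j += 1
            else:
                break
        counts[j] += 1
    return counts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20161022)
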
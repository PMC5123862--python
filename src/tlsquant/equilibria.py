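"""Binding-equilibrium solvers.

Closed-form and numeric solutions of the mass-balance equations that
underlie every fit and every synthetic data set in this package:

* two-species equilibrium (receptor R + ligand L <-> complex C) with
  explicit ligand depletion — the substrate is concentrated enough that
  [L]_free < [L]_total, so the bound complex is the physical root of a
  quadratic rather than the dilute-limit hyperbola;
* three-species competitive equilibrium (labeled ligand and an unlabeled
  competitor both binding the same receptor), the forward model for
  dose-response competition experiments.

All concentrations are in nM throughout the package; unit conversion, if
any, happens at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TwoSpeciesSystem",
    "ThreeSpeciesSystem",
    "bound_complex",
    "bound_complex_concentrations",
    "free_ligand",
    "competitive_equilibrium",
    "EquilibriumError",
]


class EquilibriumError(ValueError):
    """Invalid concentrations/constants or a solver failure."""


@dataclass(frozen=True)
class TwoSpeciesSystem:
    """A receptor-ligand pair at equilibrium.

    Parameters
    ----------
    total_receptor : float
        Total receptor concentration R_T (nM).
    total_ligand : float
        Total (added) ligand concentration L_T (nM).
    kd : float
        Equilibrium dissociation constant K_D (nM), > 0.
    """

    total_receptor: float
    total_ligand: float
    kd: float

    def __post_init__(self) -> None:
        if self.total_receptor < 0 or self.total_ligand < 0:
            raise EquilibriumError(
                f"total concentrations must be >= 0, got "
                f"R_T={self.total_receptor}, L_T={self.total_ligand}"
            )
        if not self.kd > 0:
            raise EquilibriumError(f"kd must be > 0, got {self.kd}")


@dataclass(frozen=True)
class ThreeSpeciesSystem:
    """A receptor with a labeled ligand and an unlabeled competitor.

    Both ligands bind the same receptor site with independent
    dissociation constants; this is the forward model for a competition
    titration of a pre-assembled labeled complex.
    """

    total_receptor: float
    total_labeled_ligand: float
    total_competitor: float
    kd_labeled: float
    kd_competitor: float

    def __post_init__(self) -> None:
        for name in ("total_receptor", "total_labeled_ligand", "total_competitor"):
            if getattr(self, name) < 0:
                raise EquilibriumError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (self.kd_labeled > 0 and self.kd_competitor > 0):
            raise EquilibriumError("both dissociation constants must be > 0")


def bound_complex_concentrations(total_receptor, total_ligand, kd):
    """Bound-complex concentration for the two-species equilibrium.

    Vectorized over any argument. Solves the mass-balance quadratic

        C^2 - (R_T + L_T + K_D) C + R_T L_T = 0

    and returns the smaller (physical) root, written in the
    cancellation-free form 2 R_T L_T / (b + sqrt(b^2 - 4 R_T L_T)).
    """
    rt = np.asarray(total_receptor, dtype=float)
    lt = np.asarray(total_ligand, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if np.any(rt < 0) or np.any(lt < 0):
        raise EquilibriumError("total concentrations must be >= 0")
    if np.any(kd <= 0):
        raise EquilibriumError("kd must be > 0")
    b = rt + lt + kd
    disc = b * b - 4.0 * rt * lt
    # disc >= kd^2 > 0 analytically; clip guards rounding
    root = np.sqrt(np.clip(disc, 0.0, None))
    out = np.where(b + root > 0, 2.0 * rt * lt / (b + root), 0.0)
    # the smaller root can never exceed either total
    out = np.minimum(out, np.minimum(rt, lt))
    if out.ndim == 0:
        return float(out)
    return out


def bound_complex(system: TwoSpeciesSystem) -> float:
    """Equilibrium concentration of the receptor-ligand complex (nM).

    Returns the physically meaningful root of the depletion quadratic;
    0 <= C <= min(R_T, L_T) always holds.
    """
    return bound_complex_concentrations(
        system.total_receptor, system.total_ligand, system.kd
    )


def free_ligand(total_ligand: float, bound: float) -> float:
    """Free-ligand concentration L_T - C (nM).

    Raises if ``bound`` exceeds ``total_ligand`` or is negative.
    """
    if bound < 0:
        raise EquilibriumError(f"bound must be >= 0, got {bound}")
    if bound > total_ligand:
        raise EquilibriumError(
            f"bound ({bound}) exceeds total ligand ({total_ligand})"
        )
    return total_ligand - bound


def competitive_equilibrium(system: ThreeSpeciesSystem) -> dict:
    """Solve the three-species competitive equilibrium.

    Finds the free-receptor concentration R_f by monotone bracketing of
    the receptor mass balance

        R_f (1 + L_T/(K_D + R_f) + I_T/(K_i + R_f)) = R_T

    (each ligand's own mass balance is substituted in, so all three
    balances and both K_D relations hold at the root by construction).

    Returns
    -------
    dict with keys ``bound_labeled``, ``bound_competitor``,
    ``free_receptor`` (nM).
    """
    rt = system.total_receptor
    lt = system.total_labeled_ligand
    it = system.total_competitor
    kdl = system.kd_labeled
    kdi = system.kd_competitor

    if rt == 0.0:
        return {"bound_labeled": 0.0, "bound_competitor": 0.0, "free_receptor": 0.0}

    def balance(rf: float) -> float:
        return rf * (1.0 + lt / (kdl + rf) + it / (kdi + rf)) - rt

    # balance is strictly increasing in rf; balance(0) = -rt < 0,
    # balance(rt) >= 0, so [0, rt] brackets the unique root.
    try:
        rf = brentq(balance, 0.0, rt, xtol=1e-15, rtol=8.881784197001252e-16,
                    maxiter=200)
    except Exception as exc:  # pragma: no cover - defensive
        raise EquilibriumError(
            f"three-species solver failed to converge for "
            f"R_T={rt}, L_T={lt}, I_T={it}, K_D={kdl}, K_i={kdi}: {exc}"
        ) from exc
    return {
        "bound_labeled": lt * rf / (kdl + rf),
        "bound_competitor": it * rf / (kdi + rf),
        "free_receptor": rf,
    }
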
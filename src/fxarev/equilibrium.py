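"""Coupled binding equilibria for an enzyme–inhibitor–decoy system.

The chemical model is the rapid-equilibrium, initial-rate description of a
chromogenic protease assay in which a small-molecule inhibitor I both
inhibits the enzyme E competitively and is sequestered by a catalytically
dead decoy protein A:

    E + S <-> ES    (Michaelis constant Km, μM)
    E + I <-> EI    (inhibition constant Ki, nM)
    A + I <-> AI    (decoy dissociation constant Kd, nM)

The decoy is inert toward enzyme and substrate, and the substrate is
treated as non-depleted (free S equals total S; S exceeds E by more than
four orders of magnitude in the assays this models). Under those
assumptions the whole system reduces to one monotone scalar equation in
the free inhibitor concentration, solved by bracketed root finding on
[0, I_total] — robust in the tight-binding regime where the free ≈ total
approximation fails.

Concentrations of E/I/A species are in nM; S and Km are in μM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "NO_BINDING",
    "ConvergenceError",
    "EquilibriumSystem",
    "SpeciesState",
    "solve_species_equilibrium",
    "oracle_solve",
    "unbound_inhibitor_fraction",
]

#: Sentinel dissociation constant meaning "no binding" (Ki or Kd = ∞).
NO_BINDING = math.inf

# Relative mass-balance tolerance a converged state must satisfy.
_BALANCE_RTOL = 1e-9


class ConvergenceError(RuntimeError):
    """Raised when an equilibrium or fit has not converged."""


@dataclass(frozen=True)
class EquilibriumSystem:
    """Total concentrations and binding constants for one assay well.

    Parameters
    ----------
    E_total, I_total, A_total : float
        Total enzyme, inhibitor and decoy concentrations in nM.
    S_total : float
        Total chromogenic substrate concentration in μM.
    Km : float
        Michaelis constant of the enzyme for the substrate, μM.
    Ki : float
        Enzyme–inhibitor dissociation constant, nM. ``NO_BINDING``
        (infinity) disables the E·I equilibrium.
    Kd : float
        Decoy–inhibitor dissociation constant, nM. ``NO_BINDING``
        disables the A·I equilibrium.
    """

    E_total: float
    I_total: float
    A_total: float
    S_total: float
    Km: float = 82.2
    Ki: float = NO_BINDING
    Kd: float = NO_BINDING

    def __post_init__(self) -> None:
        for name in ("E_total", "I_total", "A_total", "S_total"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        for name in ("Km", "Ki", "Kd"):
            value = getattr(self, name)
            if math.isnan(value) or value <= 0:
                raise ValueError(f"{name} must be > 0 (inf allowed for Ki/Kd), got {value}")
        if not np.isfinite(self.Km):
            raise ValueError("Km must be finite")


@dataclass(frozen=True)
class SpeciesState:
    """Solved free and complexed species (nM) for one system.

    ``residual_norm`` is the largest relative mass-balance violation over
    the E, I and A conservation equations; ``converged`` is True when it
    is below 1e-9.
    """

    E_free: float
    EI: float
    ES: float
    I_free: float
    AI: float
    A_free: float
    converged: bool
    residual_norm: float


def _state_from_ifree(system: EquilibriumSystem, i_free: float) -> SpeciesState:
    """Build the full species vector from the free-inhibitor root.

    E and A partitions are closed-form in I_free, so their balances hold
    by construction; the I balance carries the solver residual.
    """
    s_ratio = system.S_total / system.Km
    denom = 1.0 + s_ratio
    if math.isfinite(system.Ki):
        denom += i_free / system.Ki
    e_free = system.E_total / denom
    ei = 0.0 if not math.isfinite(system.Ki) else e_free * i_free / system.Ki
    es = e_free * s_ratio
    if math.isfinite(system.Kd):
        # Both species from closed forms: subtracting one from A_total
        # would cancel catastrophically when i_free << Kd.
        a_free = system.A_total * system.Kd / (system.Kd + i_free)
        ai = system.A_total * i_free / (system.Kd + i_free)
    else:
        a_free = system.A_total
        ai = 0.0

    residuals = []
    for total, parts in (
        (system.E_total, e_free + ei + es),
        (system.I_total, i_free + ei + ai),
        (system.A_total, a_free + ai),
    ):
        scale = max(total, 1e-300)
        residuals.append(abs(parts - total) / scale if total > 0 else abs(parts))
    residual_norm = max(residuals)
    return SpeciesState(
        E_free=e_free,
        EI=ei,
        ES=es,
        I_free=i_free,
        AI=ai,
        A_free=a_free,
        converged=residual_norm <= _BALANCE_RTOL,
        residual_norm=residual_norm,
    )


def _ifree_residual(x: float, system: EquilibriumSystem) -> float:
    """Inhibitor conservation residual as a function of free inhibitor.

    Strictly increasing on [0, I_total], negative at 0 (when I_total>0)
    and >= 0 at I_total, so it brackets the unique physical root.
    """
    d = 1.0 + system.S_total / system.Km
    total = x - system.I_total
    if math.isfinite(system.Ki):
        total += system.E_total * x / (d * system.Ki + x)
    if math.isfinite(system.Kd):
        total += system.A_total * x / (system.Kd + x)
    return total


def _ifree_residual_deriv(x: float, system: EquilibriumSystem) -> float:
    d = 1.0 + system.S_total / system.Km
    deriv = 1.0
    if math.isfinite(system.Ki):
        dk = d * system.Ki
        deriv += system.E_total * dk / (dk + x) ** 2
    if math.isfinite(system.Kd):
        deriv += system.A_total * system.Kd / (system.Kd + x) ** 2
    return deriv


def solve_species_equilibrium(system: EquilibriumSystem) -> SpeciesState:
    """Solve the coupled E/I/A equilibria for one well.

    Returns a :class:`SpeciesState` whose ``converged`` flag reports
    whether all three mass balances close to 1e-9 relative. The solution
    is deterministic: bracketed Brent iteration on the free-inhibitor
    conservation equation, polished by Newton steps.

    Raises
    ------
    ValueError
        If the system violates its invariants (checked at construction).
    """
    if system.I_total == 0.0:
        return _state_from_ifree(system, 0.0)

    lo, hi = 0.0, system.I_total
    if _ifree_residual(hi, system) <= 0.0:
        # No enzyme/decoy binding contributes: root is exactly I_total.
        return _state_from_ifree(system, hi)

    x = brentq(
        _ifree_residual,
        lo,
        hi,
        args=(system,),
        xtol=1e-15 * max(system.I_total, 1e-3),
        rtol=4 * np.finfo(float).eps,
        maxiter=200,
    )
    # Newton polish to drive the I balance to machine precision; the
    # residual is smooth and strictly increasing so this cannot escape.
    for _ in range(50):
        f = _ifree_residual(x, system)
        if abs(f) <= 1e-14 * max(system.I_total, 1e-300):
            break
        x = min(max(x - f / _ifree_residual_deriv(x, system), 0.0), system.I_total)
    return _state_from_ifree(system, x)


def oracle_solve(system: EquilibriumSystem, grid_points: int = 20_001) -> SpeciesState:
    """Independent brute-force solver used to cross-check the fast path.

    Scans a dense grid over free inhibitor in [0, I_total] for the sign
    change of the conservation residual, then refines by interval
    halving. Deliberately naive; kept as a verification oracle.
    """
    if grid_points < 10_000:
        raise ValueError("grid_points must be >= 10000 for the oracle scan")
    if system.I_total == 0.0:
        return _state_from_ifree(system, 0.0)

    xs = np.linspace(0.0, system.I_total, grid_points)
    d = 1.0 + system.S_total / system.Km
    res = xs - system.I_total
    if math.isfinite(system.Ki):
        res = res + system.E_total * xs / (d * system.Ki + xs)
    if math.isfinite(system.Kd):
        res = res + system.A_total * xs / (system.Kd + xs)

    idx = int(np.searchsorted(res >= 0.0, True))
    if idx == 0:
        return _state_from_ifree(system, 0.0)
    if idx >= grid_points:
        return _state_from_ifree(system, system.I_total)

    lo, hi = xs[idx - 1], xs[idx]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _ifree_residual(mid, system) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-17 * max(system.I_total, 1e-300):
            break
    return _state_from_ifree(system, 0.5 * (lo + hi))


def unbound_inhibitor_fraction(I_total: float, A_total: float, Kd: float) -> float:
    """Fraction of inhibitor not bound to the decoy (enzyme absent).

    Closed-form root of the two-species binding quadratic; this is the
    pharmacologically active pool when only decoy sequestration matters.
    By convention the fraction is 1 when ``I_total`` is 0 (nothing to
    bind). Units cancel as long as all three arguments share them.
    """
    if I_total < 0 or A_total < 0:
        raise ValueError("concentrations must be >= 0")
    if math.isnan(Kd) or Kd <= 0:
        raise ValueError("Kd must be > 0 (inf for no binding)")
    if I_total == 0.0 or not math.isfinite(Kd):
        return 1.0
    b = I_total + A_total + Kd
    disc = b * b - 4.0 * I_total * A_total
    # Stable smaller quadratic root for the complex AI.
    ai = 2.0 * I_total * A_total / (b + math.sqrt(max(disc, 0.0)))
    return min(max((I_total - ai) / I_total, 0.0), 1.0)
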
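"""Dimerization thermodynamics from a 1D free-energy profile.

Converts a plateau-zeroed profile G(ξ) into the unitless dimerization
constant K, the standard free energy ΔG° = −kT ln K, the fraction of
molecules in dimeric form at a given total concentration, and the onset
concentration at which a target dimer fraction is reached.

Convention: K = (V_box/V0) · P_b/(1 − P_b), where P_b is the Boltzmann
weight of the bound state (ξ < R) over the sampled range, V_box the
simulated box volume and V0 the standard-state volume (≈1661 Å³ for a
1 M standard concentration).  Because exp(−βG) is the full
angular-integrated density, no radial Jacobian enters here.  No
symmetry-number factor for the identical-monomer dimer is applied; the
convention tag is carried in every result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import A3_PER_LITRE, AVOGADRO, DEFAULT_STATE, ThermoState
from .exceptions import DomainError, SamplingGapError, SaturationError
from .landscape import DEFAULT_BOX_VOLUME
from .profiles import FreeEnergyProfile1D

__all__ = [
    "StandardState",
    "DimerizationResult",
    "standard_volume",
    "dimerization_constant",
    "standard_free_energy",
    "dimer_fraction",
    "onset_concentration",
]

CONVENTION_TAG = "K=(Vbox/V0)*Pb/(1-Pb); angular-integrated density; no symmetry number"


@dataclass(frozen=True)
class StandardState:
    """1 M standard state and the constants that define its volume."""

    standard_concentration: float = 1.0  # mol/L
    avogadro: float = AVOGADRO

    def __post_init__(self):
        if self.standard_concentration <= 0:
            raise DomainError("standard concentration must be positive")

    @property
    def volume(self) -> float:
        """Standard volume V0 in Å³ per molecule (≈1661 at 1 M)."""
        return A3_PER_LITRE / (self.avogadro * self.standard_concentration)


def standard_volume(standard_state: StandardState | None = None) -> float:
    """V0 in Å³, computed from the Avogadro constant (rounds to 1661 at 1 M)."""
    return (standard_state or StandardState()).volume


@dataclass(frozen=True)
class DimerizationResult:
    """Unitless K and its ingredients."""

    k: float
    delta_g: float  # kcal/mol
    p_bound: float
    bound_radius: float  # Å
    box_volume: float  # Å^3
    standard_volume: float  # Å^3
    temperature: float  # K
    convention: str = CONVENTION_TAG


def _trapezoid_split(xi, w, r):
    """Trapezoid integrals of w(ξ) over [min, r] and [r, max], splitting at r."""
    if not (xi[0] < r < xi[-1]):
        raise DomainError(
            f"bound radius {r} Å outside the profile range [{xi[0]}, {xi[-1]}] Å"
        )
    wr = float(np.interp(r, xi, w))
    left = xi <= r
    xi_b = np.append(xi[left], r)
    w_b = np.append(w[left], wr)
    xi_u = np.insert(xi[~left], 0, r)
    w_u = np.insert(w[~left], 0, wr)
    return float(np.trapezoid(w_b, xi_b)), float(np.trapezoid(w_u, xi_u))


def dimerization_constant(
    profile: FreeEnergyProfile1D,
    state: ThermoState = DEFAULT_STATE,
    bound_radius: float = 11.0,
    box_volume: float = DEFAULT_BOX_VOLUME,
    standard_state: StandardState | None = None,
    reapply_plateau_zero: bool = True,
    plateau_from: float = 20.0,
) -> DimerizationResult:
    """Unitless dimerization constant by integrating exp(−βG) over the bound state."""
    standard_state = standard_state or StandardState()
    if box_volume <= 0:
        raise DomainError("box_volume must be positive")
    prof = profile.plateau_shifted(plateau_from) if reapply_plateau_zero else profile
    g = np.asarray(prof.g, dtype=float)
    if not np.all(np.isfinite(g)):
        bad = prof.xi[~np.isfinite(g)]
        raise SamplingGapError(
            f"profile has non-finite bins near xi = {bad[:3]} Å; "
            "every reported bin needs at least one effective sample"
        )
    w = np.exp(-state.beta * g)
    i_bound, i_unbound = _trapezoid_split(prof.xi, w, bound_radius)
    p_bound = i_bound / (i_bound + i_unbound)
    if p_bound >= 1.0 - 1e-12:
        raise SaturationError("bound state engulfs the sampled domain (P_b -> 1)")
    k = (box_volume / standard_state.volume) * p_bound / (1.0 - p_bound)
    return DimerizationResult(
        k=k,
        delta_g=standard_free_energy(k, state),
        p_bound=p_bound,
        bound_radius=bound_radius,
        box_volume=box_volume,
        standard_volume=standard_state.volume,
        temperature=state.temperature,
    )


def standard_free_energy(k: float, state: ThermoState = DEFAULT_STATE) -> float:
    """ΔG° = −kT ln K in kcal/mol."""
    if k <= 0:
        raise DomainError(f"dimerization constant must be positive, got {k}")
    return -state.kT * math.log(k)


def _k_from_delta_g(delta_g: float, state: ThermoState) -> float:
    return math.exp(-state.beta * delta_g)


def dimer_fraction(
    delta_g: float, total_concentration: float, state: ThermoState = DEFAULT_STATE
) -> float:
    """Fraction of molecules in dimeric form at a total concentration (mol/L).

    Solves the two-state mass balance 2M ⇌ D with K referenced to 1 M:
    [M] = (−1 + √(1 + 8Kc)) / (4K), fraction = 2[D]/c.  Assumes no
    higher-order aggregation.
    """
    if total_concentration <= 0:
        raise DomainError("total concentration must be positive")
    k = _k_from_delta_g(delta_g, state)
    c = total_concentration
    if k == 0.0:
        return 0.0
    m = (-1.0 + math.sqrt(1.0 + 8.0 * k * c)) / (4.0 * k)
    d = k * m * m
    return 2.0 * d / c


def onset_concentration(
    delta_g: float, target_fraction: float = 0.10, state: ThermoState = DEFAULT_STATE
) -> float:
    """Total concentration (mol/L) at which the dimer fraction reaches a target.

    Closed form of the inverted mass balance: c = f / (2 (1−f)² K).
    """
    if not (0.0 < target_fraction < 1.0):
        raise DomainError("target fraction must lie strictly between 0 and 1")
    k = _k_from_delta_g(delta_g, state)
    f = target_fraction
    return f / (2.0 * (1.0 - f) ** 2 * k)
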
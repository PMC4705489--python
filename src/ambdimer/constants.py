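"""Physical constants and the thermodynamic state.

Units used throughout the package: energies in kcal/mol, lengths in Å,
angles in degrees, times in ns unless a function states otherwise
(rotational quantities and bimolecular rates use seconds).
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import DomainError

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K = 0.0019872041

#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23

#: Cubic Å per litre.
A3_PER_LITRE = 1.0e27


@dataclass(frozen=True)
class ThermoState:
    """Temperature and the derived inverse temperature.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K.  The default, 300 K, is the
        thermostat temperature of the simulations this package emulates.
    boltzmann_constant : float
        k_B in kcal mol^-1 K^-1.
    """

    temperature: float = 300.0
    boltzmann_constant: float = KB_KCAL_PER_MOL_K

    def __post_init__(self):
        if self.temperature <= 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")
        if self.boltzmann_constant <= 0:
            raise DomainError("boltzmann_constant must be > 0")

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T in kcal/mol."""
        return self.boltzmann_constant * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B*T) in mol/kcal."""
        return 1.0 / self.kT


DEFAULT_STATE = ThermoState()
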
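"""Shared physical constants for electrostatics and block-model calculations.

All voltages in the package are membrane potentials in millivolts, currents in
picoamperes, conductances in picosiemens and distances in angstroms, the native
units of patch-clamp work.  ``RT/F`` is therefore carried in millivolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import scipy.constants as _sc

FARADAY = _sc.physical_constants["Faraday constant"][0]  # C/mol
GAS_CONSTANT = _sc.R  # J/(mol K)
VACUUM_PERMITTIVITY = _sc.epsilon_0  # F/m


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic and dielectric constants used throughout the pipeline.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Room temperature (298.15 K) gives
        RT/F = 25.7 mV, the value behind the 180 mV/A screened-Coulomb
        prefactor used for vestibule electrostatics.
    relative_permittivity : float
        Solvent dielectric constant; 78.5 for water.
    """

    temperature: float = 298.15
    relative_permittivity: float = 78.5
    faraday: float = field(default=FARADAY, repr=False)
    gas_constant: float = field(default=GAS_CONSTANT, repr=False)
    vacuum_permittivity: float = field(default=VACUUM_PERMITTIVITY, repr=False)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.relative_permittivity <= 0:
            raise ValueError("relative permittivity must be positive")

    @property
    def rt_over_f_mV(self) -> float:
        """Thermal voltage RT/F in millivolts (25.69 mV at 298.15 K)."""
        return 1e3 * self.gas_constant * self.temperature / self.faraday


DEFAULT_CONSTANTS = PhysicalConstants()
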
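"""Surface-potential estimates for the outer pore of an ion channel.

Fixed negative charge at the mouth of a cation channel concentrates both
permeant ions and charged blockers above their bulk concentrations.  Two
experimental readouts report on that local potential:

* the shift in a blocker's apparent dissociation constant when a charged
  residue is mutated away, ``K_D,mut / K_D,wt = exp(-z F dphi / RT)``;
* the drop in single-channel conductance, assuming conductance tracks the
  local permeant-ion concentration, which obeys the same Boltzmann factor.

Independently, the potential a shell of fixed charges produces at the pore
axis can be estimated with screened-Coulomb (Debye-Hueckel) superposition,
``phi = sum_i z_i * A * exp(-r_i/lambda) / r_i`` with A ~ 180 mV*A in water.
When a charge sits at the water/protein interface the potential roughly
doubles, because half of space cannot be screened; the doubling is exposed
as an explicit factor rather than baked in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

#: Screened-Coulomb prefactor q/(4 pi eps0 eps) for water, in mV*A.
DEFAULT_PREFACTOR_MV_A = 180.0


@dataclass(frozen=True)
class ChargeGeometry:
    """Point charges around an evaluation point on the pore axis.

    ``valences`` and ``distances_A`` are parallel sequences: charge number
    (negative for acidic side chains) and distance from the evaluation
    point in angstroms.  ``interface_doubling`` is 1 for charges fully in
    electrolyte and 2 for charges at a water/low-dielectric interface.
    """

    valences: tuple[float, ...]
    distances_A: tuple[float, ...]
    debye_length_A: float = 8.0
    prefactor_mV_A: float = DEFAULT_PREFACTOR_MV_A
    interface_doubling: float = 1.0

    def __post_init__(self) -> None:
        if len(self.valences) != len(self.distances_A):
            raise ValueError("valences and distances must have equal length")
        if any(r <= 0 for r in self.distances_A):
            raise ValueError("all charge distances must be > 0")
        if self.debye_length_A <= 0:
            raise ValueError("Debye length must be > 0")
        if self.prefactor_mV_A <= 0:
            raise ValueError("prefactor must be > 0")
        if self.interface_doubling not in (1, 2, 1.0, 2.0):
            raise ValueError("interface_doubling must be 1 or 2")

    @classmethod
    def ring(
        cls,
        n_charges: int,
        valence: float,
        distance_A: float,
        **kwargs,
    ) -> "ChargeGeometry":
        """Equidistant ring of identical charges (e.g. one per subunit)."""
        return cls(
            valences=(valence,) * n_charges,
            distances_A=(distance_A,) * n_charges,
            **kwargs,
        )


def delta_phi_from_kd_ratio(
    kd_mut: float,
    kd_wt: float,
    z_blocker: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Surface-potential change (mV) implied by a blocker-affinity ratio.

    A mutation that removes negative charge makes the local potential less
    negative, depletes the cationic blocker, and raises its apparent K_D:
    ``dphi = (RT / z F) * ln(K_D,mut / K_D,wt)``, positive when affinity is
    lost (mutant K_D larger).
    """
    if kd_mut <= 0 or kd_wt <= 0:
        raise ValueError("dissociation constants must be positive")
    if z_blocker == 0:
        raise ValueError("blocker valence must be nonzero")
    return constants.rt_over_f_mV / z_blocker * np.log(kd_mut / kd_wt)


def boltzmann_concentration(
    bulk: float,
    phi_mV: float,
    z: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Local ion concentration at a site of potential ``phi_mV``.

    ``[I] = [I]_bulk * exp(-z F phi / RT)`` - cations accumulate where the
    potential is negative.
    """
    if bulk < 0:
        raise ValueError("bulk concentration must be >= 0")
    return bulk * np.exp(-z * phi_mV / constants.rt_over_f_mV)


def delta_phi_from_conductance_ratio(
    g_mut: float,
    g_wt: float,
    z_permeant: float = 1.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Surface-potential change (mV) from a single-channel conductance ratio.

    With conductance proportional to the permeant-ion concentration at the
    pore mouth, ``dphi = (RT / z F) * ln(g_wt / g_mut)``; a mutant with a
    smaller conductance has lost negative surface potential.
    """
    if g_mut <= 0 or g_wt <= 0:
        raise ValueError("conductances must be positive")
    if z_permeant == 0:
        raise ValueError("permeant valence must be nonzero")
    return constants.rt_over_f_mV / z_permeant * np.log(g_wt / g_mut)


def debye_length(
    ionic_strength_mM: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Debye screening length in angstroms for a 1:1 electrolyte.

    ``kappa^-1 = sqrt(eps eps0 R T / (2 F^2 I))`` with I in mol/m^3;
    about 7.9 A at 150 mM and 298 K.
    """
    if ionic_strength_mM <= 0:
        raise ValueError("ionic strength must be positive")
    ionic_strength_mol_m3 = ionic_strength_mM  # 1 mM == 1 mol/m^3
    kappa_inv_m = np.sqrt(
        constants.relative_permittivity
        * constants.vacuum_permittivity
        * constants.gas_constant
        * constants.temperature
        / (2.0 * constants.faraday**2 * ionic_strength_mol_m3)
    )
    return float(kappa_inv_m * 1e10)


def debye_huckel_potential(geometry: ChargeGeometry) -> float:
    """Screened-Coulomb potential (mV) at the evaluation point.

    Linear superposition over all charges:
    ``phi = D * sum_i z_i * A * exp(-r_i / lambda) / r_i`` where A is the
    prefactor (mV*A), lambda the Debye length and D the interface-doubling
    factor.  Negative for rings of acidic residues.
    """
    z = np.asarray(geometry.valences, dtype=float)
    r = np.asarray(geometry.distances_A, dtype=float)
    terms = z * geometry.prefactor_mV_A * np.exp(-r / geometry.debye_length_A) / r
    return float(geometry.interface_doubling * terms.sum())
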
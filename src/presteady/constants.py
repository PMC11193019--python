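"""Physical constants shared by the electrostatics and kinetics layers.

All rate laws and energy conversions in this package are expressed in the
practical electrophysiology unit system: lengths in angstrom, potentials in
mV (or thermal units kT/e), energies in kcal/mol, charges in elementary
charges, time in ms, currents in pA.
"""

from dataclasses import dataclass

#: Faraday constant in kcal/(mol·V·e) — converts (e × V) to kcal/mol.
FARADAY_KCAL_PER_MOL_V = 23.0609
#: Faraday constant in C/mol.
FARADAY_C_PER_MOL = 96485.33212
#: Gas constant in kcal/(mol·K).
R_KCAL_PER_MOL_K = 1.98720425864083e-3
#: Elementary charge in coulomb.
ELEMENTARY_CHARGE_C = 1.602176634e-19
#: Boltzmann constant in J/K.
BOLTZMANN_J_PER_K = 1.380649e-23
#: Coulomb constant times e^2, in kcal·Å/(mol·e^2): energy of two unit
#: charges 1 Å apart in vacuum.
COULOMB_KCAL_A = 332.0636
#: Avogadro constant in 1/mol.
AVOGADRO = 6.02214076e23


def thermal_voltage_mV(temperature_K: float) -> float:
    """RT/F (equivalently kT/e) in millivolts at the given temperature.

    25.693 mV at 298.15 K; every voltage-dependent rate law divides by
    twice this quantity.
    """
    return R_KCAL_PER_MOL_K * temperature_K / FARADAY_KCAL_PER_MOL_V * 1000.0


def bjerrum_length_vacuum_A(temperature_K: float) -> float:
    """Vacuum Bjerrum length e²/(4πε₀ kT) in Å (≈560.5 Å at 298.15 K)."""
    return COULOMB_KCAL_A / (R_KCAL_PER_MOL_K * temperature_K)


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of constants with a configurable temperature.

    Attributes
    ----------
    temperature_K:
        Absolute temperature. Room temperature (297 K) is the default for
        rate-law algebra; solver settings carry their own temperature.
    """

    temperature_K: float = 297.0

    @property
    def RT_over_F_mV(self) -> float:
        return thermal_voltage_mV(self.temperature_K)

    @property
    def kT_kcal_per_mol(self) -> float:
        return R_KCAL_PER_MOL_K * self.temperature_K
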
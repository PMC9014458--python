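"""Physical constants and unit conversions used across the package.

All geometry is in angstrom, molecular-mechanics energies in kcal/mol,
electron detachment energies in eV, temperatures in kelvin.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 0.0019872

#: Hartree -> kcal/mol.
HARTREE_TO_KCAL = 627.5095

#: Hartree -> eV.
HARTREE_TO_EV = 27.211386

#: Coulomb prefactor for point charges, kcal A mol^-1 e^-2.
COULOMB_KCAL = 332.0637

#: Default ensemble temperature, K.
DEFAULT_TEMPERATURE = 298.15


def hartree_to_ev(value: float) -> float:
    return value * HARTREE_TO_EV


def ev_to_hartree(value: float) -> float:
    return value / HARTREE_TO_EV


def hartree_to_kcal(value: float) -> float:
    return value * HARTREE_TO_KCAL
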
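"""Vertical and adiabatic electron-detachment energy bookkeeping.

For a dianion D2- the vertical detachment energy (VDE) is the energy
of the monoanion *at the dianion's equilibrium geometry* minus the
dianion energy; the adiabatic detachment energy (ADE) uses the relaxed
monoanion instead, so ADE <= VDE.  The electronic-structure energies
themselves come from external calculations and are only combined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .constants import HARTREE_TO_EV


class UnitError(ValueError):
    pass


@dataclass
class ChargeStateEnergies:
    """Energies of the two charge states of one conformer.

    ``e_monoanion_vertical`` must refer to the dianion-optimized
    geometry (same-geometry contract).  ``units`` is ``"hartree"`` or
    ``"eV"``; ``includes_zpe`` records whether zero-point corrections
    are folded in (metadata only — the arithmetic is identical).
    """

    label: str
    e_dianion_opt: float
    e_monoanion_vertical: float | None = None
    e_monoanion_opt: float | None = None
    units: str = "hartree"
    includes_zpe: bool = False

    def __post_init__(self) -> None:
        if self.units not in ("hartree", "eV"):
            raise UnitError(f"{self.label}: undeclared/unsupported unit {self.units!r}")

    def _to_ev(self, diff: float) -> float:
        return diff * HARTREE_TO_EV if self.units == "hartree" else diff


def vertical_detachment_energy(rec: ChargeStateEnergies) -> float:
    """VDE in eV: E(monoanion @ dianion geometry) - E(dianion).

    A negative value (electronically unbound dianion) is returned with
    a stability warning.
    """
    if rec.e_monoanion_vertical is None:
        raise ValueError(f"{rec.label}: missing vertical monoanion energy")
    vde = rec._to_ev(rec.e_monoanion_vertical - rec.e_dianion_opt)
    if vde < 0:
        warnings.warn(
            f"{rec.label}: negative VDE ({vde:.4f} eV) — dianion unbound at this geometry"
        )
    return vde


def adiabatic_detachment_energy(rec: ChargeStateEnergies) -> float:
    """ADE in eV: E(relaxed monoanion) - E(relaxed dianion).

    When the VDE is also computable, the adiabatic-relaxation contract
    ADE <= VDE is checked and violations produce a warning (the values
    are still returned).
    """
    if rec.e_monoanion_opt is None:
        raise ValueError(f"{rec.label}: missing optimized monoanion energy")
    ade = rec._to_ev(rec.e_monoanion_opt - rec.e_dianion_opt)
    if rec.e_monoanion_vertical is not None:
        vde = rec._to_ev(rec.e_monoanion_vertical - rec.e_dianion_opt)
        if ade > vde + 1e-9:
            warnings.warn(
                f"{rec.label}: ADE {ade:.4f} eV exceeds VDE {vde:.4f} eV "
                "(violates adiabatic relaxation)"
            )
    return ade
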
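"""In-vitro-to-in-vivo extrapolation of liver kinetic constants.

Per-mg-protein constants from incubations are converted to whole-liver
values with the protein-yield scaling factors (mg microsomal or S9
protein per g liver):

    Vmax [nmol/min/mg] * yield [mg/g] * 60 / 1000 -> umol/h/g liver
    k    [ml/min/mg]   * yield [mg/g] * 60        -> ml/h/g liver

The in vivo catalytic efficiency of a saturable pathway is the scaled
Vmax divided by Km; with Vmax in umol/h/g and Km in umol/L this is a
clearance in L/h/g liver.  First-order (ml/h/g) clearances are divided
by 1000 when compared on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .kinetics import KineticConstants

__all__ = [
    "ProteinYield",
    "ScaledKineticConstants",
    "scale_vmax",
    "scale_k",
    "scale_constants",
    "catalytic_efficiency_invivo",
    "DEFAULT_YIELDS",
]


@dataclass(frozen=True)
class ProteinYield:
    """Liver protein yields for one species, in mg protein per g liver."""

    species: str
    microsomal_mg_per_g_liver: float
    s9_mg_per_g_liver: float

    def __post_init__(self):
        if self.microsomal_mg_per_g_liver <= 0 or self.s9_mg_per_g_liver <= 0:
            raise ValueError("protein yields must be strictly positive")

    def for_basis(self, protein_basis: str) -> float:
        if protein_basis == "microsomal":
            return self.microsomal_mg_per_g_liver
        if protein_basis == "s9":
            return self.s9_mg_per_g_liver
        raise ValueError(f"unknown protein basis {protein_basis!r}")


DEFAULT_YIELDS = {
    "rat": ProteinYield("rat", 35.0, 143.0),
    "human": ProteinYield("human", 32.0, 143.0),
}


@dataclass
class ScaledKineticConstants:
    """Whole-liver kinetic constants for one pathway.

    vmax_scaled in umol/h/g liver, km in uM, k_scaled in ml/h/g liver.
    """

    pathway_id: str
    vmax_scaled: Optional[float] = None
    km: Optional[float] = None
    k_scaled: Optional[float] = None

    def __post_init__(self):
        saturable = self.vmax_scaled is not None and self.km is not None
        linear = self.k_scaled is not None
        if saturable == linear:
            raise ValueError("exactly one of {vmax_scaled & km, k_scaled} required")
        for value in (self.vmax_scaled, self.km, self.k_scaled):
            if value is not None and value <= 0:
                raise ValueError("scaled constants must be strictly positive")

    @property
    def kind(self) -> str:
        return "first_order" if self.k_scaled is not None else "michaelis_menten"

    @property
    def efficiency_invivo(self) -> float:
        return catalytic_efficiency_invivo(self)

    @property
    def clearance_L_per_h_g(self) -> float:
        """Linear-regime clearance, L/h/g liver, for either pathway kind."""
        if self.kind == "first_order":
            return self.k_scaled / 1000.0
        return self.vmax_scaled / self.km


def scale_vmax(vmax_invitro: float, yield_mg_per_g: float) -> float:
    """nmol/min/mg protein -> umol/h/g liver."""
    if vmax_invitro <= 0 or yield_mg_per_g <= 0:
        raise ValueError("inputs must be strictly positive")
    return vmax_invitro * yield_mg_per_g * 60.0 / 1000.0


def scale_k(k_invitro: float, yield_mg_per_g: float) -> float:
    """ml/min/mg protein -> ml/h/g liver."""
    if k_invitro <= 0 or yield_mg_per_g <= 0:
        raise ValueError("inputs must be strictly positive")
    return k_invitro * yield_mg_per_g * 60.0


def scale_constants(kc: KineticConstants, yields: ProteinYield) -> ScaledKineticConstants:
    """Scale one pathway's constants using the yield for its protein basis."""
    y = yields.for_basis(kc.protein_basis)
    if kc.kind == "michaelis_menten":
        return ScaledKineticConstants(
            pathway_id=kc.pathway_id,
            vmax_scaled=scale_vmax(kc.vmax, y),
            km=kc.km,
        )
    return ScaledKineticConstants(pathway_id=kc.pathway_id, k_scaled=scale_k(kc.k, y))


def catalytic_efficiency_invivo(sc: ScaledKineticConstants) -> float:
    """Scaled Vmax / Km, in L/h/g liver."""
    if sc.kind != "michaelis_menten":
        raise ValueError("in vivo catalytic efficiency requires a saturable pathway")
    return sc.vmax_scaled / sc.km
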
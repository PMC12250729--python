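"""Conceptual-DFT reactivity descriptors and the docking-score combination.

From frontier-orbital energies (eV), with the Koopmans-style identifications
I = −E(HOMO) and A = −E(LUMO):

    GAP = I − A            η = (I − A)/2        σ = 1/η
    χ = (I + A)/2          μ = −χ               ω = μ²/(2η)

Two electrophilicity conventions are exposed: the standard ω = μ²/(2η) and a
"table" convention ω = μ²·η/2 found in some published descriptor tables
(their ratio is exactly η²). Chemical potential and electronegativity are
computed with their standard signs (μ < 0 for a bound system); ``as-printed``
accessors flip them to the orientation some tables use (μ positive).

The docking score is the fixed linear combination
HS = 1.0·E_vdw + 0.2·E_elec + 1.0·E_desolv + 0.1·E_air (kcal/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class DescriptorSet:
    """Frontier-orbital reactivity descriptors for one molecule (eV)."""

    homo: float
    lumo: float
    ionization_potential: float
    electron_affinity: float
    gap: float
    hardness: float
    chem_potential: float
    electronegativity: float
    softness: float | None          # eV^-1; None when hardness is 0
    omega_standard: float | None    # mu^2 / (2 eta)
    omega_table: float | None       # mu^2 * eta / 2

    @property
    def mu_as_printed(self) -> float:
        """Chemical potential with the sign flipped to table orientation."""
        return -self.chem_potential

    @property
    def chi_as_printed(self) -> float:
        """Electronegativity in table orientation (negative for bound systems)."""
        return -self.electronegativity

    def omega(self, convention: str = "standard") -> float:
        value = {"standard": self.omega_standard, "table": self.omega_table}.get(convention)
        if convention not in ("standard", "table"):
            raise ValueError(f"unknown electrophilicity convention {convention!r}")
        if value is None:
            raise ZeroDivisionError("electrophilicity undefined at zero hardness")
        return value


def descriptors_from_orbitals(homo: float, lumo: float) -> DescriptorSet:
    """Compute the descriptor set from HOMO/LUMO energies in eV.

    ``lumo > homo`` gives a positive hardness; a degenerate pair
    (``homo == lumo``) yields zero hardness with softness and
    electrophilicity undefined (None).
    """
    if not (math.isfinite(homo) and math.isfinite(lumo)):
        raise ValueError("orbital energies must be finite")
    ip = -homo
    ea = -lumo
    gap = ip - ea
    eta = gap / 2.0
    chi = (ip + ea) / 2.0
    mu = -chi
    if eta != 0.0:
        sigma = 1.0 / eta
        omega_standard = mu * mu / (2.0 * eta)
        omega_table = mu * mu * eta / 2.0
    else:
        sigma = omega_standard = omega_table = None
    return DescriptorSet(
        homo=homo,
        lumo=lumo,
        ionization_potential=ip,
        electron_affinity=ea,
        gap=gap,
        hardness=eta,
        chem_potential=mu,
        electronegativity=chi,
        softness=sigma,
        omega_standard=omega_standard,
        omega_table=omega_table,
    )


@dataclass(frozen=True)
class DockingScoreInput:
    """Component energies entering the docking score, kcal/mol."""

    e_vdw: float
    e_elec: float
    e_desolv: float
    e_air: float = 0.0

    def __post_init__(self) -> None:
        for name in ("e_vdw", "e_elec", "e_desolv", "e_air"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


#: Fixed weights of the docking-score linear combination.
HADDOCK_WEIGHTS = {"e_vdw": 1.0, "e_elec": 0.2, "e_desolv": 1.0, "e_air": 0.1}


def haddock_score(components: DockingScoreInput) -> float:
    """HS = 1.0·E_vdw + 0.2·E_elec + 1.0·E_desolv + 0.1·E_air, kcal/mol."""
    return (
        HADDOCK_WEIGHTS["e_vdw"] * components.e_vdw
        + HADDOCK_WEIGHTS["e_elec"] * components.e_elec
        + HADDOCK_WEIGHTS["e_desolv"] * components.e_desolv
        + HADDOCK_WEIGHTS["e_air"] * components.e_air
    )
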
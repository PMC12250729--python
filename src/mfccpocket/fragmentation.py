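"""Conjugate-cap fragmentation of a protein–ligand complex.

For a target residue R_i, the molecular fractionation with conjugate caps
(MFCC) scheme cleaves the two peptide bonds flanking R_i and evaluates four
capped systems:

    E_I(L−R_i) = E(L·C_{i−1}R_iC_{i+1}) − E(C_{i−1}R_iC_{i+1})
               − E(L·C_{i−1}C_{i+1})   + E(C_{i−1}C_{i+1})

where the caps C_{i−1}/C_{i+1} are the entire neighbouring residues at their
source geometry. Hydrogens terminate every bond broken by the cleavage:

* *outer* hydrogens saturate the far ends of the caps (where the i−2 and i+2
  residues were attached, or the missing valence of a true chain terminus);
* *junction* hydrogens appear only in the concap systems, replacing the two
  bonds that went to R_i, placed along the former bond unit vectors.

No atom is re-optimized: every atom shared between two systems of the
quartet has bitwise-identical coordinates, which is what makes all
intra-fragment contributions cancel for a pairwise-additive backend:

    E_I = pairsum(L, R_i) − pairsum(L, junction hydrogens).

Added hydrogens carry zero charge and zero LJ depth unless a
:class:`CapSpec` says otherwise, so with the classical backend the MFCC
combination reproduces the direct ligand–residue pair energy to machine
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .backends import EnergyBackend
from .errors import BackendError, ConnectivityError, FragmentationError
from .structure import Atom, ComplexStructure, ResidueGroup, ResidueKey

logger = logging.getLogger(__name__)

#: Maximum peptide-bond length; a larger N–C gap is treated as a chain break.
PEPTIDE_BOND_CUTOFF = 2.0

#: Generic covalent-contact cutoff used for the side-chain bridge check.
COVALENT_CUTOFF = 1.7

BACKBONE_NAMES = {"N", "CA", "C", "O", "H", "HA", "OXT", "H1", "H2", "H3"}


@dataclass
class CapSpec:
    """Capping geometry settings.

    Caps are whole neighbouring residues; the bond lengths set where the
    terminating hydrogens sit along the former bond vectors (C–H 1.090 Å,
    N–H 1.010 Å by default). ``hydrogen_charge``/``hydrogen_lj`` parameterize
    the added hydrogens; the zero defaults make them ghosts for the classical
    backend.
    """

    ch_bond_length: float = 1.090
    nh_bond_length: float = 1.010
    hydrogen_charge: float = 0.0
    hydrogen_lj: tuple[float, float] = (0.0, 0.0)  # (epsilon kcal/mol, rmin/2 Å)

    def __post_init__(self) -> None:
        for length in (self.ch_bond_length, self.nh_bond_length):
            if not 0.5 < length < 1.5:
                raise ValueError(f"cap bond length {length} Å outside (0.5, 1.5)")


@dataclass
class FragmentQuartet:
    """The four atom systems whose energies combine into one E_I(L−R_i)."""

    residue_key: ResidueKey
    sys_L_cap_R_cap: list[Atom]
    sys_cap_R_cap: list[Atom]
    sys_L_concap: list[Atom]
    sys_concap: list[Atom]
    junction_hydrogens: list[Atom] = field(default_factory=list)
    outer_hydrogens: list[Atom] = field(default_factory=list)

    def systems(self) -> dict[str, list[Atom]]:
        return {
            "L_cap_R_cap": self.sys_L_cap_R_cap,
            "cap_R_cap": self.sys_cap_R_cap,
            "L_concap": self.sys_L_concap,
            "concap": self.sys_concap,
        }


def _unit(vec: np.ndarray) -> np.ndarray:
    norm = float(np.linalg.norm(vec))
    if norm < 1e-9:
        raise ConnectivityError("degenerate bond vector while placing a cap hydrogen")
    return vec / norm


def _make_hydrogen(
    parent: Atom,
    direction: np.ndarray,
    length: float,
    spec: CapSpec,
    junction: bool,
    serial: int,
) -> Atom:
    eps, rmh = spec.hydrogen_lj
    return Atom(
        serial=serial,
        name="HJ" if junction else "HX",
        element="H",
        coords=parent.coords + length * _unit(direction),
        partial_charge=spec.hydrogen_charge,
        lj_epsilon=eps,
        lj_rmin_half=rmh,
        residue_key=parent.residue_key,
        is_cap_hydrogen=True,
        is_junction=junction,
    )


def _valence_completion_direction(parent: Atom, group: ResidueGroup) -> np.ndarray:
    """Direction of the missing substituent at a true chain terminus.

    Computed as minus the resultant of unit vectors to the atoms covalently
    bonded to ``parent`` within its own residue.
    """
    resultant = np.zeros(3)
    for atom in group.atoms:
        if atom is parent:
            continue
        delta = atom.coords - parent.coords
        if float(np.linalg.norm(delta)) <= COVALENT_CUTOFF:
            resultant += _unit(delta)
    if float(np.linalg.norm(resultant)) < 1e-9:
        raise ConnectivityError(
            f"cannot orient terminal cap hydrogen on {parent.name}@{parent.residue_key}"
        )
    return -resultant


def _bonded_neighbor(
    complex_structure: ComplexStructure, group: ResidueGroup, offset: int
) -> ResidueGroup | None:
    """Sequence neighbour that is also within peptide-bond distance."""
    other = complex_structure.neighbor(group, offset)
    if other is None:
        return None
    if offset < 0:
        a, b = other.backbone_c, group.backbone_n
    else:
        a, b = group.backbone_c, other.backbone_n
    if a is None or b is None:
        return None
    gap = float(np.linalg.norm(a.coords - b.coords))
    if gap > PEPTIDE_BOND_CUTOFF:
        logger.warning(
            "chain break between %s and %s (N–C %.2f Å); treating as terminus",
            group.key, other.key, gap,
        )
        return None
    return other


def _check_no_sidechain_bridge(
    complex_structure: ComplexStructure, target: ResidueGroup
) -> None:
    """Refuse residues whose side chain bonds outside their own group."""
    outside = [
        a
        for g in complex_structure.polymer
        if g is not target
        for a in g.atoms
        if a.element != "H"
    ]
    if not outside:
        return
    out_coords = np.array([a.coords for a in outside])
    for atom in target.atoms:
        if atom.element == "H" or atom.name in BACKBONE_NAMES:
            continue
        dists = np.linalg.norm(out_coords - atom.coords, axis=1)
        j = int(np.argmin(dists))
        if dists[j] <= COVALENT_CUTOFF:
            other = outside[j]
            raise FragmentationError(
                f"side-chain atom {atom.name}@{target.key} is covalently bonded to "
                f"{other.name}@{other.residue_key}; cross-link cleavage is unsupported"
            )


def build_quartet(
    complex_structure: ComplexStructure,
    residue_key: ResidueKey | tuple[str, int],
    spec: CapSpec | None = None,
) -> FragmentQuartet:
    """Build the four capped systems for one target residue.

    The caps are the full neighbouring residues at their source geometry. A
    terminal target residue is capped on its one existing side only; a lone
    residue (no neighbour on either side) cannot be fragmented.
    """
    spec = spec or CapSpec()
    ligand = complex_structure.ligand
    if tuple(residue_key)[:2] == (ligand.chain_id, ligand.seq_id):
        raise FragmentationError("cannot fragment the ligand group")
    target = complex_structure.residue(residue_key)
    if not target.cleavable:
        raise ConnectivityError(f"residue {target.key} flagged non-cleavable")
    _check_no_sidechain_bridge(complex_structure, target)

    prev_res = _bonded_neighbor(complex_structure, target, -1)
    next_res = _bonded_neighbor(complex_structure, target, +1)
    if prev_res is None and next_res is None:
        raise FragmentationError(
            f"residue {target.key} has no bonded neighbour on either side"
        )

    serial = max(a.serial for a in complex_structure.all_atoms()) + 1
    outer_minus: list[Atom] = []
    outer_plus: list[Atom] = []
    junction: list[Atom] = []

    def next_serial() -> int:
        nonlocal serial
        serial += 1
        return serial - 1

    cap_minus: list[Atom] = []
    if prev_res is not None:
        cap_minus = list(prev_res.atoms)
        n_atom = prev_res.backbone_n
        if n_atom is None:
            raise ConnectivityError(f"cap residue {prev_res.key} lacks backbone N")
        outer_res = _bonded_neighbor(complex_structure, prev_res, -1)
        if outer_res is not None:
            c_outer = outer_res.backbone_c
            if c_outer is None:
                raise ConnectivityError(f"residue {outer_res.key} lacks backbone C")
            direction = c_outer.coords - n_atom.coords
        else:
            direction = _valence_completion_direction(n_atom, prev_res)
        outer_minus.append(
            _make_hydrogen(n_atom, direction, spec.nh_bond_length, spec, False, next_serial())
        )

    cap_plus: list[Atom] = []
    if next_res is not None:
        cap_plus = list(next_res.atoms)
        c_atom = next_res.backbone_c
        if c_atom is None:
            raise ConnectivityError(f"cap residue {next_res.key} lacks backbone C")
        outer_res = _bonded_neighbor(complex_structure, next_res, +1)
        if outer_res is not None:
            n_outer = outer_res.backbone_n
            if n_outer is None:
                raise ConnectivityError(f"residue {outer_res.key} lacks backbone N")
            direction = n_outer.coords - c_atom.coords
        else:
            direction = _valence_completion_direction(c_atom, next_res)
        outer_plus.append(
            _make_hydrogen(c_atom, direction, spec.ch_bond_length, spec, False, next_serial())
        )

    # junction hydrogens: replace the two bonds that went to the target
    if prev_res is not None:
        c_prev = prev_res.backbone_c
        n_target = target.backbone_n
        if c_prev is None or n_target is None:
            raise ConnectivityError(
                f"missing C@{prev_res.key} or N@{target.key} for the N-side junction"
            )
        junction.append(
            _make_hydrogen(
                c_prev, n_target.coords - c_prev.coords, spec.ch_bond_length, spec, True, next_serial()
            )
        )
    if next_res is not None:
        n_next = next_res.backbone_n
        c_target = target.backbone_c
        if n_next is None or c_target is None:
            raise ConnectivityError(
                f"missing N@{next_res.key} or C@{target.key} for the C-side junction"
            )
        junction.append(
            _make_hydrogen(
                n_next, c_target.coords - n_next.coords, spec.nh_bond_length, spec, True, next_serial()
            )
        )

    ligand = list(complex_structure.ligand.atoms)
    cap_r_cap = cap_minus + outer_minus + list(target.atoms) + cap_plus + outer_plus
    concap = cap_minus + outer_minus + cap_plus + outer_plus + junction
    return FragmentQuartet(
        residue_key=target.key,
        sys_L_cap_R_cap=ligand + cap_r_cap,
        sys_cap_R_cap=cap_r_cap,
        sys_L_concap=ligand + concap,
        sys_concap=concap,
        junction_hydrogens=junction,
        outer_hydrogens=outer_minus + outer_plus,
    )


def mfcc_interaction_energy(
    quartet: FragmentQuartet,
    backend: EnergyBackend,
    dielectric: float,
) -> float:
    """Combine the quartet energies into E_I(L−R_i), kcal/mol (negative = attractive)."""
    energies: dict[str, float] = {}
    for role, system in quartet.systems().items():
        try:
            energies[role] = backend.evaluate(system, dielectric)
        except Exception as exc:
            raise BackendError(
                f"backend {getattr(backend, 'label', backend)!r} failed on system "
                f"{role!r} of residue {quartet.residue_key}: {exc}"
            ) from exc
    return (
        energies["L_cap_R_cap"]
        - energies["cap_R_cap"]
        - energies["L_concap"]
        + energies["concap"]
    )
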
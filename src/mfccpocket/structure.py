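"""Molecular structure containers and PDB/PQR/XYZ input-output.

A :class:`ComplexStructure` holds one polymer chain (or several) split into
:class:`ResidueGroup` objects plus exactly one group flagged as the ligand.
Atoms carry coordinates in Å, partial charges in elementary-charge units and
Lennard-Jones parameters (well depth in kcal/mol, r_min/2 in Å) — everything
the classical pairwise energy backend needs.

PDB and PQR files are parsed through MDAnalysis; because MDAnalysis stores
coordinates and charges in single precision, parsed values are re-quantized to
the fixed decimal precision the text formats carry (4 decimal places), which
makes write/read round-trips exact in double precision.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    FormatError,
    ParameterizationError,
    SelectionError,
)

logger = logging.getLogger(__name__)

#: Decimal places carried by the PQR records this package writes; parsed
#: coordinates/charges/radii are rounded back to this precision.
PQR_DECIMALS = 4

_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "SE", "SI",
}

ResidueKey = tuple[str, int, str]


def element_from_name(name: str, res_name: str = "") -> str:
    """Guess an element symbol from an atom name.

    Names like CA/CB/CD resolve to carbon by the Greek remoteness convention
    ("CA" meaning calcium would need an explicit element column, which PQR
    lacks); two-letter halogen/metal symbols are recognised directly.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    upper = stripped.upper()
    if upper[:2] in _TWO_LETTER_ELEMENTS:
        return upper[0] + upper[1].lower()
    return upper[0]


@dataclass
class Atom:
    """One atom with coordinates and nonbonded parameters.

    ``is_cap_hydrogen``/``is_junction`` mark hydrogens created during MFCC
    capping; source atoms always have both flags False.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0
    residue_key: ResidueKey | None = None
    is_cap_hydrogen: bool = False
    is_junction: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} ({self.name}): coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}): element must be non-empty")
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial} ({self.name}): lj_epsilon must be >= 0")

    def copy(self) -> "Atom":
        return Atom(
            serial=self.serial,
            name=self.name,
            element=self.element,
            coords=self.coords.copy(),
            partial_charge=self.partial_charge,
            lj_epsilon=self.lj_epsilon,
            lj_rmin_half=self.lj_rmin_half,
            residue_key=self.residue_key,
            is_cap_hydrogen=self.is_cap_hydrogen,
            is_junction=self.is_junction,
        )


@dataclass
class ResidueGroup:
    """A polymer residue (or the ligand group) with its atoms in file order."""

    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    is_ligand: bool = False
    cleavable: bool = True

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_id, self.res_name)

    def atom_by_name(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    @property
    def backbone_n(self) -> Atom | None:
        """Amide nitrogen joining this residue to its N-side neighbour."""
        return self.atom_by_name("N")

    @property
    def backbone_c(self) -> Atom | None:
        """Carbonyl carbon joining this residue to its C-side neighbour."""
        return self.atom_by_name("C")

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def net_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))


@dataclass
class ComplexStructure:
    """A receptor chain decomposed into residues, plus one ligand group."""

    polymer: list[ResidueGroup]
    ligand: ResidueGroup

    def __post_init__(self) -> None:
        if not self.ligand.is_ligand:
            raise ValueError("ligand group must be flagged is_ligand")
        seen: set[tuple[str, int]] = set()
        for group in self.polymer:
            if group.is_ligand:
                raise ValueError("polymer groups must not be flagged is_ligand")
            ident = (group.chain_id, group.seq_id)
            if ident in seen:
                raise FormatError(f"duplicate residue identifier {ident}")
            seen.add(ident)

    @property
    def residue_keys(self) -> list[ResidueKey]:
        return [g.key for g in self.polymer]

    def residue(self, key: ResidueKey | tuple[str, int]) -> ResidueGroup:
        for group in self.polymer:
            if group.key == key or (group.chain_id, group.seq_id) == key:
                return group
        raise SelectionError(f"no polymer residue with key {key}")

    def neighbor(self, group: ResidueGroup, offset: int) -> ResidueGroup | None:
        """Sequence neighbour at ``seq_id + offset`` in the same chain, if any."""
        for other in self.polymer:
            if other.chain_id == group.chain_id and other.seq_id == group.seq_id + offset:
                return other
        return None

    def all_atoms(self) -> list[Atom]:
        atoms: list[Atom] = []
        for group in self.polymer:
            atoms.extend(group.atoms)
        atoms.extend(self.ligand.atoms)
        return atoms

    def polymer_atoms(self) -> list[Atom]:
        atoms: list[Atom] = []
        for group in self.polymer:
            atoms.extend(group.atoms)
        return atoms


# ---------------------------------------------------------------------------
# reading


def _quantize(value: float, decimals: int = PQR_DECIMALS) -> float:
    return round(float(value), decimals)


def _ligand_matches(group: ResidueGroup, selector: str) -> bool:
    selector = selector.strip()
    if ":" in selector:
        chain, _, seq = selector.partition(":")
        try:
            return group.chain_id == chain and group.seq_id == int(seq)
        except ValueError as exc:
            raise SelectionError(f"bad chain:seq selector {selector!r}") from exc
    return group.res_name == selector


def read_structure(
    path: str | Path,
    format: str | None = None,
    ligand_selector: str = "LIG",
) -> ComplexStructure:
    """Read a PDB or PQR file into a :class:`ComplexStructure`.

    Parameters
    ----------
    path:
        Structure file. ``format`` (``"PDB"``/``"PQR"``) defaults to the file
        suffix.
    ligand_selector:
        Either a residue name (e.g. ``"LIG"``) or a ``chain:seq`` spec
        (e.g. ``"B:9"``); must match exactly one group.

    For PQR input, per-atom charge and radius (used as the Lennard-Jones
    r_min/2) come from the two columns after the coordinates; PDB input
    leaves charges at zero to be filled by :func:`assign_parameters`.
    Alternate locations other than "A"/blank are discarded with a warning.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "PQR"):
        raise FormatError(f"unsupported structure format {fmt!r}")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # MDAnalysis raises assorted types
        raise FormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc

    atoms_u = universe.atoms
    if hasattr(atoms_u, "altLocs"):
        keep = np.isin(atoms_u.altLocs, ("", " ", "A"))
        if not keep.all():
            logger.warning("%s: discarding %d alternate-location atoms", path, int((~keep).sum()))
            atoms_u = atoms_u[keep]

    groups: dict[tuple[str, int, str], ResidueGroup] = {}
    order: list[tuple[str, int, str]] = []
    hetero: set[tuple[str, int, str]] = set()
    for idx, a in enumerate(atoms_u):
        chain = getattr(a, "chainID", "") or getattr(a, "segid", "") or "A"
        res_name = a.resname.strip()
        ident = (str(chain).strip() or "A", int(a.resid), res_name)
        if ident not in groups:
            groups[ident] = ResidueGroup(chain_id=ident[0], seq_id=ident[1], res_name=res_name)
            order.append(ident)
        record = str(getattr(a, "record_type", "ATOM")).upper()
        if record.startswith("HETATM"):
            hetero.add(ident)
        coords = np.array([_quantize(c, 3 if fmt == "PDB" else PQR_DECIMALS) for c in a.position])
        charge = _quantize(getattr(a, "charge", 0.0)) if fmt == "PQR" else 0.0
        radius = _quantize(getattr(a, "radius", 0.0)) if fmt == "PQR" else 0.0
        name = a.name.strip()
        groups[ident].atoms.append(
            Atom(
                serial=idx,
                name=name,
                element=element_from_name(name, res_name),
                coords=coords,
                partial_charge=charge,
                lj_rmin_half=radius,
                residue_key=ident,
            )
        )

    # duplicate (chain, seq) under different residue names is a format error
    seen_ids: dict[tuple[str, int], str] = {}
    for chain, seq, res_name in order:
        prev = seen_ids.get((chain, seq))
        if prev is not None and prev != res_name:
            raise FormatError(f"duplicate residue id {(chain, seq)}: {prev!r} vs {res_name!r}")
        seen_ids[(chain, seq)] = res_name

    matches = [ident for ident in order if _ligand_matches(groups[ident], ligand_selector)]
    if len(matches) != 1:
        raise SelectionError(
            f"ligand selector {ligand_selector!r} matched {len(matches)} groups"
            f" (expected 1): {matches}"
        )
    ligand_ident = matches[0]
    ligand = groups[ligand_ident]
    ligand.is_ligand = True

    polymer = [groups[i] for i in order if i != ligand_ident]
    polymer.sort(key=lambda g: (g.chain_id, g.seq_id))
    for group in polymer:
        if group.backbone_n is None or group.backbone_c is None:
            logger.warning(
                "residue %s missing backbone N/C; flagged non-cleavable", group.key
            )
            group.cleavable = False
    return ComplexStructure(polymer=polymer, ligand=ligand)


# ---------------------------------------------------------------------------
# writing


def write_xyz(system: Sequence[Atom], path: str | Path, comment: str = "") -> None:
    """Write an atom list as standard XYZ (count / comment / element x y z)."""
    if not system:
        raise ValueError("cannot write an empty XYZ file")
    path = Path(path)
    lines = [str(len(system)), comment.replace("\n", " ")]
    for atom in system:
        x, y, z = atom.coords
        lines.append(f"{atom.element:<2s} {x:18.8f} {y:18.8f} {z:18.8f}")
    path.write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> list[Atom]:
    """Parse an XYZ file written by :func:`write_xyz` (or any standard XYZ)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: bad XYZ atom count line") from exc
    atoms = []
    for i, line in enumerate(lines[2 : 2 + count]):
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: bad XYZ coordinate line {line!r}")
        atoms.append(
            Atom(
                serial=i,
                name=parts[0],
                element=parts[0],
                coords=np.array([float(p) for p in parts[1:4]]),
            )
        )
    if len(atoms) != count:
        raise FormatError(f"{path}: XYZ declares {count} atoms, found {len(atoms)}")
    return atoms


def write_pqr(complex_structure: ComplexStructure, path: str | Path) -> None:
    """Write the complex as whitespace-delimited PQR.

    Column order follows the PQR convention: record, serial, name, residue
    name, chain, residue number, x, y, z, charge, radius. The ligand group is
    written as HETATM records after the polymer.
    """
    path = Path(path)
    lines = []
    serial = 1

    def fmt(record: str, group: ResidueGroup, atom: Atom) -> str:
        x, y, z = atom.coords
        return (
            f"{record:<6s}{serial:>5d} {atom.name:<4s} {group.res_name:<4s}"
            f"{group.chain_id:>1s}{group.seq_id:>4d}    "
            f"{x:10.4f}{y:10.4f}{z:10.4f} {atom.partial_charge:8.4f} {atom.lj_rmin_half:7.4f}"
        )

    for group in complex_structure.polymer:
        for atom in group.atoms:
            lines.append(fmt("ATOM", group, atom))
            serial += 1
    for atom in complex_structure.ligand.atoms:
        lines.append(fmt("HETATM", complex_structure.ligand, atom))
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# parameter assignment


def assign_parameters(
    complex_structure: ComplexStructure,
    table: Mapping,
    keep_charges: bool = False,
) -> ComplexStructure:
    """Attach partial charges and LJ parameters from a lookup table, in place.

    ``table`` maps ``(res_name, atom_name)`` — with a bare element-symbol
    fallback — to ``(charge, lj_epsilon, lj_rmin_half)``. With
    ``keep_charges=True`` (PQR input already carries charges) only the LJ
    parameters are taken from the table. Raises
    :class:`~mfccpocket.errors.ParameterizationError` naming every uncovered
    atom.
    """
    missing: list[str] = []
    groups = list(complex_structure.polymer) + [complex_structure.ligand]
    for group in groups:
        for atom in group.atoms:
            entry = table.get((group.res_name, atom.name))
            if entry is None:
                entry = table.get(atom.element)
            if entry is None:
                missing.append(f"{group.res_name}:{atom.name} (element {atom.element})")
                continue
            charge, eps, rmin_half = entry
            if not keep_charges:
                atom.partial_charge = float(charge)
            atom.lj_epsilon = float(eps)
            atom.lj_rmin_half = float(rmin_half)
    if missing:
        raise ParameterizationError(
            "no parameters for atoms: " + ", ".join(sorted(set(missing)))
        )
    polymer_charge = sum(g.net_charge() for g in complex_structure.polymer)
    logger.info("total polymer charge after parameterization: %+.4f e", polymer_charge)
    return complex_structure


def total_charge(atoms: Iterable[Atom]) -> float:
    return float(math.fsum(a.partial_charge for a in atoms))
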
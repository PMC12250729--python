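"""Energy backends for the four-term MFCC evaluation.

Two routes implement the same contract — a scalar energy in kcal/mol for an
atom system at a given dielectric constant:

* :class:`ClassicalBackend`: pairwise Coulomb + Lennard-Jones sum over all
  unordered atom pairs, with the dielectric dividing the Coulomb term as a
  uniform screening factor. Because the MFCC combination subtracts
  identical-geometry subsystems, every intra-fragment term cancels exactly,
  so no bonded terms or 1-2/1-3 exclusions are needed.
* :class:`QmFileBackend`: writes a plain-text single-point job (route line,
  title, charge/multiplicity, Cartesian block) for an external quantum code
  and parses the final energy from its output, converting Hartree to
  kcal/mol. Without a configured runner it only emits inputs.

``pairsum`` is the brute-force double loop over inter-system pairs used as
the independent oracle for the MFCC cancellation property.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import (
    AwaitingEnergiesError,
    ChargeAssignmentError,
    ClashError,
    QmParseError,
)
from .structure import Atom, total_charge, write_xyz  # noqa: F401  (write_xyz re-exported for adapters)

logger = logging.getLogger(__name__)

#: Electrostatic conversion constant, kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0637

#: 1 Hartree in kcal/mol.
HARTREE_TO_KCAL = 627.509474

#: Hard floor on interatomic distances; anything closer is a clash.
MIN_DISTANCE = 0.1


class EnergyBackend(Protocol):
    """Contract: deterministic scalar energy of an atom system, kcal/mol."""

    label: str

    def evaluate(self, system: Sequence[Atom], dielectric: float) -> float: ...


def _arrays(system: Sequence[Atom]):
    coords = np.array([a.coords for a in system], dtype=float).reshape(len(system), 3)
    q = np.array([a.partial_charge for a in system], dtype=float)
    eps = np.array([a.lj_epsilon for a in system], dtype=float)
    rmh = np.array([a.lj_rmin_half for a in system], dtype=float)
    return coords, q, eps, rmh


def _check_clash(dists: np.ndarray, atoms_a: Sequence[Atom], atoms_b: Sequence[Atom] | None = None) -> None:
    if dists.size == 0:
        return
    idx = np.unravel_index(np.argmin(dists), dists.shape)
    if dists[idx] < MIN_DISTANCE:
        if atoms_b is None:
            a, b = atoms_a[idx[0]], atoms_a[idx[1]]
        else:
            a, b = atoms_a[idx[0]], atoms_b[idx[1]]
        raise ClashError(
            f"atoms {a.name}@{a.residue_key} and {b.name}@{b.residue_key} "
            f"are {dists[idx]:.3f} Å apart (< {MIN_DISTANCE} Å)"
        )


def classical_energy(
    system: Sequence[Atom],
    dielectric: float,
    exclude_junction: bool = False,
) -> float:
    """Total pairwise Coulomb + LJ energy of a system, kcal/mol.

    E = Σ_{i<j} [ 332.0637 q_i q_j / (ε r_ij)
                  + ε_ij ((r_min,ij/r_ij)^12 − 2 (r_min,ij/r_ij)^6) ]

    with Lorentz–Berthelot-style combination ε_ij = √(ε_i ε_j) and
    r_min,ij = r_min,i/2 + r_min,j/2. With ``exclude_junction``, hydrogens
    flagged as junction caps contribute nothing.
    """
    if dielectric <= 0:
        raise ValueError("dielectric must be positive")
    if exclude_junction:
        system = [a for a in system if not a.is_junction]
    if len(system) < 2:
        return 0.0
    coords, q, eps, rmh = _arrays(system)
    r = pdist(coords)
    _check_clash(squareform(r) + np.eye(len(system)) * 1e6, system)
    iu = np.triu_indices(len(system), k=1)
    qq = np.outer(q, q)[iu]
    eij = np.sqrt(np.outer(eps, eps))[iu]
    rmin = (rmh[:, None] + rmh[None, :])[iu]
    coulomb = COULOMB_CONSTANT * qq / (dielectric * r)
    ratio6 = np.zeros_like(r)
    nz = eij > 0
    ratio6[nz] = (rmin[nz] / r[nz]) ** 6
    lj = eij * (ratio6**2 - 2.0 * ratio6)
    # exactly-rounded summation: the MFCC combination subtracts totals that
    # share large intra-fragment terms, so summation-order noise must not leak
    return float(math.fsum(coulomb) + math.fsum(lj))


def pairsum(
    system_a: Sequence[Atom],
    system_b: Sequence[Atom],
    dielectric: float,
) -> float:
    """Brute-force interaction energy between two disjoint systems, kcal/mol.

    Double loop over a×b pairs with the same pair formula as
    :func:`classical_energy`; serves as the independent oracle for the MFCC
    term-cancellation property.
    """
    if dielectric <= 0:
        raise ValueError("dielectric must be positive")
    ids_a = {id(a) for a in system_a}
    if any(id(b) in ids_a for b in system_b):
        raise ValueError("pairsum requires disjoint atom lists")
    if not system_a or not system_b:
        return 0.0
    ca, qa, ea, ra = _arrays(system_a)
    cb, qb, eb, rb = _arrays(system_b)
    r = cdist(ca, cb)
    _check_clash(r, system_a, system_b)
    qq = np.outer(qa, qb)
    eij = np.sqrt(np.outer(ea, eb))
    rmin = ra[:, None] + rb[None, :]
    coulomb = COULOMB_CONSTANT * qq / (dielectric * r)
    ratio6 = np.zeros_like(r)
    nz = eij > 0
    ratio6[nz] = (rmin[nz] / r[nz]) ** 6
    lj = eij * (ratio6**2 - 2.0 * ratio6)
    return float(math.fsum(coulomb.ravel()) + math.fsum(lj.ravel()))


@dataclass
class ClassicalBackend:
    """Classical pairwise backend; the desk-scale stand-in for a QM code."""

    exclude_junction: bool = False
    label: str = "classical"

    def evaluate(self, system: Sequence[Atom], dielectric: float) -> float:
        return classical_energy(system, dielectric, exclude_junction=self.exclude_junction)


# ---------------------------------------------------------------------------
# external-QM file adapter


@dataclass
class QmJobSpec:
    """Labels and electronic-state settings for an emitted single-point job."""

    method_label: str = "B97D"
    basis_label: str = "6-311+G(d,p)"
    solvent_model_label: str = "CPCM"
    dielectric: float = 10.0
    net_charge: int | None = None
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")


#: How far a summed partial charge may sit from an integer before rounding
#: is refused and the caller must set net_charge explicitly.
CHARGE_ROUND_TOLERANCE = 0.3


def emit_qm_input(
    system: Sequence[Atom],
    spec: QmJobSpec,
    path: str | Path,
    title: str = "single-point fragment energy",
) -> None:
    """Write a generic plain-text single-point input for an external QM code.

    Layout: route line (method/basis/solvent + dielectric), blank line, title,
    blank line, ``net_charge multiplicity``, then one ``element x y z`` line
    per atom. The net charge defaults to the rounded sum of partial charges;
    if that sum is more than 0.3 e from an integer the caller must decide.
    """
    if not system:
        raise ValueError("cannot emit a QM input for an empty system")
    net = spec.net_charge
    if net is None:
        q = total_charge(system)
        net = int(round(q))
        if abs(q - net) > CHARGE_ROUND_TOLERANCE:
            raise ChargeAssignmentError(
                f"summed charge {q:+.4f} e is {abs(q - net):.4f} e from the nearest "
                f"integer (> {CHARGE_ROUND_TOLERANCE}); set net_charge explicitly"
            )
    lines = [
        f"# {spec.method_label}/{spec.basis_label} "
        f"SCRF=({spec.solvent_model_label},eps={spec.dielectric:g})",
        "",
        title,
        "",
        f"{net} {spec.multiplicity}",
    ]
    for atom in system:
        x, y, z = atom.coords
        lines.append(f"{atom.element:<2s} {x:16.8f} {y:16.8f} {z:16.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


#: Default pattern for the final-energy line of a QM output; the captured
#: group is a value in Hartree.
DEFAULT_ENERGY_PATTERN = r"ENERGY\s*=\s*(-?\d+\.\d+(?:[eE][+-]?\d+)?)"


def parse_qm_energy(path: str | Path, pattern: str = DEFAULT_ENERGY_PATTERN) -> float:
    """Extract the final energy (Hartree) from a QM output; return kcal/mol.

    If several lines match, the last one wins (logged); no match raises
    :class:`~mfccpocket.errors.QmParseError`.
    """
    text = Path(path).read_text()
    matches = re.findall(pattern, text)
    if not matches:
        raise QmParseError(f"{path}: no energy line matching {pattern!r}")
    if len(matches) > 1:
        logger.info("%s: %d energy lines matched; using the last", path, len(matches))
    return float(matches[-1]) * HARTREE_TO_KCAL


#: Runner hook: (input_path, output_path, system, spec) -> None.
QmRunner = Callable[[Path, Path, Sequence[Atom], QmJobSpec], None]


@dataclass
class QmFileBackend:
    """File-based adapter satisfying the backend contract via an external code.

    ``evaluate`` writes the job input under ``workdir`` and, when a ``runner``
    is configured, invokes it and parses the resulting output file. Without a
    runner it raises :class:`AwaitingEnergiesError` after emitting the input,
    so a driver can hand the files to a real QM package and resume later.
    """

    workdir: Path
    job_template: QmJobSpec | None = None
    runner: QmRunner | None = None
    energy_pattern: str = DEFAULT_ENERGY_PATTERN
    label: str = "qm-adapter"
    _counter: int = 0

    def evaluate(self, system: Sequence[Atom], dielectric: float) -> float:
        self.workdir = Path(self.workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        template = self.job_template or QmJobSpec()
        spec = QmJobSpec(
            method_label=template.method_label,
            basis_label=template.basis_label,
            solvent_model_label=template.solvent_model_label,
            dielectric=dielectric,
            net_charge=template.net_charge,
            multiplicity=template.multiplicity,
        )
        self._counter += 1
        stem = f"job_{self._counter:04d}_eps{dielectric:g}"
        inp = self.workdir / f"{stem}.inp"
        out = self.workdir / f"{stem}.out"
        emit_qm_input(system, spec, inp, title=stem)
        if self.runner is None:
            raise AwaitingEnergiesError(
                f"QM input emitted at {inp}; no runner configured"
            )
        self.runner(inp, out, system, spec)
        return parse_qm_energy(out, self.energy_pattern)
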
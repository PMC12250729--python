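"""Synthetic protein–ligand complexes with known ground-truth energetics.

The generator builds a toy but chemically well-formed system: an extended
polypeptide of GLY-like five-atom residues (N, CA, C, O, amide H) with
3.8 Å CA–CA spacing and proper peptide-bond geometry, plus a small rigid
ligand placed so that chosen residues sit at requested minimum distances.
Per-atom partial charges and Lennard-Jones parameters are assigned from
simple schemes and quantized to the precision the PQR format carries, so the
in-memory structure, the written file and the ground truth all describe
exactly the same system.

The ground truth (per-residue ligand interaction energies, shell membership,
convergence radius) is computed by a deliberately naive pure-Python double
loop that shares no code with the vectorized energy backend — that
independence is what makes the equivalence tests meaningful.

What the fixtures emulate: pocket geometry (residues at controlled
distances), charge–charge screening across dielectrics, and energy decay
with distance. What they do not: realistic force-field parameters, side-chain
chemistry, solvent/membrane atoms, or conformational sampling — so agreement
on fixtures validates the bookkeeping and the energy algebra, not force-field
accuracy on real receptors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .errors import GenerationError
from .pocket import DEFAULT_DIELECTRICS, default_radii
from .structure import (
    Atom,
    ComplexStructure,
    ResidueGroup,
    write_pqr,
)

#: Same electrostatic constant as the backend; restated here because the
#: oracle is implemented independently.
_COULOMB = 332.0637

#: GLY-like residue template: atom name -> (element, offset from CA, Å).
RESIDUE_TEMPLATE: dict[str, tuple[str, tuple[float, float, float]]] = {
    "N": ("N", (-1.2, 0.8, 0.0)),
    "CA": ("C", (0.0, 0.0, 0.0)),
    "C": ("C", (1.2, 0.9, 0.0)),
    "O": ("O", (1.3, 2.1, 0.0)),
    "H": ("H", (-1.55, 1.75, 0.0)),
}

#: Optional one-atom side-chain pseudo-atom (exercises side-chain capping).
SIDECHAIN_ATOM = ("CB", "C", (0.0, -1.0, 1.15))

CA_SPACING = 3.8

#: Default per-atom residue charges (sums to zero per residue).
RESIDUE_CHARGES = {"N": -0.4, "CA": 0.1, "C": 0.5, "O": -0.5, "H": 0.3, "CB": 0.0}

#: Default per-element LJ parameters: element -> (epsilon kcal/mol, rmin/2 Å).
#: Radii are scaled to the fixture's contact scale (pocket shells start at
#: 2 Å) so that a 2.1 Å ligand contact sits near the LJ minimum instead of
#: deep inside the repulsive wall; well depths are Amber-like.
LJ_SCHEME = {
    "H": (0.0157, 0.4),
    "C": (0.086, 1.0),
    "N": (0.17, 0.95),
    "O": (0.21, 0.9),
}

_Q = 4  # decimal places retained everywhere (matches the PQR writer)


def _quant(x: float) -> float:
    return round(float(x), _Q)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic complex.

    ``ligand_placement`` lists (1-based residue index, target minimum
    distance Å) constraints the ligand position must satisfy to within
    0.05 Å. ``residue_charge_scale`` multiplies each residue's charges
    (defaults to 1.0 everywhere); ``charge_scheme`` is ``"dipole"``,
    ``"zero"`` or ``"random"``.
    """

    n_residues: int = 3
    ligand_atoms: int = 4
    ligand_placement: list[tuple[int, float]] = field(
        default_factory=lambda: [(1, 2.1), (2, 3.4), (3, 6.0)]
    )
    charge_scheme: str = "dipole"
    ligand_net_charge: float = 0.0
    residue_charge_scale: list[float] | None = None
    lj_scheme: dict[str, tuple[float, float]] | str = "default"
    include_sidechain: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise GenerationError("need at least 3 residues")
        if not 3 <= self.ligand_atoms <= 10:
            raise GenerationError("ligand_atoms must be in 3..10")
        for idx, dist in self.ligand_placement:
            if not 1 <= idx <= self.n_residues:
                raise GenerationError(f"placement residue index {idx} out of range")
            if dist < 1.5:
                raise GenerationError(f"target distance {dist} Å below 1.5 Å")


@dataclass
class GroundTruth:
    """Independent reference energetics for one fixture (naive double loop)."""

    dielectrics: tuple[float, ...]
    radii: tuple[float, ...]
    min_distances: dict[int, float]                      # seq_id -> Å
    pair_energies: dict[tuple[int, float], float]        # (seq_id, eps) -> kcal/mol
    pair_energies_coulomb: dict[tuple[int, float], float]
    pair_energies_lj: dict[int, float]                   # eps-independent
    shell_membership: dict[float, set[int]]              # radius -> seq_id set
    totals: dict[tuple[float, float], float]             # (radius, eps) -> kcal/mol
    converged_radius: float | None
    tolerance: float
    ligand_net_charge: float

    def group_sum(self, seq_ids, dielectric: float) -> float:
        return float(math.fsum(self.pair_energies[(s, dielectric)] for s in seq_ids))

    def to_json_dict(self) -> dict:
        return {
            "dielectrics": list(self.dielectrics),
            "radii": list(self.radii),
            "tolerance": self.tolerance,
            "ligand_net_charge": self.ligand_net_charge,
            "min_distances": {str(k): v for k, v in self.min_distances.items()},
            "pair_energies": {f"{s}:{e:g}": v for (s, e), v in self.pair_energies.items()},
            "pair_energies_coulomb": {
                f"{s}:{e:g}": v for (s, e), v in self.pair_energies_coulomb.items()
            },
            "pair_energies_lj": {str(s): v for s, v in self.pair_energies_lj.items()},
            "shell_membership": {f"{r:g}": sorted(m) for r, m in self.shell_membership.items()},
            "totals": {f"{r:g}:{e:g}": v for (r, e), v in self.totals.items()},
            "converged_radius": self.converged_radius,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# geometry


def _residue_atoms(index: int, spec: FixtureSpec) -> list[tuple[str, str, np.ndarray]]:
    ca = np.array([CA_SPACING * (index - 1), 0.0, 0.0])
    names = dict(RESIDUE_TEMPLATE)
    atoms = [(name, el, ca + np.array(off)) for name, (el, off) in names.items()]
    if spec.include_sidechain:
        name, el, off = SIDECHAIN_ATOM
        atoms.append((name, el, ca + np.array(off)))
    return atoms


def _ligand_offsets(spec: FixtureSpec) -> np.ndarray:
    """Rigid ligand shape: evenly spread points on a 0.8 Å sphere.

    A Fibonacci lattice keeps atoms well separated for any count; a seeded
    random rotation varies the shape's orientation between fixtures.
    """
    n = spec.ligand_atoms
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    points = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    rng = np.random.default_rng(spec.seed + 7919)
    points = points @ _rotation_matrix(rng.uniform(-math.pi, math.pi, size=3)).T
    offsets = 0.8 * points
    return offsets - offsets.mean(axis=0)


def _rotation_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues rotation from an axis-angle vector."""
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-12:
        return np.eye(3)
    k = rotvec / angle
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(angle) * kx + (1 - math.cos(angle)) * (kx @ kx)


def _place_ligand(spec: FixtureSpec, residue_coords: dict[int, np.ndarray]) -> np.ndarray:
    """Find a rigid ligand pose meeting every (residue, min-distance) target.

    The pose has six degrees of freedom (centre + axis-angle orientation);
    each target must be met to within 0.05 Å or the request is infeasible.
    The optimizer aims 0.02 Å below each requested minimum so that a shell
    whose radius equals the request reliably contains the residue despite
    coordinate quantization.
    """
    offsets = _ligand_offsets(spec)
    targets = [(idx, d - 0.02) for idx, d in spec.ligand_placement]

    def pose_coords(params: np.ndarray) -> np.ndarray:
        return params[:3] + offsets @ _rotation_matrix(params[3:]).T

    def achieved(params: np.ndarray) -> dict[int, float]:
        lig = pose_coords(params)
        return {
            idx: float(
                np.min(np.linalg.norm(lig[:, None, :] - coords[None, :, :], axis=2))
            )
            for idx, coords in residue_coords.items()
        }

    def cost(params: np.ndarray) -> float:
        got = achieved(params)
        return sum((got[idx] - d) ** 2 for idx, d in targets)

    first_idx, first_d = targets[0]
    anchor = residue_coords[first_idx].mean(axis=0)
    rng = np.random.default_rng(spec.seed + 104729)
    best = None
    for attempt in range(40):
        if attempt < 4:
            direction = (np.array([0.0, 0.2, 1.0]), np.array([0.0, 1.0, 0.3]),
                         np.array([-0.5, 0.3, 1.0]), np.array([0.5, -0.3, 1.0]))[attempt]
            rot0 = np.zeros(3)
        else:
            direction = rng.normal(size=3)
            direction[2] = abs(direction[2]) + 0.2
            rot0 = rng.uniform(-np.pi, np.pi, size=3)
        center0 = anchor + (first_d + 1.4) * direction / np.linalg.norm(direction)
        x0 = np.concatenate([center0, rot0])
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"fatol": 1e-12, "xatol": 1e-7, "maxiter": 4000,
                                "maxfev": 4000})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-8:
            break
    got = achieved(best.x)
    bad = [
        (idx, d, got[idx])
        for idx, d in spec.ligand_placement
        if abs(got[idx] - d) > 0.05
    ]
    if bad:
        raise GenerationError(
            "infeasible ligand placement; unmet targets (residue, wanted, got): "
            + ", ".join(f"({i}, {d:.2f}, {g:.2f})" for i, d, g in bad)
        )
    return pose_coords(best.x)


# ---------------------------------------------------------------------------
# parameters


def _lj_table(spec: FixtureSpec) -> dict[str, tuple[float, float]]:
    if spec.lj_scheme == "default":
        return dict(LJ_SCHEME)
    if spec.lj_scheme == "zero":
        return {el: (0.0, 0.0) for el in LJ_SCHEME}
    if isinstance(spec.lj_scheme, dict):
        return dict(spec.lj_scheme)
    raise GenerationError(f"unknown lj_scheme {spec.lj_scheme!r}")


def _residue_charges(spec: FixtureSpec, rng: np.random.Generator) -> dict[int, dict[str, float]]:
    scales = spec.residue_charge_scale or [1.0] * spec.n_residues
    if len(scales) != spec.n_residues:
        raise GenerationError("residue_charge_scale length must equal n_residues")
    out: dict[int, dict[str, float]] = {}
    for i in range(1, spec.n_residues + 1):
        if spec.charge_scheme == "zero":
            base = {name: 0.0 for name in RESIDUE_CHARGES}
        elif spec.charge_scheme == "random":
            base = {name: float(rng.uniform(-0.5, 0.5)) for name in RESIDUE_CHARGES}
        elif spec.charge_scheme == "dipole":
            base = dict(RESIDUE_CHARGES)
        else:
            raise GenerationError(f"unknown charge_scheme {spec.charge_scheme!r}")
        out[i] = {name: _quant(q * scales[i - 1]) for name, q in base.items()}
    return out


def _ligand_charges(spec: FixtureSpec, rng: np.random.Generator) -> list[float]:
    n = spec.ligand_atoms
    if spec.charge_scheme == "zero":
        charges = [0.0] * n
    elif spec.charge_scheme == "random":
        charges = [float(rng.uniform(-0.4, 0.4)) for _ in range(n)]
    else:
        charges = [0.3 if i % 2 == 0 else -0.3 for i in range(n)]
    charges = [_quant(q) for q in charges]
    # shift the last atom so the quantized net charge is exactly as declared
    drift = spec.ligand_net_charge - math.fsum(charges)
    charges[-1] = _quant(charges[-1] + drift)
    return charges


# ---------------------------------------------------------------------------
# the naive oracle (no shared code with the backend)


def _naive_pair_energy(
    lig: list[Atom], res: list[Atom], dielectric: float
) -> tuple[float, float]:
    """(coulomb, lj) energies by an explicit double loop, kcal/mol."""
    coulomb = 0.0
    lj = 0.0
    for a in lig:
        for b in res:
            dx = a.coords[0] - b.coords[0]
            dy = a.coords[1] - b.coords[1]
            dz = a.coords[2] - b.coords[2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            coulomb += _COULOMB * a.partial_charge * b.partial_charge / (dielectric * r)
            eij = math.sqrt(a.lj_epsilon * b.lj_epsilon)
            if eij > 0.0:
                s = (a.lj_rmin_half + b.lj_rmin_half) / r
                lj += eij * (s**12 - 2.0 * s**6)
    return coulomb, lj


def _naive_min_distance(lig: list[Atom], res: list[Atom]) -> float:
    best = math.inf
    for a in lig:
        for b in res:
            d = math.dist(tuple(a.coords), tuple(b.coords))
            best = min(best, d)
    return best


def _naive_converged_radius(
    radii, totals, dielectrics, tolerance
) -> float | None:
    for prev, curr in zip(radii, radii[1:]):
        ok, compared = True, False
        for eps in dielectrics:
            t_prev = totals[(prev, eps)]
            if t_prev == 0.0:
                continue
            compared = True
            if abs(totals[(curr, eps)] - t_prev) / abs(t_prev) >= tolerance:
                ok = False
        if ok and compared:
            return curr
    return None


# ---------------------------------------------------------------------------
# public API


def generate_complex(spec: FixtureSpec) -> tuple[ComplexStructure, GroundTruth]:
    """Build the complex and its ground truth; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    lj_table = _lj_table(spec)
    res_charges = _residue_charges(spec, rng)

    serial = 0
    polymer: list[ResidueGroup] = []
    residue_coords: dict[int, np.ndarray] = {}
    for i in range(1, spec.n_residues + 1):
        group = ResidueGroup(chain_id="A", seq_id=i, res_name="GLY")
        coords_list = []
        for name, element, coords in _residue_atoms(i, spec):
            coords = np.array([_quant(c) for c in coords])
            eps, rmh = lj_table.get(element, (0.0, 0.0))
            group.atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    coords=coords,
                    partial_charge=res_charges[i][name],
                    lj_epsilon=eps,
                    lj_rmin_half=rmh,
                    residue_key=group.key,
                )
            )
            coords_list.append(coords)
            serial += 1
        polymer.append(group)
        residue_coords[i] = np.array(coords_list)

    lig_coords = _place_ligand(spec, residue_coords)
    lig_charges = _ligand_charges(spec, rng)
    elements = ["C", "N", "O"]
    ligand = ResidueGroup(chain_id="B", seq_id=900, res_name="LIG", is_ligand=True)
    for j in range(spec.ligand_atoms):
        element = elements[j % len(elements)]
        eps, rmh = lj_table.get(element, (0.0, 0.0))
        ligand.atoms.append(
            Atom(
                serial=serial,
                name=f"{element}{j + 1}",
                element=element,
                coords=np.array([_quant(c) for c in lig_coords[j]]),
                partial_charge=lig_charges[j],
                lj_epsilon=eps,
                lj_rmin_half=rmh,
                residue_key=ligand.key,
            )
        )
        serial += 1

    structure = ComplexStructure(polymer=polymer, ligand=ligand)
    truth = _ground_truth(structure, spec)
    return structure, truth


def _ground_truth(
    structure: ComplexStructure,
    spec: FixtureSpec,
    dielectrics: tuple[float, ...] = DEFAULT_DIELECTRICS,
    radii: tuple[float, ...] | None = None,
    tolerance: float = 0.10,
) -> GroundTruth:
    radii = radii or default_radii()
    lig = structure.ligand.atoms
    mins: dict[int, float] = {}
    pair: dict[tuple[int, float], float] = {}
    pair_c: dict[tuple[int, float], float] = {}
    pair_lj: dict[int, float] = {}
    for group in structure.polymer:
        seq = group.seq_id
        mins[seq] = _naive_min_distance(lig, group.atoms)
        for eps in dielectrics:
            coulomb, lj = _naive_pair_energy(lig, group.atoms, eps)
            pair[(seq, eps)] = coulomb + lj
            pair_c[(seq, eps)] = coulomb
            pair_lj[seq] = lj
    shells = {r: {s for s, d in mins.items() if d <= r} for r in radii}
    totals = {
        (r, eps): float(math.fsum(pair[(s, eps)] for s in shells[r]))
        for r in radii
        for eps in dielectrics
    }
    converged = _naive_converged_radius(radii, totals, dielectrics, tolerance)
    return GroundTruth(
        dielectrics=dielectrics,
        radii=radii,
        min_distances=mins,
        pair_energies=pair,
        pair_energies_coulomb=pair_c,
        pair_energies_lj=pair_lj,
        shell_membership=shells,
        totals=totals,
        converged_radius=converged,
        tolerance=tolerance,
        ligand_net_charge=spec.ligand_net_charge,
    )


def write_fixture(
    spec: FixtureSpec, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Write fixture.pqr, params.json (LJ table) and ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure, truth = generate_complex(spec)
    pqr = outdir / "fixture.pqr"
    write_pqr(structure, pqr)
    params = outdir / "params.json"
    # assign_parameters triples (charge, epsilon, rmin/2); charges come from
    # the PQR itself, so the table's charge column is a placeholder zero
    params.write_text(
        json.dumps({el: [0.0, eps, rmh] for el, (eps, rmh) in _lj_table(spec).items()},
                   indent=2) + "\n"
    )
    truth_path = outdir / "ground_truth.json"
    truth.write_json(truth_path)
    return pqr, params, truth_path


def decaying_energy_fixture(seed: int = 0) -> tuple[ComplexStructure, GroundTruth]:
    """Fixture whose shell-total series converges under the 10% rule.

    Five residues, Coulomb-only (so shell totals scale exactly as 1/ε); the
    ligand sits nearest residue 2, and per-residue charge scales fall off
    along the chain so that the first shell addition changes the running
    total by well over 10% while later additions change it by less — the
    ground truth records the resulting converged radius.
    """
    spec = decaying_fixture_spec(seed)
    return generate_complex(spec)


def decaying_fixture_spec(seed: int = 0) -> FixtureSpec:
    return FixtureSpec(
        n_residues=5,
        ligand_atoms=4,
        ligand_placement=[(2, 2.1), (1, 3.0), (3, 3.4)],
        charge_scheme="dipole",
        residue_charge_scale=[0.5, 1.0, 0.08, 0.04, 0.02],
        lj_scheme="zero",
        seed=seed,
    )
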
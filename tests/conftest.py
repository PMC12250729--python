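"""Shared fixtures: synthetic complexes with ground truth, format helpers."""

from __future__ import annotations

import warnings

import pytest

from mfccpocket import ComplexStructure, FixtureSpec, generate_complex
from mfccpocket.synthetic import decaying_energy_fixture

warnings.filterwarnings("ignore", module="MDAnalysis")


@pytest.fixture(scope="session")
def default_fixture():
    """3-residue complex with ligand at min distances ~2.1/3.4/6.0 Å."""
    return generate_complex(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def chain5_fixture():
    """5-residue chain; middle residues have neighbours on both sides."""
    spec = FixtureSpec(
        n_residues=5,
        ligand_atoms=4,
        ligand_placement=[(3, 2.5)],
        seed=11,
    )
    return generate_complex(spec)


@pytest.fixture(scope="session")
def decaying_fixture():
    """Coulomb-only fixture whose shell totals converge under the 10% rule."""
    return decaying_energy_fixture(0)


def structure_to_pdb_text(structure: ComplexStructure) -> str:
    """Minimal fixed-column PDB rendering of a complex (test-side helper)."""
    lines = []
    serial = 1
    for group in list(structure.polymer) + [structure.ligand]:
        record = "HETATM" if group.is_ligand else "ATOM  "
        for atom in group.atoms:
            x, y, z = atom.coords
            lines.append(
                f"{record}{serial:>5d} {atom.name:<4s} {group.res_name:<3s}"
                f" {group.chain_id}{group.seq_id:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
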
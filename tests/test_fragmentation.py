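"""Quartet construction, cap geometry and MFCC energy assembly."""

import numpy as np
import pytest

from mfccpocket import (
    CapSpec,
    ClassicalBackend,
    ComplexStructure,
    FixtureSpec,
    build_quartet,
    generate_complex,
    mfcc_interaction_energy,
    pairsum,
)
from mfccpocket.errors import BackendError, FragmentationError
from mfccpocket.structure import Atom, ResidueGroup

ATOMS_PER_RESIDUE = 5  # GLY-like template: N, CA, C, O, H


class StubBackend:
    """Returns preset energies keyed by system role order of evaluation."""

    label = "stub"

    def __init__(self, values):
        self.values = list(values)
        self.calls = 0

    def evaluate(self, system, dielectric):
        value = self.values[self.calls]
        self.calls += 1
        return value


class TestQuartetBookkeeping:
    def test_middle_residue_of_three_chain(self, default_fixture):
        structure, _ = default_fixture
        quartet = build_quartet(structure, ("A", 2))
        n_lig = len(structure.ligand.atoms)

        # caps are the chain termini; outer valences are hydrogen-saturated
        assert len(quartet.outer_hydrogens) == 2
        assert len(quartet.junction_hydrogens) == 2
        assert len(quartet.sys_cap_R_cap) == 3 * ATOMS_PER_RESIDUE + 2
        assert len(quartet.sys_concap) == 2 * ATOMS_PER_RESIDUE + 2 + 2
        assert len(quartet.sys_L_cap_R_cap) == len(quartet.sys_cap_R_cap) + n_lig
        assert len(quartet.sys_L_concap) == len(quartet.sys_concap) + n_lig

    def test_concap_contains_no_target_atom(self, default_fixture):
        structure, _ = default_fixture
        target_atoms = {id(a) for a in structure.residue(("A", 2)).atoms}
        quartet = build_quartet(structure, ("A", 2))
        assert not target_atoms & {id(a) for a in quartet.sys_concap}
        assert target_atoms <= {id(a) for a in quartet.sys_cap_R_cap}

    def test_receptor_systems_contain_no_ligand_atom(self, default_fixture):
        structure, _ = default_fixture
        ligand_ids = {id(a) for a in structure.ligand.atoms}
        quartet = build_quartet(structure, ("A", 2))
        assert not ligand_ids & {id(a) for a in quartet.sys_cap_R_cap}
        assert not ligand_ids & {id(a) for a in quartet.sys_concap}

    def test_shared_atoms_have_identical_coordinates(self, default_fixture):
        """No re-optimization: the ligand-present and ligand-absent systems
        share their receptor atoms bitwise."""
        structure, _ = default_fixture
        quartet = build_quartet(structure, ("A", 2))
        n_lig = len(structure.ligand.atoms)
        for with_l, without_l in (
            (quartet.sys_L_cap_R_cap, quartet.sys_cap_R_cap),
            (quartet.sys_L_concap, quartet.sys_concap),
        ):
            receptor_part = with_l[n_lig:]
            assert len(receptor_part) == len(without_l)
            for a, b in zip(receptor_part, without_l):
                assert a is b

    def test_interior_residue_junction_geometry(self, chain5_fixture):
        structure, _ = chain5_fixture
        spec = CapSpec()
        quartet = build_quartet(structure, ("A", 3), spec)
        assert len(quartet.junction_hydrogens) == 2

        prev_c = structure.residue(("A", 2)).backbone_c
        next_n = structure.residue(("A", 4)).backbone_n
        h_on_c, h_on_n = quartet.junction_hydrogens
        assert np.linalg.norm(h_on_c.coords - prev_c.coords) == pytest.approx(
            spec.ch_bond_length, abs=1e-9
        )
        assert np.linalg.norm(h_on_n.coords - next_n.coords) == pytest.approx(
            spec.nh_bond_length, abs=1e-9
        )
        # placed along the former bond vectors
        n_target = structure.residue(("A", 3)).backbone_n
        bond = n_target.coords - prev_c.coords
        cos = np.dot(h_on_c.coords - prev_c.coords, bond) / (
            np.linalg.norm(h_on_c.coords - prev_c.coords) * np.linalg.norm(bond)
        )
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_outer_hydrogens_follow_former_bonds(self, chain5_fixture):
        structure, _ = chain5_fixture
        spec = CapSpec()
        quartet = build_quartet(structure, ("A", 3), spec)
        assert len(quartet.outer_hydrogens) == 2
        h_minus, h_plus = quartet.outer_hydrogens
        n2 = structure.residue(("A", 2)).backbone_n
        c1 = structure.residue(("A", 1)).backbone_c
        assert np.linalg.norm(h_minus.coords - n2.coords) == pytest.approx(
            spec.nh_bond_length, abs=1e-9
        )
        direction = (c1.coords - n2.coords) / np.linalg.norm(c1.coords - n2.coords)
        assert np.allclose(
            h_minus.coords, n2.coords + spec.nh_bond_length * direction, atol=1e-9
        )
        c4 = structure.residue(("A", 4)).backbone_c
        assert np.linalg.norm(h_plus.coords - c4.coords) == pytest.approx(
            spec.ch_bond_length, abs=1e-9
        )

    def test_first_residue_uses_single_cap(self, default_fixture):
        structure, _ = default_fixture
        quartet = build_quartet(structure, ("A", 1))
        res2_ids = {id(a) for a in structure.residue(("A", 2)).atoms}
        res3_ids = {id(a) for a in structure.residue(("A", 3)).atoms}
        concap_ids = {id(a) for a in quartet.sys_concap}
        assert res2_ids <= {id(a) for a in quartet.sys_cap_R_cap}
        assert res2_ids <= concap_ids
        assert not res3_ids & concap_ids
        assert len(quartet.junction_hydrogens) == 1


class TestQuartetErrors:
    def test_ligand_cannot_be_fragmented(self, default_fixture):
        structure, _ = default_fixture
        with pytest.raises(FragmentationError):
            build_quartet(structure, structure.ligand.key)

    def test_lone_residue_cannot_be_fragmented(self, default_fixture):
        structure, _ = default_fixture
        lone = ComplexStructure(
            polymer=[structure.polymer[0]], ligand=structure.ligand
        )
        with pytest.raises(FragmentationError):
            build_quartet(lone, ("A", 1))

    def test_chain_break_treated_as_terminus(self):
        structure, _ = generate_complex(FixtureSpec(seed=6))
        far = structure.residue(("A", 3))
        for atom in far.atoms:
            atom.coords = atom.coords + np.array([50.0, 0.0, 0.0])
        quartet = build_quartet(structure, ("A", 2))
        assert not {id(a) for a in far.atoms} & {id(a) for a in quartet.sys_cap_R_cap}
        assert len(quartet.junction_hydrogens) == 1

    def test_sidechain_bridge_rejected(self):
        structure, _ = generate_complex(FixtureSpec(seed=6, include_sidechain=True))
        cb2 = structure.residue(("A", 2)).atom_by_name("CB")
        cb1 = structure.residue(("A", 1)).atom_by_name("CB")
        cb2.coords = cb1.coords + np.array([1.5, 0.0, 0.0])
        with pytest.raises(FragmentationError, match="CB"):
            build_quartet(structure, ("A", 2))


class TestMfccEnergy:
    @pytest.mark.parametrize(
        "values,expected",
        [((-100.0, -60.0, -55.0, -15.0), 0.0), ((-10.0, -4.0, -7.0, -2.0), -1.0)],
    )
    def test_four_term_arithmetic(self, default_fixture, values, expected):
        structure, _ = default_fixture
        quartet = build_quartet(structure, ("A", 2))
        assert mfcc_interaction_energy(quartet, StubBackend(values), 10.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_backend_failure_names_system(self, default_fixture):
        structure, _ = default_fixture
        quartet = build_quartet(structure, ("A", 2))

        class Failing:
            label = "failing"

            def evaluate(self, system, dielectric):
                raise RuntimeError("boom")

        with pytest.raises(BackendError, match="L_cap_R_cap"):
            mfcc_interaction_energy(quartet, Failing(), 10.0)

    @pytest.mark.parametrize("eps", [10.0, 20.0, 40.0])
    def test_ghost_junction_reproduces_direct_pair_energy(self, chain5_fixture, eps):
        """With zero-parameter cap hydrogens the four-term combination equals
        the brute-force ligand-residue pair energy (term cancellation)."""
        structure, _ = chain5_fixture
        backend = ClassicalBackend()
        for key in structure.residue_keys:
            quartet = build_quartet(structure, key)
            mfcc = mfcc_interaction_energy(quartet, backend, eps)
            direct = pairsum(structure.ligand.atoms, structure.residue(key).atoms, eps)
            assert mfcc == pytest.approx(direct, abs=1e-8)

    def test_charged_junction_hydrogens_follow_cancellation_identity(self, chain5_fixture):
        """With real (charged) cap hydrogens, E_I = pairsum(L, R_i)
        - pairsum(L, junction H): only the junction hydrogens survive the
        cancellation because the outer hydrogens appear in both receptor
        systems."""
        structure, _ = chain5_fixture
        spec = CapSpec(hydrogen_charge=0.25, hydrogen_lj=(0.02, 0.5))
        backend = ClassicalBackend()
        quartet = build_quartet(structure, ("A", 3), spec)
        mfcc = mfcc_interaction_energy(quartet, backend, 10.0)
        lig = structure.ligand.atoms
        expected = pairsum(lig, structure.residue(("A", 3)).atoms, 10.0) - pairsum(
            lig, quartet.junction_hydrogens, 10.0
        )
        assert mfcc == pytest.approx(expected, abs=1e-8)
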
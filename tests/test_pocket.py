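"""Shell selection, convergence rule, ranking and group sums."""

import math

import pytest

from mfccpocket import (
    ClassicalBackend,
    ScanConfig,
    group_sum,
    rank_residues,
    residues_within,
    run_scan,
)
from mfccpocket.pocket import (
    ProfileEntry,
    ResidueEnergyProfile,
    find_converged_radius,
)

EPS = 10.0

# per-residue interaction energies reported for the lemborexant-receptor
# complex (kcal/mol), used as a ready-made ranking/grouping dataset
LEMBOREXANT_RESIDUES = [
    ("HIS", 344, -5.43), ("VAL", 130, -4.93), ("TYR", 311, -4.54),
    ("GLN", 126, -4.38), ("ILE", 314, -4.00), ("ASN", 318, -3.81),
    ("VAL", 347, -2.07), ("TYR", 244, -1.77), ("ALA", 127, -1.66),
    ("SER", 315, -1.63), ("THR", 223, -1.63), ("TYR", 348, -1.59),
    ("LYS", 321, -1.56), ("GLU", 204, -1.44), ("VAL", 134, -1.17),
]


def literature_profile():
    entries = [
        ProfileEntry(residue_key=("A", seq, name), min_distance=1.0,
                     energies={EPS: energy})
        for name, seq, energy in LEMBOREXANT_RESIDUES
    ]
    return ResidueEnergyProfile(entries=entries, dielectrics=(EPS,))


class TestResiduesWithin:
    @pytest.mark.parametrize("radius,expected", [(2.5, {1}), (3.5, {1, 2}), (6.0, {1, 2, 3})])
    def test_shell_membership_matches_construction(self, default_fixture, radius, expected):
        structure, truth = default_fixture
        members = residues_within(structure, radius)
        assert {k[1] for k in members} == expected == truth.shell_membership[radius]

    def test_radius_below_closest_contact_is_empty(self, default_fixture):
        structure, _ = default_fixture
        assert residues_within(structure, 1.6) == {}

    def test_largest_radius_holds_all_residues(self, default_fixture):
        structure, _ = default_fixture
        assert len(residues_within(structure, 8.0)) == len(structure.polymer)

    def test_min_distances_reported(self, default_fixture):
        structure, truth = default_fixture
        members = residues_within(structure, 8.0)
        for key, dist in members.items():
            assert dist == pytest.approx(truth.min_distances[key[1]], abs=1e-9)

    def test_shells_are_nested(self, decaying_fixture):
        structure, _ = decaying_fixture
        radii = [2.0, 2.5, 3.0, 4.0, 6.0, 8.0]
        shells = [set(residues_within(structure, r)) for r in radii]
        for smaller, larger in zip(shells, shells[1:]):
            assert smaller <= larger


class TestConvergenceRule:
    def test_stated_series_converges_at_third_radius(self):
        radii = (1.0, 2.0, 3.0, 4.0)
        series = [-10.0, -12.0, -12.5, -12.6]
        totals = {(r, EPS): t for r, t in zip(radii, series)}
        # relative changes: 20%, 4.17%, 0.8% -> first success at the 3rd radius
        assert find_converged_radius(radii, totals, [EPS], 0.10) == 3.0

    def test_zero_tolerance_never_converges(self):
        radii = (1.0, 2.0, 3.0)
        totals = {(r, EPS): -5.0 for r in radii}
        assert find_converged_radius(radii, totals, [EPS], 0.0) is None

    def test_zero_denominator_comparisons_skipped(self):
        radii = (1.0, 2.0, 3.0)
        totals = {(1.0, EPS): 0.0, (2.0, EPS): -4.0, (3.0, EPS): -4.1}
        assert find_converged_radius(radii, totals, [EPS], 0.10) == 3.0

    def test_requires_all_dielectrics_simultaneously(self):
        radii = (1.0, 2.0)
        totals = {(1.0, 10.0): -10.0, (2.0, 10.0): -10.1,
                  (1.0, 20.0): -5.0, (2.0, 20.0): -8.0}
        assert find_converged_radius(radii, totals, [10.0, 20.0], 0.10) is None


class TestRunScan:
    def test_totals_match_ground_truth(self, decaying_fixture):
        structure, truth = decaying_fixture
        scan, profile = run_scan(structure, ClassicalBackend())
        assert scan.converged_radius == truth.converged_radius
        for r in scan.radii:
            assert {k[1] for k in scan.shell_members[r]} == truth.shell_membership[r]
            for eps in (10.0, 20.0, 40.0):
                assert scan.totals[(r, eps)] == pytest.approx(
                    truth.totals[(r, eps)], abs=1e-8
                )

    def test_totals_equal_shell_restricted_profile_sums(self, decaying_fixture):
        structure, _ = decaying_fixture
        scan, profile = run_scan(structure, ClassicalBackend())
        for r in scan.radii:
            members = sorted(scan.shell_members[r])
            for eps in (10.0, 20.0, 40.0):
                assert scan.totals[(r, eps)] == group_sum(profile, members, eps)

    def test_single_member_shell_total_equals_residue_energy(self, decaying_fixture):
        structure, _ = decaying_fixture
        scan, profile = run_scan(structure, ClassicalBackend())
        one_member = [r for r in scan.radii if len(scan.shell_members[r]) == 1]
        assert one_member
        for r in one_member:
            (key,) = scan.shell_members[r]
            assert scan.totals[(r, EPS)] == profile.entry(key).energies[EPS]

    def test_tolerance_one_converges_at_second_nonzero_radius(self, decaying_fixture):
        structure, _ = decaying_fixture
        scan, _ = run_scan(structure, ClassicalBackend(), ScanConfig(tolerance=1.0))
        nonzero = [r for r in scan.radii if scan.totals[(r, EPS)] != 0.0]
        assert scan.converged_radius == nonzero[1]

    def test_backend_failure_yields_partial_results(self, decaying_fixture):
        structure, _ = decaying_fixture

        class FailsOnResidueOne:
            label = "flaky"
            inner = ClassicalBackend()

            def evaluate(self, system, dielectric):
                if any(a.residue_key == ("A", 1, "GLY") for a in system):
                    raise RuntimeError("synthetic failure")
                return self.inner.evaluate(system, dielectric)

        scan, profile = run_scan(structure, FailsOnResidueOne())
        assert scan.failures
        surviving = {e.residue_key for e in profile.entries}
        assert surviving
        assert all(k not in scan.failures for k in surviving)


class TestRankingAndGroups:
    def test_rank_most_negative_first(self):
        profile = ResidueEnergyProfile(
            entries=[
                ProfileEntry(("A", 1, "AAA"), 1.0, {EPS: -5.0}),
                ProfileEntry(("A", 2, "BBB"), 1.0, {EPS: -1.0}),
                ProfileEntry(("A", 3, "CCC"), 1.0, {EPS: -3.0}),
            ],
            dielectrics=(EPS,),
        )
        ranked = [e.residue_key[2] for e in rank_residues(profile, EPS)]
        assert ranked == ["AAA", "CCC", "BBB"]

    def test_ties_break_by_sequence(self):
        profile = ResidueEnergyProfile(
            entries=[
                ProfileEntry(("A", 7, "XXX"), 1.0, {EPS: -2.0}),
                ProfileEntry(("A", 3, "YYY"), 1.0, {EPS: -2.0}),
            ],
            dielectrics=(EPS,),
        )
        assert [e.residue_key[1] for e in rank_residues(profile, EPS)] == [3, 7]

    def test_unknown_dielectric_rejected(self):
        with pytest.raises(ValueError):
            rank_residues(literature_profile(), 99.0)

    def test_reported_residue_list_is_already_ranked(self):
        # SER315/THR223 tie at -1.63; our rule breaks ties by sequence number
        profile = literature_profile()
        ranked = [e.residue_key[1] for e in rank_residues(profile, EPS)]
        expected = [seq for _, seq, _ in
                    sorted(LEMBOREXANT_RESIDUES, key=lambda t: (t[2], t[1]))]
        assert ranked == expected
        energies = [e.energies[EPS] for e in rank_residues(profile, EPS)]
        assert energies == sorted(energies)

    def test_key_residue_group_sum(self):
        """The four strongest residues of the lemborexant complex jointly
        contribute -19.28 kcal/mol."""
        profile = literature_profile()
        keys = [("A", seq, name) for name, seq, _ in LEMBOREXANT_RESIDUES[:4]]
        assert group_sum(profile, keys, EPS) == pytest.approx(-19.28, abs=1e-9)

    def test_empty_group_sums_to_zero(self):
        assert group_sum(literature_profile(), [], EPS) == 0.0

    def test_missing_key_rejected(self):
        with pytest.raises(KeyError):
            group_sum(literature_profile(), [("A", 1, "ZZZ")], EPS)

    def test_dielectric_ordering_of_magnitudes(self, decaying_fixture):
        """Coulomb-dominated totals shrink in magnitude as the dielectric
        grows, at every radius."""
        structure, _ = decaying_fixture
        scan, _ = run_scan(structure, ClassicalBackend())
        for r in scan.radii:
            m10 = abs(scan.totals[(r, 10.0)])
            m20 = abs(scan.totals[(r, 20.0)])
            m40 = abs(scan.totals[(r, 40.0)])
            assert m10 >= m20 >= m40
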
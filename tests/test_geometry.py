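"""Order parameters against brute-force distance oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycoclam.geometry import (
    contact_fraction,
    glycan_lobe_min_distance,
    interlobe_distance,
    joint_histogram,
    min_heavy_distance,
)
from glycoclam.structure import AtomRecord, Frame, Trajectory, select_atoms


def _frame_from_coords(coords, chain="A", residue_start=1, element="C", atom_name="CA"):
    atoms = [
        AtomRecord(i + 1, atom_name, "ALA", chain, residue_start + i, element, *xyz)
        for i, xyz in enumerate(coords)
    ]
    return Frame(model_index=1, atoms=atoms)


def _two_marker_frame(pos_a, pos_b):
    return Frame(
        model_index=1,
        atoms=[
            AtomRecord(1, "CA", "ALA", "A", 507, "C", *pos_a),
            AtomRecord(2, "CA", "ALA", "B", 701, "C", *pos_b),
        ],
    )


class TestInterlobeDistance:
    def test_constructed_37_angstrom_pair(self):
        frame = _two_marker_frame((0, 0, 0), (37.0, 0, 0))
        assert interlobe_distance(frame) == pytest.approx(3.7)

    def test_coincident_markers_give_zero(self):
        frame = _two_marker_frame((1, 2, 3), (1, 2, 3))
        assert interlobe_distance(frame) == pytest.approx(0.0)

    def test_matches_brute_force_on_random_frame(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-30, 30, size=(50, 3))
        atoms = [
            AtomRecord(i + 1, "CA", "ALA", "A", 500 + i, "C", *xyz)
            for i, xyz in enumerate(coords)
        ]
        frame = Frame(1, atoms)
        got = interlobe_distance(frame, res_a=507, res_b=530)
        expected = np.sqrt(((coords[7] - coords[30]) ** 2).sum()) * 0.1
        assert got == pytest.approx(expected, abs=1e-12)

    def test_ambiguous_selection_names_residue_and_count(self):
        frame = Frame(
            1,
            [
                AtomRecord(1, "CA", "ALA", "A", 507, "C", 0, 0, 0),
                AtomRecord(2, "CA", "ALA", "B", 507, "C", 1, 0, 0),
                AtomRecord(3, "CA", "ALA", "B", 701, "C", 2, 0, 0),
            ],
        )
        with pytest.raises(ValueError, match="507.*2 atoms"):
            interlobe_distance(frame)

    def test_invariant_under_rigid_rotation_and_translation(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-10, 10, size=(5, 3))
        frame = _frame_from_coords(coords, residue_start=505)
        # random rotation via QR of a Gaussian matrix
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = coords @ q.T + np.array([5.0, -3.0, 12.0])
        frame2 = _frame_from_coords(moved, residue_start=505)
        d1 = interlobe_distance(frame, res_a=505, res_b=509)
        d2 = interlobe_distance(frame2, res_a=505, res_b=509)
        assert d2 == pytest.approx(d1, abs=1e-12)


class TestMinDistance:
    def test_single_close_pair(self):
        lobe = [(10 + i, 0, 0) for i in range(5)]
        glycan = [(10, 4.0, 0), (0, 50, 0)]
        atoms = _frame_from_coords(lobe, chain="B", residue_start=710).atoms + [
            AtomRecord(10 + i, "C1", "MAN", "G", i + 1, "C", *xyz) for i, xyz in enumerate(glycan)
        ]
        frame = Frame(1, atoms)
        gly_idx = select_atoms(frame, chain="G")
        assert glycan_lobe_min_distance(frame, gly_idx) == pytest.approx(0.4)

    def test_coincident_atoms_give_zero(self):
        atoms = _frame_from_coords([(1, 1, 1)], chain="B", residue_start=712).atoms + [
            AtomRecord(9, "C1", "MAN", "G", 1, "C", 1, 1, 1)
        ]
        frame = Frame(1, atoms)
        assert glycan_lobe_min_distance(frame, np.array([1])) == pytest.approx(0.0)

    def test_matches_exhaustive_all_pairs_minimum(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 40, size=(20, 3))
        b = rng.uniform(0, 40, size=(30, 3))
        atoms = [
            AtomRecord(i + 1, "C1", "MAN", "G", i + 1, "C", *xyz) for i, xyz in enumerate(a)
        ] + [
            AtomRecord(100 + i, "CA", "ALA", "B", 710 + i % 14, "C", *xyz)
            for i, xyz in enumerate(b)
        ]
        frame = Frame(1, atoms)
        got = glycan_lobe_min_distance(frame, np.arange(20))
        brute = min(np.sqrt(((pa - pb) ** 2).sum()) for pa in a for pb in b) * 0.1
        assert got == pytest.approx(brute, abs=1e-12)

    def test_empty_side_identified(self):
        frame = Frame(1, [AtomRecord(1, "CA", "ALA", "B", 712, "C", 0, 0, 0)])
        with pytest.raises(ValueError, match="glycan"):
            glycan_lobe_min_distance(frame, np.array([], dtype=int))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded_by_any_pair(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 20, size=(4, 3))
        b = rng.uniform(0, 20, size=(6, 3))
        atoms = [
            AtomRecord(i + 1, "C", "X", "A", i + 1, "C", *xyz) for i, xyz in enumerate(a)
        ] + [AtomRecord(10 + i, "C", "X", "B", 20 + i, "C", *xyz) for i, xyz in enumerate(b)]
        frame = Frame(1, atoms)
        ia, ib = np.arange(4), np.arange(4, 10)
        m = min_heavy_distance(frame, ia, ib)
        assert m == pytest.approx(min_heavy_distance(frame, ib, ia), abs=1e-15)
        pair = np.sqrt(((a[0] - b[0]) ** 2).sum()) * 0.1
        assert m <= pair + 1e-15


class TestContactFraction:
    def _trajectory_with_contacts(self, n_contact, n_total):
        # frame i has the glycan atom 0.3 nm from residue 712 when i < n_contact,
        # else 2.0 nm away
        frames = []
        for i in range(n_total):
            offset = 3.0 if i < n_contact else 20.0
            atoms = [
                AtomRecord(1, "CA", "ALA", "B", 712, "C", 0, 0, 0),
                AtomRecord(2, "CA", "ALA", "B", 713, "C", 8, 0, 0),
                AtomRecord(3, "C1", "MAN", "G", 1, "C", offset, 0, 0),
            ]
            frames.append(Frame(i + 1, atoms))
        return Trajectory(frames=frames)

    def test_counting_fixture_fifteen_of_hundred(self):
        traj = self._trajectory_with_contacts(15, 100)
        frac, profile = contact_fraction(traj, np.array([2]), np.array([0, 1]))
        assert frac == pytest.approx(0.15)
        assert profile.fractions[712] == pytest.approx(0.15)
        assert profile.sorted_items()[0][0] == 712

    def test_every_frame_in_contact(self):
        traj = self._trajectory_with_contacts(10, 10)
        frac, _ = contact_fraction(traj, np.array([2]), np.array([0, 1]))
        assert frac == 1.0

    def test_cutoff_below_global_minimum_gives_zero(self):
        traj = self._trajectory_with_contacts(10, 10)
        frac, _ = contact_fraction(traj, np.array([2]), np.array([0, 1]), cutoff=0.2)
        assert frac == 0.0

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contact_fraction(Trajectory(frames=[]), np.array([0]), np.array([1]))


class TestJointHistogram:
    def test_identical_frames_fill_single_cell(self):
        d = np.full(50, 3.75)
        g = np.full(50, 0.25)
        jh = joint_histogram(d, g, np.arange(3.0, 5.01, 0.1), np.arange(0, 1.01, 0.1))
        assert jh.counts.max() == 50
        assert (jh.counts > 0).sum() == 1
        assert jh.overflow == 0

    def test_counts_match_brute_force_binning(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(3.0, 6.0, 400)
        g = rng.uniform(0.0, 3.0, 400)
        de = np.arange(3.0, 5.51, 0.25)
        ge = np.arange(0.0, 2.51, 0.25)
        jh = joint_histogram(d, g, de, ge)
        brute = np.zeros((len(de) - 1, len(ge) - 1), dtype=int)
        for x, y in zip(d, g):
            i = np.searchsorted(de, x, side="right") - 1
            j = np.searchsorted(ge, y, side="right") - 1
            if 0 <= i < brute.shape[0] and 0 <= j < brute.shape[1]:
                brute[i, j] += 1
        assert np.array_equal(jh.counts, brute)
        assert jh.counts.sum() + jh.overflow == 400

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_total_mass_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        d = rng.uniform(2, 7, n)
        g = rng.uniform(0, 4, n)
        jh = joint_histogram(d, g, np.arange(3.0, 6.01, 0.1), np.arange(0.0, 3.01, 0.1))
        assert jh.counts.sum() + jh.overflow == n

    def test_decreasing_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            joint_histogram(np.array([3.7]), np.array([0.3]), np.array([4, 3]), np.array([0, 1]))
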
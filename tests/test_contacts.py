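import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_frames
from stanalyzer.contacts import (
    ContactSeries,
    bond_statistics,
    contact_residence_time,
    radial_distribution,
    residue_contacts,
    run_lengths,
)
from stanalyzer.fixtures import FixtureSpec, build_system
from stanalyzer.topology import AtomTable
from stanalyzer.trajectory import Frame


def _atoms(names, resnames, resids):
    return AtomTable.from_arrays(names, resnames, resids)


class TestBondStatistics:
    def test_constant_distance(self):
        atoms = _atoms(["C1", "C2"], ["MOL", "MOL"], [1, 2])
        coords = np.array([[0.0, 0, 0], [3.0, 4.0, 0]]) + 20
        frames = make_frames([coords] * 5, box=(100, 100, 100))
        table, mean, sd = bond_statistics(frames, ["resid 1", "resid 2"], atoms)
        assert mean == pytest.approx(5.0)
        assert sd == 0.0

    def test_right_angle(self):
        atoms = _atoms(["C1", "C2", "C3"], ["MOL"] * 3, [1, 2, 3])
        coords = np.array([[1.0, 0, 0], [0, 0, 0], [0, 1.0, 0]]) + 20
        frames = make_frames([coords], box=(100, 100, 100))
        _, mean, _ = bond_statistics(frames, ["resid 1", "resid 2", "resid 3"], atoms)
        assert mean == pytest.approx(90.0)

    def test_minimum_image_distance(self):
        atoms = _atoms(["C1", "C2"], ["MOL", "MOL"], [1, 2])
        coords = np.array([[1.0, 5.0, 5.0], [9.0, 5.0, 5.0]])
        frames = make_frames([coords], box=(10, 10, 10))
        _, mean, _ = bond_statistics(frames, ["resid 1", "resid 2"], atoms)
        assert mean == pytest.approx(2.0)

    def test_dihedral(self):
        atoms = _atoms(["C1", "C2", "C3", "C4"], ["MOL"] * 4, [1, 2, 3, 4])
        coords = np.array([[0, 1.0, 0], [0, 0, 0], [1.0, 0, 0], [1.0, -1.0, 0]]) + 20
        frames = make_frames([coords], box=(100, 100, 100))
        _, mean, _ = bond_statistics(
            frames, ["resid 1", "resid 2", "resid 3", "resid 4"], atoms
        )
        assert mean == pytest.approx(180.0)

    def test_bad_arity(self):
        atoms = _atoms(["C1"], ["MOL"], [1])
        with pytest.raises(ValueError):
            bond_statistics([], ["resid 1"], atoms)

    def test_empty_group_errors(self):
        atoms = _atoms(["C1", "C2"], ["MOL", "MOL"], [1, 2])
        with pytest.raises(ValueError):
            bond_statistics([], ["resid 1", "name XX"], atoms)


class TestResidueContacts:
    def _two_residue_frames(self, separations):
        atoms = _atoms(["CA", "CA"], ["ALA", "GLY"], [1, 2])
        coords_list = [
            np.array([[10.0, 10, 10], [10.0 + d, 10, 10]]) for d in separations
        ]
        return atoms, make_frames(coords_list, box=(50, 50, 50))

    def test_always_in_contact(self):
        atoms, frames = self._two_residue_frames([3.0] * 4)
        table, _ = residue_contacts(frames, "resid 1", "resid 2", atoms, cutoff=4.5)
        assert table.rows[0][2] == pytest.approx(1.0)

    def test_far_apart_absent(self):
        atoms, frames = self._two_residue_frames([20.0] * 4)
        table, _ = residue_contacts(frames, "resid 1", "resid 2", atoms, cutoff=4.5)
        assert table.rows == []

    def test_half_frequency(self):
        atoms, frames = self._two_residue_frames([3.0, 20.0] * 5)
        table, series = residue_contacts(frames, "resid 1", "resid 2", atoms, cutoff=4.5)
        assert table.rows[0][2] == pytest.approx(0.5)
        assert table.rows[0][3] == "0,2,4,6,8"

    def test_hydrogens_ignored(self):
        atoms = _atoms(["CA", "HA", "CA"], ["ALA", "ALA", "GLY"], [1, 1, 2])
        coords = np.array([[0.0, 0, 0], [8.0, 0, 0], [9.0, 0, 0]]) + 10
        frames = make_frames([coords], box=(50, 50, 50))
        table, _ = residue_contacts(frames, "resid 1", "resid 2", atoms, cutoff=4.5)
        assert table.rows == []  # CA...CA = 9 Å; H would be 1 Å but is skipped

    def test_overlap_warns_and_excludes_self(self):
        atoms, frames = self._two_residue_frames([3.0])
        with pytest.warns(UserWarning, match="overlap"):
            table, _ = residue_contacts(frames, "protein", "protein", atoms, cutoff=4.5)
        for row in table.rows:
            assert row[0] != row[1]

    def test_frequency_sorted(self):
        atoms = _atoms(["CA", "CA", "CA"], ["ALA", "GLY", "SER"], [1, 2, 3])
        coords_near = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 3.0, 0]]) + 20
        coords_far = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 20.0, 0]]) + 20
        frames = make_frames([coords_near, coords_far, coords_far, coords_near, coords_far],
                             box=(60, 60, 60))
        table, _ = residue_contacts(frames, "resid 1", "resid 2:3", atoms, cutoff=4.5)
        freqs = [row[2] for row in table.rows]
        assert freqs == sorted(freqs, reverse=True)


class TestResidenceTime:
    def test_hand_counted(self):
        series = ContactSeries(pair=("a", "b"), flags=np.array([1, 1, 1, 0, 1, 1], bool))
        stats = contact_residence_time(series)
        assert stats["n_events"] == 2
        assert stats["mean_frames"] == pytest.approx(2.5)
        assert stats["sd_frames"] == pytest.approx(0.5)

    def test_all_true(self):
        series = ContactSeries(pair=("a", "b"), flags=np.ones(10, bool))
        stats = contact_residence_time(series)
        assert stats == {
            "n_events": 1, "mean_frames": 10.0, "sd_frames": 0.0, "total_frames": 10
        }

    def test_all_false_returns_none(self):
        series = ContactSeries(pair=("a", "b"), flags=np.zeros(5, bool))
        assert contact_residence_time(series) is None

    def test_gap_tolerance(self):
        flags = np.array([1, 1, 0, 1, 1, 0, 0, 0, 1], bool)
        merged = contact_residence_time(ContactSeries(pair=("a", "b"), flags=flags),
                                        gap_tolerance=1)
        assert merged["n_events"] == 2  # gap of 1 merged, gap of 3 not
        assert merged["mean_frames"] == pytest.approx((5 + 1) / 2)

    def test_duration_sum_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            flags = rng.random(rng.integers(1, 60)) < 0.4
            stats = contact_residence_time(ContactSeries(pair=("a", "b"), flags=flags))
            if stats is None:
                assert flags.sum() == 0
            else:
                assert stats["total_frames"] == int(flags.sum())

    @staticmethod
    def _oracle_runs(flags):
        # independent run-length scanner
        runs, current = [], 0
        for f in flags:
            if f:
                current += 1
            elif current:
                runs.append(current)
                current = 0
        if current:
            runs.append(current)
        return runs

    def test_matches_oracle_on_1000_random_series(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(1, 50))
            flags = rng.random(n) < rng.uniform(0.1, 0.9)
            oracle = self._oracle_runs(flags)
            stats = contact_residence_time(ContactSeries(pair=("a", "b"), flags=flags))
            assert run_lengths(flags) == oracle
            if not oracle:
                assert stats is None
            else:
                arr = np.array(oracle, float)
                assert stats["n_events"] == len(oracle)
                assert stats["mean_frames"] == pytest.approx(arr.mean())
                assert stats["sd_frames"] == pytest.approx(arr.std())

    @given(st.lists(st.booleans(), min_size=1, max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_run_lengths_property(self, flags):
        assert run_lengths(flags) == self._oracle_runs(flags)


class TestRdf:
    def test_two_atoms_single_bin(self):
        atoms = _atoms(["AR", "AR"], ["GAS", "GAS"], [1, 2])
        coords = np.array([[10.0, 10, 10], [15.0, 10, 10]])
        frames = make_frames([coords], box=(30, 30, 30))
        table = radial_distribution(frames, "resid 1", "resid 2", atoms,
                                    bin_width=0.5, r_max=10.0)
        g = np.array(table.column("g"))
        r = np.array(table.column("r"))
        nonzero = np.nonzero(g)[0]
        assert len(nonzero) == 1
        assert abs(r[nonzero[0]] - 5.0) <= 0.25

    def test_ideal_gas_plateau(self):
        spec = FixtureSpec(
            kind="ideal_gas", seed=6, n_frames=100, box=(25.0, 25.0, 25.0),
            params={"n": 1000},
        )
        atoms, frames, _, _ = build_system(spec)
        table = radial_distribution(frames, "resname GAS", "resname GAS", atoms,
                                    bin_width=0.25, r_max=10.0)
        g = np.array(table.column("g"))
        r = np.array(table.column("r"))
        plateau = g[r >= 2.0]
        assert 0.95 <= plateau.mean() <= 1.05

    def test_counting_identity(self):
        spec = FixtureSpec(
            kind="ideal_gas", seed=7, n_frames=20, box=(25.0, 25.0, 25.0),
            params={"n": 300},
        )
        atoms, frames, _, _ = build_system(spec)
        bin_width, r_max = 0.25, 10.0
        table = radial_distribution(frames, "resname GAS", "resname GAS", atoms,
                                    bin_width=bin_width, r_max=r_max)
        g = np.array(table.column("g"))
        r = np.array(table.column("r"))
        rho = 300 / 25.0**3
        integral = rho * np.sum(g * 4 * np.pi * r**2 * bin_width)
        # direct mean neighbor count within r_max
        from stanalyzer.contacts import _min_image_dists

        counts = []
        for frame in frames:
            d = _min_image_dists(frame.coords, frame.coords, frame.box)
            np.fill_diagonal(d, np.inf)
            counts.append((d < r_max).sum(axis=1).mean())
        assert integral == pytest.approx(np.mean(counts), rel=0.01)

    def test_r_max_validity(self):
        atoms = _atoms(["AR"], ["GAS"], [1])
        frames = make_frames([np.ones((1, 3))], box=(10, 10, 10))
        with pytest.raises(ValueError, match="r_max"):
            radial_distribution(frames, "name AR", "name AR", atoms,
                                bin_width=0.5, r_max=8.0)

    def test_g_nonnegative(self):
        spec = FixtureSpec(kind="ideal_gas", seed=8, n_frames=5, params={"n": 50},
                           box=(20.0, 20.0, 20.0))
        atoms, frames, _, _ = build_system(spec)
        table = radial_distribution(frames, "resname GAS", "resname GAS", atoms,
                                    bin_width=0.5, r_max=9.0)
        assert all(v >= 0 for v in table.column("g"))
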
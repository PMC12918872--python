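import numpy as np
import pytest

from conftest import make_frames, random_rotation
from stanalyzer.protein import (
    covariance_analysis,
    pore_radius_profile,
    rmsd_series,
    rmsf_per_residue,
)
from stanalyzer.fixtures import FixtureSpec, build_system
from stanalyzer.topology import AtomTable
from stanalyzer.trajectory import Frame


@pytest.fixture
def small_protein():
    """10 CA atoms, one per residue."""
    n = 10
    atoms = AtomTable.from_arrays(["CA"] * n, ["ALA"] * n, list(range(1, n + 1)))
    rng = np.random.default_rng(0)
    base = rng.uniform(10, 30, (n, 3))
    return atoms, base


class TestRmsd:
    def test_reference_is_zero(self, small_protein):
        atoms, base = small_protein
        frames = make_frames([base], box=(50, 50, 50))
        table = rmsd_series(frames, "name CA", frames[0], atoms, fit=True)
        assert table.column("rmsd")[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_fit_vs_nofit(self, small_protein):
        atoms, base = small_protein
        rng = np.random.default_rng(1)
        rot = random_rotation(rng)
        moved = (base - base.mean(0)) @ rot.T + base.mean(0) + np.array([2.0, 1.0, -3.0])
        ref = Frame(index=0, coords=base, box=np.array([50.0, 50.0, 50.0]))
        frames = make_frames([moved], box=(50, 50, 50))
        fit = rmsd_series(frames, "name CA", ref, atoms, fit=True).column("rmsd")[0]
        nofit = rmsd_series(frames, "name CA", ref, atoms, fit=False).column("rmsd")[0]
        assert fit == pytest.approx(0.0, abs=1e-9)
        assert nofit > 0.5

    def test_uniform_displacement_nofit(self, small_protein):
        atoms, base = small_protein
        ref = Frame(index=0, coords=base, box=np.array([50.0, 50.0, 50.0]))
        frames = make_frames([base + np.array([3.0, 4.0, 0.0])], box=(50, 50, 50))
        value = rmsd_series(frames, "name CA", ref, atoms, fit=False).column("rmsd")[0]
        assert value == pytest.approx(5.0, abs=1e-12)

    def test_fit_never_exceeds_nofit(self, small_protein):
        atoms, base = small_protein
        rng = np.random.default_rng(2)
        ref = Frame(index=0, coords=base, box=np.array([50.0, 50.0, 50.0]))
        coords_list = [base + rng.normal(0, 0.8, base.shape) for _ in range(10)]
        fit = rmsd_series(make_frames(coords_list), "name CA", ref, atoms, fit=True)
        nofit = rmsd_series(make_frames(coords_list), "name CA", ref, atoms, fit=False)
        for a, b in zip(fit.column("rmsd"), nofit.column("rmsd")):
            assert a <= b + 1e-12


class TestRmsf:
    def test_static_zero(self, small_protein):
        atoms, base = small_protein
        table = rmsf_per_residue(make_frames([base] * 5), "name CA", atoms)
        assert np.allclose(table.column("rmsf"), 0.0, atol=1e-12)

    def test_alternating_atom(self):
        # residue 1 alternates between x=0 and x=2 -> RMSF 1 Å; a large static
        # anchor cloud pins the superposition so no global motion is induced
        n = 200
        atoms = AtomTable.from_arrays(["CA"] * n, ["ALA"] * n, list(range(1, n + 1)))
        rng = np.random.default_rng(7)
        base = rng.uniform(-100, 100, (n, 3))
        frames = []
        for t in range(10):
            coords = base.copy()
            coords[0] = [2.0 if t % 2 else 0.0, 0.0, 0.0]
            frames.append(coords)
        table = rmsf_per_residue(make_frames(frames, box=(500, 500, 500)), "name CA", atoms)
        assert table.column("rmsf")[0] == pytest.approx(1.0, abs=0.02)
        assert max(table.column("rmsf")[1:]) < 0.02

    def test_rigid_motion_removed(self, small_protein):
        atoms, base = small_protein
        rng = np.random.default_rng(3)
        coords_list = []
        for _ in range(8):
            rot = random_rotation(rng)
            coords_list.append((base - base.mean(0)) @ rot.T + rng.uniform(-5, 5, 3) + 50)
        table = rmsf_per_residue(make_frames(coords_list, box=(200, 200, 200)), "name CA", atoms)
        assert max(table.column("rmsf")) < 1e-6

    def test_needs_two_frames(self, small_protein):
        atoms, base = small_protein
        with pytest.raises(ValueError):
            rmsf_per_residue(make_frames([base]), "name CA", atoms)


class TestPoreRadius:
    def test_single_ring(self):
        spec = FixtureSpec(
            kind="pore", box=(30.0, 30.0, 20.0), params={"rings": [(0.0, 5.0)]}
        )
        atoms, frames, truth, _ = build_system(spec)
        table = pore_radius_profile(frames, "resname POR", atoms, bin_width=2.0)
        radii = [r for _, r in zip(table.column("z_center"), table.column("pore_radius"))
                 if not np.isnan(r)]
        assert radii[0] == pytest.approx(5.0 - 1.7, abs=1e-9)

    def test_two_rings_independent_bins(self):
        spec = FixtureSpec(
            kind="pore", box=(30.0, 30.0, 20.0),
            params={"rings": [(-5.0, 5.0), (5.0, 4.0)]},
        )
        atoms, frames, _, _ = build_system(spec)
        table = pore_radius_profile(frames, "resname POR", atoms, bin_width=2.0)
        by_z = {z: r for z, r in zip(table.column("z_center"), table.column("pore_radius"))}
        assert by_z[-5.0] == pytest.approx(3.3, abs=1e-9)
        assert by_z[5.0] == pytest.approx(2.3, abs=1e-9)

    def test_on_axis_clamped_to_zero(self):
        atoms = AtomTable.from_arrays(["C"] * 2, ["POR"] * 2, [1, 2])
        coords = np.array([[15.0, 15.0, 0.0], [15.0, 15.0, 1.0]])
        frames = make_frames([coords], box=(30, 30, 20))
        table = pore_radius_profile(frames, "resname POR", atoms, bin_width=20.0)
        assert table.column("pore_radius")[0] == 0.0

    def test_empty_bins_nan(self):
        spec = FixtureSpec(kind="pore", box=(30.0, 30.0, 20.0), params={"rings": [(0.0, 5.0)]})
        atoms, frames, _, _ = build_system(spec)
        table = pore_radius_profile(frames, "resname POR", atoms, bin_width=2.0)
        assert any(np.isnan(v) for v in table.column("pore_radius"))


class TestCovariance:
    def test_static_zero_matrix(self, small_protein):
        atoms, base = small_protein
        result = covariance_analysis(make_frames([base] * 4), "name CA", atoms, fit=False)
        assert np.allclose(result.matrix, 0.0)

    def test_correlated_and_anticorrelated(self):
        atoms = AtomTable.from_arrays(["CA", "CA"], ["ALA", "ALA"], [1, 2])
        frames = []
        for t in range(20):
            dx = 1.0 if t % 2 else -1.0
            frames.append(np.array([[dx, 0, 0], [10 + dx, 0, 0]]))
        res = covariance_analysis(make_frames(frames), "name CA", atoms, fit=False)
        c = res.matrix
        corr = c[0, 3] / np.sqrt(c[0, 0] * c[3, 3])
        assert corr == pytest.approx(1.0)
        frames_anti = []
        for t in range(20):
            dx = 1.0 if t % 2 else -1.0
            frames_anti.append(np.array([[dx, 0, 0], [10 - dx, 0, 0]]))
        res2 = covariance_analysis(make_frames(frames_anti), "name CA", atoms, fit=False)
        c2 = res2.matrix
        assert c2[0, 3] / np.sqrt(c2[0, 0] * c2[3, 3]) == pytest.approx(-1.0)

    def test_symmetric_psd_and_trace(self, small_protein):
        atoms, base = small_protein
        rng = np.random.default_rng(4)
        coords_list = [base + rng.normal(0, 0.5, base.shape) for _ in range(30)]
        frames = make_frames(coords_list)
        res = covariance_analysis(frames, "name CA", atoms, fit=True)
        assert np.allclose(res.matrix, res.matrix.T, atol=1e-12)
        assert res.eigenvalues.min() >= -1e-8
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        # trace = Σ per-atom MSF, computed independently from aligned coords
        from stanalyzer.protein import _aligned_coords, _sel_idx

        idx = _sel_idx("name CA", atoms)
        aligned = _aligned_coords(make_frames(coords_list), idx, atoms.masses[idx])
        msf = ((aligned - aligned.mean(axis=0)) ** 2).sum(axis=2).mean(axis=0)
        assert res.trace == pytest.approx(msf.sum(), rel=1e-9)

    def test_needs_two_frames(self, small_protein):
        atoms, base = small_protein
        with pytest.raises(ValueError):
            covariance_analysis(make_frames([base]), "name CA", atoms)
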
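import numpy as np
import pytest

from conftest import make_frames
from stanalyzer.fixtures import FixtureSpec, build_system
from stanalyzer.membrane import (
    area_compressibility,
    area_per_lipid,
    assign_leaflets,
    lateral_msd,
    membrane_thickness,
    msd_diffusion_fit,
    position_timeseries,
    scd_profile,
    shell_composition,
    sterol_tilt,
    z_density_profile,
)
from stanalyzer.topology import AtomTable
from stanalyzer.trajectory import Frame

KB = 1.380649e-23


def _p_sheet_system(n_per_leaflet=8, z=19.0):
    """One P atom per 'lipid', n in each leaflet."""
    n = 2 * n_per_leaflet
    atoms = AtomTable.from_arrays(
        ["P"] * n, ["LIP"] * n, list(range(1, n + 1))
    )
    coords = np.zeros((n, 3))
    coords[:, 0] = np.tile(np.arange(n_per_leaflet) * 4.0 + 2, 2)
    coords[:n_per_leaflet, 2] = z
    coords[n_per_leaflet:, 2] = -z
    return atoms, coords


class TestAssignLeaflets:
    def test_split(self):
        atoms, coords = _p_sheet_system()
        frame = Frame(index=0, coords=coords, box=np.array([40.0, 40.0, 80.0]))
        assign = assign_leaflets(frame, "name P", atoms)
        assert list(assign.labels) == ["upper"] * 8 + ["lower"] * 8

    def test_tie_goes_upper(self):
        atoms = AtomTable.from_arrays(["P", "P"], ["LIP", "LIP"], [1, 2])
        coords = np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 5.0]])
        frame = Frame(index=0, coords=coords, box=np.array([20.0, 20.0, 40.0]))
        assign = assign_leaflets(frame, "name P", atoms)
        assert list(assign.labels) == ["upper", "upper"]

    def test_matches_fixture_ground_truth(self):
        spec = FixtureSpec(
            kind="bilayer", seed=5, params={"nx": 3, "ny": 3, "z_jitter": 2.0, "xy_jitter": 1.0}
        )
        atoms, frames, _, extras = build_system(spec)
        assign = assign_leaflets(frames[0], "name P", atoms)
        assert list(assign.labels) == extras["leaflet_labels"]

    def test_empty_selection_errors(self):
        atoms, coords = _p_sheet_system()
        frame = Frame(index=0, coords=coords, box=np.array([40.0, 40.0, 80.0]))
        with pytest.raises(ValueError):
            assign_leaflets(frame, "name XX", atoms)


class TestAreaPerLipid:
    def test_lattice_apl(self, bilayer_system):
        atoms, frames, truth, _ = bilayer_system
        table = area_per_lipid(frames, "name P", atoms)
        for col in ("apl_LIPA", "apl_LIPB"):
            assert np.allclose(table.column(col), truth["apl"][0])

    def test_leaflet_area_conservation_random(self):
        spec = FixtureSpec(
            kind="bilayer", seed=9, n_frames=2,
            params={"nx": 5, "ny": 5, "xy_jitter": 1.5},
        )
        atoms, frames, _, _ = build_system(spec)
        from stanalyzer.geometry import periodic_voronoi

        assign = assign_leaflets(frames[0], "name P", atoms)
        for leaflet in ("upper", "lower"):
            groups = assign.leaflet(leaflet)
            sites = np.array([frames[0].coords[g, :2].mean(axis=0) for g in groups])
            diagram = periodic_voronoi(sites, frames[0].box[:2])
            assert diagram.areas.sum() == pytest.approx(1600.0, rel=1e-6)

    def test_checkerboard_types_equal(self, bilayer_system):
        atoms, frames, _, _ = bilayer_system
        table = area_per_lipid(frames, "name P", atoms)
        assert table.column("apl_LIPA") == pytest.approx(table.column("apl_LIPB"))

    def test_xy_translation_invariance(self, bilayer_system):
        atoms, frames, _, _ = bilayer_system
        base = area_per_lipid([frames[0]], "name P", atoms)
        shifted = Frame(
            index=0, coords=frames[0].coords + np.array([3.0, -7.0, 0.0]),
            box=frames[0].box,
        )
        moved = area_per_lipid([shifted], "name P", atoms)
        assert moved.rows[0][1:] == pytest.approx(base.rows[0][1:], rel=1e-9)


class TestShellComposition:
    def test_two_lipid_shell(self):
        atoms, coords = _p_sheet_system(n_per_leaflet=2)
        frame = Frame(index=0, coords=coords, box=np.array([8.0, 8.0, 80.0]))
        table = shell_composition([frame], "LIP", "name P", atoms, n_shells=1)
        total = sum(r[2] for r in table.rows if r[0] == 1)
        assert total == pytest.approx(1.0)

    def test_hexagonal_shell1_is_six(self):
        import math

        a = 8.0
        nx = ny = 4
        pts = [
            (i * a + (j % 2) * a / 2, j * a * math.sqrt(3) / 2)
            for j in range(ny)
            for i in range(nx)
        ]
        n = len(pts)
        atoms = AtomTable.from_arrays(["P"] * 2 * n, ["LIP"] * 2 * n, list(range(1, 2 * n + 1)))
        coords = np.zeros((2 * n, 3))
        coords[:n, :2] = pts
        coords[:n, 2] = 19.0
        coords[n:, :2] = pts
        coords[n:, 2] = -19.0
        box = np.array([nx * a, ny * a * math.sqrt(3) / 2, 80.0])
        frame = Frame(index=0, coords=coords, box=box)
        table = shell_composition([frame], "LIP", "name P", atoms, n_shells=1)
        total = sum(r[2] for r in table.rows if r[0] == 1)
        assert total == pytest.approx(6.0)

    def test_checkerboard_shell1_of_A_is_4B(self, bilayer_system):
        atoms, frames, _, _ = bilayer_system  # square lattice: 4 edge neighbors
        table = shell_composition([frames[0]], "LIPA", "name P", atoms, n_shells=1)
        by_type = {r[1]: r[2] for r in table.rows if r[0] == 1}
        assert by_type["LIPB"] == pytest.approx(4.0)
        assert by_type.get("LIPA", 0.0) == pytest.approx(0.0)

    def test_no_center_type_errors(self, bilayer_system):
        atoms, frames, _, _ = bilayer_system
        with pytest.raises(ValueError):
            shell_composition([frames[0]], "NOPE", "name P", atoms)


class TestScd:
    def _chain_spec(self, n_carbons=3):
        return [(f"C{k+2}", [f"H{k+2}A", f"H{k+2}B"]) for k in range(n_carbons)]

    def test_all_z_is_one(self, bilayer_system):
        atoms, frames, _, _ = bilayer_system
        table = scd_profile(frames, self._chain_spec(), "resname LIPA or resname LIPB", atoms)
        assert np.allclose(table.column("scd"), 1.0, atol=1e-12)

    def test_all_xy_is_half(self):
        spec = FixtureSpec(
            kind="bilayer", seed=2, params={"nx": 3, "ny": 3, "ch_orientation": "xy"}
        )
        atoms, frames, _, _ = build_system(spec)
        table = scd_profile(
            frames, [("C2", ["H2A", "H2B"])], "resname LIPA", atoms
        )
        assert np.allclose(table.column("scd"), 0.5, atol=1e-12)

    def test_isotropic_near_zero(self):
        # 10^5 isotropic C–H samples -> |S| < 0.01 (⟨cos²θ⟩ = 1/3)
        rng = np.random.default_rng(42)
        n = 100_000
        names = []
        resids = []
        for i in range(n):
            names += ["C2", "H2A"]
            resids += [i + 1, i + 1]
        atoms = AtomTable.from_arrays(names, ["LIP"] * 2 * n, resids)
        vec = rng.normal(size=(n, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        coords = np.zeros((2 * n, 3))
        coords[1::2] = vec * 1.09
        frame = Frame(index=0, coords=coords + 50.0, box=np.array([120.0, 120.0, 120.0]))
        table = scd_profile([frame], [("C2", ["H2A"])], "resname LIP", atoms)
        assert abs(table.column("scd")[0]) < 0.01

    def test_missing_hydrogens_error(self, bilayer_system):
        atoms, frames, _, _ = bilayer_system
        with pytest.raises(ValueError, match="hydrogen"):
            scd_profile(frames, [("C2", ["HX"])], "resname LIPA", atoms)

    def test_magnitude_bounds(self):
        spec = FixtureSpec(
            kind="bilayer", seed=8, params={"nx": 4, "ny": 4, "ch_orientation": "iso"}
        )
        atoms, frames, _, _ = build_system(spec)
        table = scd_profile(frames, self._chain_spec(4), "resname LIPA", atoms)
        assert all(0.0 <= v <= 1.0 for v in table.column("scd"))


class TestThickness:
    def test_flat_sheets(self):
        atoms, coords = _p_sheet_system(z=19.0)
        frame = Frame(index=0, coords=coords, box=np.array([40.0, 40.0, 80.0]))
        table = membrane_thickness([frame], "name P", atoms)
        assert table.column("dpp")[0] == pytest.approx(38.0)

    def test_z_translation_invariance(self):
        atoms, coords = _p_sheet_system(z=19.0)
        box = np.array([40.0, 40.0, 80.0])
        base = membrane_thickness(
            [Frame(index=0, coords=coords, box=box)], "name P", atoms
        ).column("dpp")[0]
        shifted = membrane_thickness(
            [Frame(index=0, coords=coords + np.array([0, 0, 5.0]), box=box)],
            "name P",
            atoms,
        ).column("dpp")[0]
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_jitter_averages_out(self):
        rng = np.random.default_rng(10)
        n = 10_000
        atoms = AtomTable.from_arrays(["P"] * n, ["LIP"] * n, list(range(1, n + 1)))
        coords = np.zeros((n, 3))
        coords[: n // 2, 2] = 19.0 + rng.uniform(-1, 1, n // 2)
        coords[n // 2 :, 2] = -19.0 + rng.uniform(-1, 1, n // 2)
        frame = Frame(index=0, coords=coords, box=np.array([200.0, 200.0, 80.0]))
        table = membrane_thickness([frame], "name P", atoms)
        assert table.column("dpp")[0] == pytest.approx(38.0, abs=0.05)

    def test_single_leaflet_errors(self):
        atoms = AtomTable.from_arrays(["P", "P"], ["LIP"] * 2, [1, 2])
        coords = np.array([[0, 0, 19.0], [5, 5, 19.0]])
        frame = Frame(index=0, coords=coords, box=np.array([40.0, 40.0, 80.0]))
        # all heads tie at midplane -> all upper -> error
        with pytest.raises(ValueError):
            membrane_thickness([frame], "name P", atoms)


class TestSterolTilt:
    def _system(self, directions):
        n = len(directions)
        names, resids = [], []
        for i in range(n):
            names += ["C3", "C17"]
            resids += [i + 1, i + 1]
        atoms = AtomTable.from_arrays(names, ["STER"] * 2 * n, resids)
        coords = np.zeros((2 * n, 3))
        coords[1::2] = np.asarray(directions) * 8.0
        return atoms, Frame(
            index=0, coords=coords + 100.0, box=np.array([300.0, 300.0, 300.0])
        )

    def test_vertical_is_zero(self):
        atoms, frame = self._system([(0, 0, 1), (0, 0, -1)])
        series, _ = sterol_tilt([frame], "resname STER", atoms)
        assert series.column("theta_mean")[0] == pytest.approx(0.0, abs=1e-9)

    def test_in_plane_is_ninety(self):
        atoms, frame = self._system([(1, 0, 0), (0, 1, 0)])
        series, _ = sterol_tilt([frame], "resname STER", atoms)
        assert series.column("theta_mean")[0] == pytest.approx(90.0, abs=1e-9)

    def test_isotropic_mean(self):
        rng = np.random.default_rng(21)
        v = rng.normal(size=(100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        atoms, frame = self._system(v)
        series, hist = sterol_tilt([frame], "resname STER", atoms)
        assert series.column("theta_mean")[0] == pytest.approx(np.degrees(1.0), abs=0.2)
        assert sum(hist.column("count")) == 100_000


class TestAreaCompressibility:
    def test_direct_formula(self):
        # oracle: K_A = kB*303.15*4000/400 J/Å² × 1e23 = 4185.437 mN/m
        rng = np.random.default_rng(0)
        areas = np.array([4000.0 - 20.0, 4000.0 + 20.0])  # mean 4000, var 400
        ka = area_compressibility(areas, 303.15)
        assert ka == pytest.approx(KB * 303.15 * 4000 / 400 * 1e23, rel=1e-12)
        assert ka == pytest.approx(4185.44, abs=0.01)

    def test_doubling_var_halves(self):
        base = np.array([4000.0 - 20, 4000.0 + 20])
        double = np.array([4000.0 - 20 * np.sqrt(2), 4000.0 + 20 * np.sqrt(2)])
        assert area_compressibility(base, 300) == pytest.approx(
            2 * area_compressibility(double, 300), rel=1e-9
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        areas = 4000 + rng.normal(0, 15, 200)
        c = 2.5
        assert area_compressibility(c * areas, 300) == pytest.approx(
            area_compressibility(areas, 300) / c, rel=1e-9
        )

    def test_constant_series_errors(self):
        with pytest.raises(ValueError, match="constant"):
            area_compressibility([4000.0, 4000.0], 300)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            area_compressibility([4000.0], 300)


class TestZDensity:
    def test_ideal_gas_uniform(self):
        spec = FixtureSpec(
            kind="ideal_gas", seed=4, n_frames=20, box=(20.0, 20.0, 50.0),
            params={"n": 1000},
        )
        atoms, frames, _, _ = build_system(spec)
        table = z_density_profile(frames, {"gas": "resname GAS"}, atoms, bin_width=5.0)
        expected = 1000 / (20 * 20 * 50)
        dens = np.array(table.column("density_gas"))
        # 3σ Poisson band on per-bin counts (2000 Å³ bins, 20 frames)
        per_bin = 1000 / 10
        sigma = np.sqrt(per_bin / 20) / 2000
        assert np.all(np.abs(dens - expected) < 3.5 * sigma)

    def test_count_conservation(self):
        spec = FixtureSpec(
            kind="ideal_gas", seed=5, n_frames=3, box=(20.0, 20.0, 50.0), params={"n": 333}
        )
        atoms, frames, _, _ = build_system(spec)
        table = z_density_profile(frames, {"gas": "resname GAS"}, atoms, bin_width=1.0)
        bin_volume = 20 * 20 * 1.0
        assert sum(table.column("density_gas")) * bin_volume == pytest.approx(333, rel=1e-9)

    def test_single_atom_one_bin(self):
        atoms = AtomTable.from_arrays(["AR"], ["GAS"], [1])
        coords = np.array([[5.0, 5.0, 10.0]])
        frame = Frame(index=0, coords=coords, box=np.array([20.0, 20.0, 50.0]))
        table = z_density_profile([frame], {"g": "name AR"}, atoms, bin_width=1.0)
        dens = np.array(table.column("density_g"))
        centers = np.array(table.column("z_center"))
        nonzero = np.nonzero(dens)[0]
        assert len(nonzero) == 1
        assert abs(centers[nonzero[0]] - 10.0) <= 0.5

    def test_mass_mode(self):
        atoms = AtomTable.from_arrays(["AR"], ["GAS"], [1])
        frame = Frame(
            index=0, coords=np.array([[5.0, 5.0, 0.0]]), box=np.array([10.0, 10.0, 10.0])
        )
        table = z_density_profile([frame], {"g": "name AR"}, atoms, bin_width=10.0, mode="mass")
        assert table.column("density_g")[0] == pytest.approx(39.948 / 1000.0)

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            z_density_profile([], {}, AtomTable.from_arrays(["A"], ["B"], [1]), bin_width=0)


class TestLateralMsd:
    def _walk_atoms(self, n):
        return AtomTable.from_arrays(["AR"] * n, ["WLK"] * n, list(range(1, n + 1)))

    def test_static_zero(self):
        atoms = self._walk_atoms(5)
        coords = np.random.default_rng(0).uniform(0, 30, (5, 3))
        frames = make_frames([coords] * 6, box=(30, 30, 30))
        table = lateral_msd(frames, "resname WLK", atoms)
        assert np.allclose(table.column("msd"), 0.0)

    def test_ballistic_quadratic(self):
        atoms = self._walk_atoms(3)
        base = np.random.default_rng(1).uniform(5, 25, (3, 3))
        frames = make_frames(
            [base + np.array([1.0, 0, 0]) * t for t in range(8)], box=(1000, 1000, 1000)
        )
        table = lateral_msd(frames, "resname WLK", atoms)
        for tau, msd in zip(table.column("lag"), table.column("msd")):
            assert msd == pytest.approx(float(tau) ** 2, abs=1e-9)

    def test_msd0_zero_and_nonnegative(self):
        spec = FixtureSpec(kind="random_walk", seed=3, n_frames=50, params={"n": 20})
        atoms, frames, _, _ = build_system(spec)
        table = lateral_msd(frames, "resname WLK", atoms)
        msd = table.column("msd")
        assert msd[0] == 0.0
        assert all(v >= 0 for v in msd)

    def test_random_walk_diffusion_recovery(self):
        spec = FixtureSpec(
            kind="random_walk", seed=1, n_frames=500, box=(60.0, 60.0, 60.0),
            params={"n": 200, "sigma": 0.5},
        )
        atoms, frames, truth, _ = build_system(spec)
        table = lateral_msd(frames, "resname WLK", atoms)
        d_fit = msd_diffusion_fit(table.column("lag"), table.column("msd"), n_dim=2)
        expected = truth["diffusion"][0]  # σ²/(2Δt)
        assert abs(d_fit - expected) / expected < 0.10


class TestPositionTimeseries:
    def test_static_constant(self):
        atoms = AtomTable.from_arrays(["AR"], ["GAS"], [1])
        coords = np.array([[3.0, 4.0, 5.0]])
        frames = make_frames([coords] * 4, box=(10, 10, 10))
        table = position_timeseries(frames, {"g": "name AR"}, atoms)
        assert table.column("g_z") == [5.0] * 4

    def test_linear_motion(self):
        atoms = AtomTable.from_arrays(["AR"], ["GAS"], [1])
        frames = make_frames(
            [np.array([[0.0, 0.0, float(t)]]) for t in range(5)], box=(10, 10, 10)
        )
        table = position_timeseries(frames, {"g": "name AR"}, atoms)
        assert table.column("g_z") == pytest.approx([0, 1, 2, 3, 4])

    def test_matches_com_oracle(self):
        from stanalyzer.geometry import center_of_mass

        atoms = AtomTable.from_arrays(["C1", "O1"], ["MOL", "MOL"], [1, 1])
        rng = np.random.default_rng(2)
        coords_list = [rng.uniform(0, 10, (2, 3)) for _ in range(3)]
        frames = make_frames(coords_list, box=(10, 10, 10))
        table = position_timeseries(frames, {"m": "resname MOL"}, atoms)
        for row, coords in zip(table.rows, coords_list):
            oracle = center_of_mass(coords, atoms.masses)
            assert row[1:] == pytest.approx(tuple(oracle))

    def test_empty_group_errors(self):
        atoms = AtomTable.from_arrays(["AR"], ["GAS"], [1])
        frames = make_frames([np.zeros((1, 3))], box=(10, 10, 10))
        with pytest.raises(ValueError):
            position_timeseries(frames, {"g": "name XX"}, atoms)
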
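"""Membrane observables.

Leaflet assignment, Voronoi area per lipid, shell composition, deuterium
order parameters, bilayer thickness, sterol tilt, area compressibility,
z-density profiles, lateral MSD and group-position time series.

Conventions: the bilayer normal is the global z axis (flat-bilayer
assumption); the membrane midplane is the per-frame mean z of the selected
head-group atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.constants as const

from .geometry import center_of_mass, minimum_image_displacement, periodic_voronoi
from .selection import selection_indices
from .tables import TimeSeriesTable
from .topology import ATOMIC_NUMBERS, AtomTable
from .trajectory import Frame

__all__ = [
    "assign_leaflets",
    "area_per_lipid",
    "shell_composition",
    "scd_profile",
    "membrane_thickness",
    "sterol_tilt",
    "area_compressibility",
    "z_density_profile",
    "lateral_msd",
    "position_timeseries",
    "msd_diffusion_fit",
]

#: Boltzmann constant in J/K (CODATA).
KB = const.k


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels for one frame."""

    lipid_residues: list[np.ndarray]   # atom-index groups, one per lipid
    labels: np.ndarray                 # 'upper' / 'lower' per lipid
    midplane: float                    # z of the dividing plane (Å)

    def leaflet(self, which: str) -> list[np.ndarray]:
        return [g for g, lab in zip(self.lipid_residues, self.labels) if lab == which]


def _wrap_z(z: np.ndarray, lz: float) -> np.ndarray:
    return z - np.floor(z / lz + 0.5) * lz


def assign_leaflets(frame: Frame, head_sel: str, atoms: AtomTable) -> LeafletAssignment:
    """Label each lipid upper/lower by its head-atom z versus the midplane.

    The midplane is the mean z of all selected head atoms (after wrapping);
    a head exactly on the midplane goes to the upper leaflet.
    """
    idx = selection_indices(head_sel, atoms)
    if len(idx) == 0:
        raise ValueError(f"empty head selection: {head_sel!r}")
    groups = atoms.residue_groups(idx)
    lz = frame.box[2]
    head_z = np.array(
        [_wrap_z(frame.coords[g, 2], lz).mean() for g in groups]
    )
    midplane = float(head_z.mean())
    labels = np.where(head_z >= midplane, "upper", "lower")
    return LeafletAssignment(lipid_residues=groups, labels=labels, midplane=midplane)


def _lipid_types(groups: list[np.ndarray], atoms: AtomTable) -> list[str]:
    return [str(atoms.resnames[g[0]]).strip() for g in groups]


def area_per_lipid(frames, lipid_site_sel: str, atoms: AtomTable) -> TimeSeriesTable:
    """Per-frame, per-lipid-type mean Voronoi cell area (Ų).

    One site per lipid: the centroid of the atoms ``lipid_site_sel`` selects
    within each lipid residue.  Both leaflets are tessellated independently
    and pooled into the per-type means.
    """
    table: TimeSeriesTable | None = None
    for frame in frames:
        assign = assign_leaflets(frame, lipid_site_sel, atoms)
        types = _lipid_types(assign.lipid_residues, atoms)
        type_names = sorted(set(types))
        if table is None:
            table = TimeSeriesTable(["frame"] + [f"apl_{t}" for t in type_names])
        per_type: dict[str, list[float]] = {t: [] for t in type_names}
        for leaflet in ("upper", "lower"):
            groups = assign.leaflet(leaflet)
            if not groups:
                warnings.warn(f"leaflet {leaflet} empty in frame {frame.index}; skipped")
                continue
            sites = np.array([frame.coords[g, :2].mean(axis=0) for g in groups])
            diagram = periodic_voronoi(sites, frame.box[:2])
            for g, area in zip(groups, diagram.areas):
                per_type[str(atoms.resnames[g[0]]).strip()].append(float(area))
        table.append(
            frame.index,
            *[float(np.mean(per_type[t])) if per_type[t] else float("nan") for t in type_names],
        )
    if table is None:
        raise ValueError("no frames")
    return table


def shell_composition(
    frames, center_type: str, site_sel: str, atoms: AtomTable, n_shells: int = 3
) -> TimeSeriesTable:
    """Mean lipid-type counts in successive Voronoi neighbor shells.

    Shell 1 holds the Voronoi neighbors of each center-type site; shell k
    holds neighbors of shell k−1 not already counted.  Counts are averaged
    over center lipids and frames (leaflets treated independently).
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    totals: dict[tuple[int, str], float] = {}
    n_centers = 0
    n_frames = 0
    all_types: set[str] = set()
    for frame in frames:
        n_frames += 1
        assign = assign_leaflets(frame, site_sel, atoms)
        for leaflet in ("upper", "lower"):
            groups = assign.leaflet(leaflet)
            if not groups:
                continue
            types = _lipid_types(groups, atoms)
            all_types.update(types)
            sites = np.array([frame.coords[g, :2].mean(axis=0) for g in groups])
            diagram = periodic_voronoi(sites, frame.box[:2])
            centers = [i for i, t in enumerate(types) if t == center_type]
            for c in centers:
                n_centers += 1
                visited = {c}
                shell = set(diagram.neighbors[c]) - visited
                for k in range(1, n_shells + 1):
                    if not shell:
                        break
                    for s in shell:
                        key = (k, types[s])
                        totals[key] = totals.get(key, 0.0) + 1.0
                    visited |= shell
                    nxt: set[int] = set()
                    for s in shell:
                        nxt |= diagram.neighbors[s]
                    shell = nxt - visited
    if n_centers == 0:
        raise ValueError(f"no lipids of center type {center_type!r}")
    table = TimeSeriesTable(["shell", "lipid_type", "mean_count"])
    for k in range(1, n_shells + 1):
        for t in sorted(all_types):
            count = totals.get((k, t), 0.0) / n_centers
            table.append(k, t, count)
    return table


def scd_profile(
    frames,
    chain_spec: list[tuple[str, list[str]]],
    lipid_sel: str,
    atoms: AtomTable,
    chain_label: str = "chain",
) -> TimeSeriesTable:
    """Deuterium order parameter |S_CD| per carbon along an acyl chain.

    chain_spec lists (carbon_name, [hydrogen names]) in chain order starting
    at carbon index 2.  S_CD = ⟨(3cos²θ − 1)/2⟩ with θ the C→H angle to +z,
    averaged over lipids, hydrogens and frames; the magnitude is reported.
    """
    idx = selection_indices(lipid_sel, atoms)
    if len(idx) == 0:
        raise ValueError(f"empty lipid selection: {lipid_sel!r}")
    groups = atoms.residue_groups(idx)
    pairs_per_carbon: list[list[tuple[int, int]]] = []
    for c_name, h_names in chain_spec:
        pairs: list[tuple[int, int]] = []
        for g in groups:
            names = np.char.strip(atoms.names[g])
            c_hits = g[names == c_name]
            if len(c_hits) == 0:
                continue
            c_atom = int(c_hits[0])
            h_atoms = [int(a) for h in h_names for a in g[names == h]]
            if not h_atoms:
                raise ValueError(
                    f"carbon {c_name} has no hydrogens {h_names}: "
                    "S_CD requires explicit hydrogen atoms"
                )
            pairs.extend((c_atom, h) for h in h_atoms)
        pairs_per_carbon.append(pairs)
    sums = np.zeros(len(chain_spec))
    counts = np.zeros(len(chain_spec), dtype=np.int64)
    for frame in frames:
        for ci, pairs in enumerate(pairs_per_carbon):
            if not pairs:
                continue
            arr = np.asarray(pairs)
            vec = frame.coords[arr[:, 1]] - frame.coords[arr[:, 0]]
            cos2 = (vec[:, 2] ** 2) / (vec**2).sum(axis=1)
            sums[ci] += (1.5 * cos2 - 0.5).sum()
            counts[ci] += len(pairs)
    table = TimeSeriesTable(["chain", "carbon_index", "scd"])
    for ci in range(len(chain_spec)):
        value = abs(sums[ci] / counts[ci]) if counts[ci] else float("nan")
        table.append(chain_label, ci + 2, float(value))
    return table


def membrane_thickness(frames, phosphate_sel: str, atoms: AtomTable) -> TimeSeriesTable:
    """D_PP per frame: mean upper-leaflet P z minus mean lower-leaflet P z."""
    table = TimeSeriesTable(["frame", "dpp"])
    for frame in frames:
        assign = assign_leaflets(frame, phosphate_sel, atoms)
        lz = frame.box[2]
        upper = assign.leaflet("upper")
        lower = assign.leaflet("lower")
        if not upper or not lower:
            raise ValueError(
                f"phosphate selection resolves to a single leaflet in frame {frame.index}"
            )
        z_up = np.concatenate([_wrap_z(frame.coords[g, 2], lz) for g in upper])
        z_lo = np.concatenate([_wrap_z(frame.coords[g, 2], lz) for g in lower])
        table.append(frame.index, float(z_up.mean() - z_lo.mean()))
    return table


def sterol_tilt(
    frames,
    sterol_sel: str,
    atoms: AtomTable,
    tail_name: str = "C3",
    head_name: str = "C17",
    n_bins: int = 90,
):
    """Sterol tilt angle Θ = arccos|u·ẑ| ∈ [0°, 90°] per sterol.

    Returns (per-frame-mean table, pooled histogram table).  Θ is folded to
    [0°, 90°] so head/tail orientation is irrelevant.
    """
    idx = selection_indices(sterol_sel, atoms)
    if len(idx) == 0:
        raise ValueError(f"empty sterol selection: {sterol_sel!r}")
    groups = atoms.residue_groups(idx)
    vectors: list[tuple[int, int]] = []
    for g in groups:
        names = np.char.strip(atoms.names[g])
        tails = g[names == tail_name]
        heads = g[names == head_name]
        if len(tails) == 0 or len(heads) == 0:
            raise ValueError(
                f"sterol residue missing {tail_name}/{head_name} atoms"
            )
        vectors.append((int(tails[0]), int(heads[0])))
    series = TimeSeriesTable(["frame", "theta_mean"])
    pooled: list[float] = []
    for frame in frames:
        thetas = []
        for tail, head in vectors:
            v = frame.coords[head] - frame.coords[tail]
            norm = np.linalg.norm(v)
            if norm == 0:
                warnings.warn("zero-length sterol vector; molecule skipped")
                continue
            thetas.append(float(np.degrees(np.arccos(min(abs(v[2]) / norm, 1.0)))))
        pooled.extend(thetas)
        series.append(frame.index, float(np.mean(thetas)) if thetas else float("nan"))
    hist, edges = np.histogram(pooled, bins=n_bins, range=(0.0, 90.0))
    hist_table = TimeSeriesTable(["theta_center", "count"])
    centers = 0.5 * (edges[:-1] + edges[1:])
    for c, h in zip(centers, hist):
        hist_table.append(float(c), int(h))
    return series, hist_table


def area_compressibility(area_series, temperature: float) -> float:
    """Area compressibility modulus K_A = k_B·T·⟨A⟩ / var(A), in mN/m.

    Areas are the lateral box areas Lx·Ly per frame in Ų; the variance is
    the population variance.  1 J/Ų = 1e23 mN/m.
    """
    areas = np.asarray(area_series, dtype=float)
    if areas.size < 2:
        raise ValueError("need at least 2 frames for K_A")
    var = float(np.var(areas))
    if var == 0:
        raise ValueError("constant area series: K_A undefined")
    mean = float(np.mean(areas))
    ka_j_per_a2 = KB * temperature * mean / var
    return ka_j_per_a2 * 1e23


def area_compressibility_blocks(
    area_series, temperature: float, n_blocks: int = 5
) -> tuple[float, float]:
    """K_A with a block-averaged standard-error estimate (mN/m)."""
    areas = np.asarray(area_series, dtype=float)
    ka = area_compressibility(areas, temperature)
    blocks = np.array_split(areas, n_blocks)
    vals = [
        area_compressibility(b, temperature)
        for b in blocks
        if len(b) >= 2 and np.var(b) > 0
    ]
    if len(vals) < 2:
        return ka, float("nan")
    return ka, float(np.std(vals, ddof=1) / np.sqrt(len(vals)))


def z_density_profile(
    frames,
    group_sels: dict[str, str],
    atoms: AtomTable,
    bin_width: float = 1.0,
    mode: str = "number",
    center_sel: str | None = None,
) -> TimeSeriesTable:
    """Frame-averaged density along z per selection group.

    Modes: ``number`` (atoms/Å³), ``mass`` (amu/Å³), ``electron``
    (electrons/Å³, electrons = atomic number − partial charge; falls back
    to number mode with a warning if elements are unknown).  When
    ``center_sel`` is given, z is re-centered on that group's mean z
    (the membrane midplane) each frame.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if mode not in ("number", "mass", "electron"):
        raise ValueError(f"unknown density mode {mode!r}")
    group_idx = {label: selection_indices(sel, atoms) for label, sel in group_sels.items()}
    weights: dict[str, np.ndarray] = {}
    for label, idx in group_idx.items():
        if mode == "number":
            weights[label] = np.ones(len(idx))
        elif mode == "mass":
            weights[label] = atoms.masses[idx]
        else:
            electrons = np.array(
                [ATOMIC_NUMBERS.get(el, -1) for el in atoms.elements[idx]], dtype=float
            )
            if np.any(electrons < 0):
                warnings.warn("electron mode needs known elements; using number mode")
                electrons = np.ones(len(idx))
            elif atoms.charges is not None:
                electrons = electrons - atoms.charges[idx]
            weights[label] = electrons
    center_idx = selection_indices(center_sel, atoms) if center_sel else None

    accum: dict[str, np.ndarray] = {}
    edges = None
    n_frames = 0
    for frame in frames:
        lz = frame.box[2]
        if edges is None:
            n_bins = max(int(round(lz / bin_width)), 1)
            edges = np.linspace(-lz / 2, lz / 2, n_bins + 1)
            accum = {label: np.zeros(n_bins) for label in group_idx}
        n_frames += 1
        area = frame.box[0] * frame.box[1]
        z_all = frame.coords[:, 2]
        offset = 0.0
        if center_idx is not None and len(center_idx):
            offset = _wrap_z(z_all[center_idx], lz).mean()
        for label, idx in group_idx.items():
            z = _wrap_z(z_all[idx] - offset, lz)
            hist, _ = np.histogram(z, bins=edges, weights=weights[label])
            accum[label] += hist / (area * (edges[1] - edges[0]))
    if edges is None:
        raise ValueError("no frames")
    table = TimeSeriesTable(["z_center"] + [f"density_{label}" for label in group_idx])
    centers = 0.5 * (edges[:-1] + edges[1:])
    for i, z in enumerate(centers):
        table.append(float(z), *[float(accum[label][i] / n_frames) for label in group_idx])
    return table


def _unwrap_com_track(frames, groups, atoms: AtomTable, dims: slice) -> np.ndarray:
    """(n_frames, n_groups, d) unwrapped COM track via minimum-image increments."""
    track = []
    prev = None
    unwrapped = None
    single = all(len(g) == 1 for g in groups)
    flat = np.concatenate(groups) if single else None
    for frame in frames:
        if single:
            com = frame.coords[flat][:, dims]
        else:
            com = np.array(
                [center_of_mass(frame.coords[g], atoms.masses[g]) for g in groups]
            )[:, dims]
        box = frame.box[dims]
        if unwrapped is None:
            unwrapped = com.copy()
        else:
            step = minimum_image_displacement(prev, com, box)
            if np.any(np.abs(step) > box / 2 + 1e-9):
                warnings.warn("unwrap heuristic violated: jump larger than box/2")
            unwrapped = unwrapped + step
        prev = com
        track.append(unwrapped.copy())
    if not track:
        raise ValueError("no frames")
    return np.array(track)


def msd_curve(track: np.ndarray) -> np.ndarray:
    """All-origin MSD(τ) for τ = 0..n−1 from an (n, m, d) position track."""
    n = track.shape[0]
    msd = np.zeros(n)
    for tau in range(1, n):
        diff = track[tau:] - track[:-tau]
        msd[tau] = float((diff**2).sum(axis=2).mean())
    return msd


def lateral_msd(frames, lipid_sel: str, atoms: AtomTable) -> TimeSeriesTable:
    """Lateral (xy) MSD(τ) of per-lipid COMs, averaged over origins and lipids."""
    idx = selection_indices(lipid_sel, atoms)
    if len(idx) == 0:
        raise ValueError(f"empty selection: {lipid_sel!r}")
    groups = atoms.residue_groups(idx)
    track = _unwrap_com_track(frames, groups, atoms, slice(0, 2))
    if track.shape[0] < 2:
        raise ValueError("need at least 2 frames for MSD")
    msd = msd_curve(track)
    table = TimeSeriesTable(["lag", "msd"])
    for tau, value in enumerate(msd):
        table.append(tau, float(value))
    return table


def msd_diffusion_fit(
    lags, msd, n_dim: int, dt: float = 1.0, fit_window: tuple[float, float] = (0.2, 0.8)
) -> float:
    """Diffusion coefficient from the MSD slope: D = slope / (2·n_dim).

    The least-squares line is fit over the middle ``fit_window`` fraction of
    available lags; dt converts lag units to time (ps).
    """
    lags = np.asarray(lags, dtype=float)
    msd = np.asarray(msd, dtype=float)
    max_lag = lags.max()
    lo, hi = fit_window
    mask = (lags >= lo * max_lag) & (lags <= hi * max_lag)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 lag points in fit window")
    slope = np.polyfit(lags[mask] * dt, msd[mask], 1)[0]
    return float(slope / (2 * n_dim))


def position_timeseries(frames, group_sels: dict[str, str], atoms: AtomTable) -> TimeSeriesTable:
    """Mass-weighted COM (x, y, z) of each selection group per frame."""
    group_idx = {}
    for label, sel in group_sels.items():
        idx = selection_indices(sel, atoms)
        if len(idx) == 0:
            raise ValueError(f"empty group {label!r}: {sel!r}")
        group_idx[label] = idx
    cols = ["frame"]
    for label in group_idx:
        cols += [f"{label}_x", f"{label}_y", f"{label}_z"]
    table = TimeSeriesTable(cols)
    for frame in frames:
        row: list = [frame.index]
        for idx in group_idx.values():
            com = center_of_mass(frame.coords[idx], atoms.masses[idx])
            row += [float(com[0]), float(com[1]), float(com[2])]
        table.append(*row)
    return table
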
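"""Protein observables: RMSD, RMSF, pore radius, covariance analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose
from .selection import selection_indices
from .tables import TimeSeriesTable
from .topology import AtomTable
from .trajectory import Frame

__all__ = [
    "rmsd_series",
    "rmsf_per_residue",
    "pore_radius_profile",
    "covariance_analysis",
    "CovarianceResult",
]


def _sel_idx(sel: str, atoms: AtomTable) -> np.ndarray:
    idx = selection_indices(sel, atoms)
    if len(idx) == 0:
        raise ValueError(f"empty selection: {sel!r}")
    return idx


def rmsd_series(
    frames, sel: str, reference: Frame, atoms: AtomTable, fit: bool = True
) -> TimeSeriesTable:
    """Mass-weighted RMSD of a selection versus a reference frame.

    With ``fit`` the selection is optimally superposed (Kabsch) before the
    residual is taken; otherwise raw coordinates are compared.
    """
    idx = _sel_idx(sel, atoms)
    if reference.n_atoms != atoms.n_atoms:
        raise ValueError("reference frame atom count does not match topology")
    ref = reference.coords[idx]
    masses = atoms.masses[idx]
    table = TimeSeriesTable(["frame", "rmsd"])
    for frame in frames:
        mob = frame.coords[idx]
        if fit:
            value = kabsch_superpose(mob, ref, masses).rmsd
        else:
            resid = mob - ref
            value = float(
                np.sqrt((masses * (resid**2).sum(axis=1)).sum() / masses.sum())
            )
        table.append(frame.index, float(value))
    return table


def _aligned_coords(frames, idx, masses) -> np.ndarray:
    """Two-pass alignment: to frame 0, then to the resulting mean structure."""
    coords = np.array([f.coords[idx] for f in frames])
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    ref0 = coords[0]
    pass1 = np.array(
        [kabsch_superpose(c, ref0, masses).apply(c) for c in coords]
    )
    mean1 = pass1.mean(axis=0)
    return np.array([kabsch_superpose(c, mean1, masses).apply(c) for c in coords])


def rmsf_per_residue(frames, sel: str, atoms: AtomTable) -> TimeSeriesTable:
    """Per-residue RMSF (Å) about the mean structure after superposition.

    Per-atom RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩); the residue value is the
    mass-weighted mean of its selected atoms.
    """
    idx = _sel_idx(sel, atoms)
    masses = atoms.masses[idx]
    aligned = _aligned_coords(list(frames), idx, masses)
    mean = aligned.mean(axis=0)
    atom_rmsf = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    table = TimeSeriesTable(["resid", "rmsf"])
    pos_of = {int(a): i for i, a in enumerate(idx)}
    for group in atoms.residue_groups(idx):
        local = np.array([pos_of[int(a)] for a in group])
        w = masses[local]
        table.append(int(atoms.resids[group[0]]), float((w * atom_rmsf[local]).sum() / w.sum()))
    return table


def pore_radius_profile(
    frames,
    sel: str,
    atoms: AtomTable,
    bin_width: float = 1.0,
    axis_xy: tuple[float, float] | None = None,
) -> TimeSeriesTable:
    """Frame-averaged pore radius per z bin.

    Radius in a bin = min over its atoms of (xy distance to the pore axis −
    vdW radius of the element), clamped at 0.  The axis defaults to the
    selection's mean (x̄, ȳ) each frame.  Empty bins report NaN.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    idx = _sel_idx(sel, atoms)
    radii = atoms.vdw_radii()[idx]
    sums = None
    counts = None
    edges = None
    for frame in frames:
        lz = frame.box[2]
        if edges is None:
            n_bins = max(int(round(lz / bin_width)), 1)
            edges = np.linspace(-lz / 2, lz / 2, n_bins + 1)
            sums = np.zeros(n_bins)
            counts = np.zeros(n_bins, dtype=np.int64)
        pos = frame.coords[idx]
        ax = np.array(axis_xy) if axis_xy is not None else pos[:, :2].mean(axis=0)
        rad_xy = np.linalg.norm(pos[:, :2] - ax, axis=1) - radii
        z = pos[:, 2] - np.floor(pos[:, 2] / lz + 0.5) * lz
        which = np.clip(np.digitize(z, edges) - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            in_bin = which == b
            if in_bin.any():
                sums[b] += max(float(rad_xy[in_bin].min()), 0.0)
                counts[b] += 1
    if edges is None:
        raise ValueError("no frames")
    table = TimeSeriesTable(["z_center", "pore_radius"])
    centers = 0.5 * (edges[:-1] + edges[1:])
    for z, s, c in zip(centers, sums, counts):
        table.append(float(z), float(s / c) if c else float("nan"))
    return table


@dataclass
class CovarianceResult:
    atom_indices: np.ndarray     # selection, length N
    matrix: np.ndarray           # 3N×3N covariance, Ų
    eigenvalues: np.ndarray      # descending
    eigenvectors: np.ndarray     # columns matching eigenvalues

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))


def covariance_analysis(frames, sel: str, atoms: AtomTable, fit: bool = True) -> CovarianceResult:
    """Positional covariance C = ⟨Δx Δxᵀ⟩ over frames (Δx = 3N displacement
    from the mean structure, after optional superposition)."""
    idx = _sel_idx(sel, atoms)
    masses = atoms.masses[idx]
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    if fit:
        coords = _aligned_coords(frames, idx, masses)
    else:
        coords = np.array([f.coords[idx] for f in frames])
    flat = coords.reshape(len(frames), -1)
    delta = flat - flat.mean(axis=0)
    matrix = delta.T @ delta / len(frames)
    eigenvalues, eigenvectors = np.linalg.eigh(matrix)
    order = np.argsort(eigenvalues)[::-1]
    return CovarianceResult(
        atom_indices=idx,
        matrix=matrix,
        eigenvalues=eigenvalues[order],
        eigenvectors=eigenvectors[:, order],
    )
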
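"""Contact analyses: group geometry series, residue contact maps,
residence-time statistics and radial distribution functions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import center_of_mass, measure_internal, minimum_image_displacement
from .selection import selection_indices
from .tables import TimeSeriesTable
from .topology import AtomTable

__all__ = [
    "bond_statistics",
    "residue_contacts",
    "ContactSeries",
    "contact_residence_time",
    "radial_distribution",
    "run_lengths",
]

DEFAULT_CONTACT_CUTOFF = 4.5  # Å heavy-atom minimum distance


def bond_statistics(frames, group_sels: list[str], atoms: AtomTable):
    """Distance/angle/dihedral between 2–4 group COMs per frame.

    Returns (TimeSeriesTable, mean, population SD).  The two-group distance
    uses the minimum image convention.
    """
    if len(group_sels) not in (2, 3, 4):
        raise ValueError("bond statistics needs 2, 3 or 4 groups")
    group_idx = []
    for sel in group_sels:
        idx = selection_indices(sel, atoms)
        if len(idx) == 0:
            raise ValueError(f"empty group: {sel!r}")
        group_idx.append(idx)
    kind = {2: "distance", 3: "angle", 4: "dihedral"}[len(group_sels)]
    table = TimeSeriesTable(["frame", kind])
    values = []
    for frame in frames:
        coms = np.array(
            [center_of_mass(frame.coords[idx], atoms.masses[idx]) for idx in group_idx]
        )
        if kind == "distance":
            value = float(
                np.linalg.norm(minimum_image_displacement(coms[0], coms[1], frame.box))
            )
        else:
            value = measure_internal(coms)
        values.append(value)
        table.append(frame.index, value)
    mean = float(np.mean(values))
    sd = float(np.std(values))
    return table, mean, sd


@dataclass
class ContactSeries:
    """Boolean per-frame contact indicator for one residue (or group) pair."""

    pair: tuple
    flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def _heavy(idx: np.ndarray, atoms: AtomTable) -> np.ndarray:
    return idx[atoms.elements[idx] != "H"]


def _min_image_dists(a_pos, b_pos, box):
    disp = minimum_image_displacement(a_pos[:, None, :], b_pos[None, :, :], box)
    return np.sqrt((disp**2).sum(axis=2))


def residue_contacts(
    frames,
    sel_a: str,
    sel_b: str,
    atoms: AtomTable,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
):
    """Residue-pair contact frequencies over the trajectory.

    Two residues are in contact in a frame when their minimum heavy-atom
    (minimum-image) distance is ≤ cutoff.  Returns (table sorted by
    frequency descending, {pair: ContactSeries}).  Table columns include
    the ascending frame-index list per pair.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    idx_a = _heavy(selection_indices(sel_a, atoms), atoms)
    idx_b = _heavy(selection_indices(sel_b, atoms), atoms)
    if set(idx_a) & set(idx_b):
        warnings.warn("selections overlap: self residue pairs are excluded")
    res_a = atoms.residue_groups(idx_a)
    res_b = atoms.residue_groups(idx_b)
    labels = atoms.residue_keys()

    def res_name(group):
        i = group[0]
        return f"{str(atoms.segids[i]).strip()}/{str(atoms.resnames[i]).strip()}{atoms.resids[i]}"

    flat_a = np.concatenate(res_a)
    flat_b = np.concatenate(res_b)
    owner_a = np.concatenate([np.full(len(g), k) for k, g in enumerate(res_a)])
    owner_b = np.concatenate([np.full(len(g), k) for k, g in enumerate(res_b)])
    hits: dict[tuple[int, int], list[int]] = {}   # pair -> run-order positions
    frame_ids: list[int] = []                     # global index per analyzed frame
    for pos, frame in enumerate(frames):
        frame_ids.append(frame.index)
        dists = _min_image_dists(frame.coords[flat_a], frame.coords[flat_b], frame.box)
        close = dists <= cutoff
        if not close.any():
            continue
        ia, ib = np.nonzero(close)
        seen = set()
        for pa, pb in zip(owner_a[ia], owner_b[ib]):
            key = (int(pa), int(pb))
            if key in seen:
                continue
            if labels[res_a[key[0]][0]] == labels[res_b[key[1]][0]]:
                continue  # same residue appearing in both selections
            seen.add(key)
            hits.setdefault(key, []).append(pos)
    n_frames = len(frame_ids)
    if n_frames == 0:
        raise ValueError("no frames")
    records = []
    series: dict[tuple[str, str], ContactSeries] = {}
    for (pa, pb), positions in hits.items():
        name_pair = (res_name(res_a[pa]), res_name(res_b[pb]))
        flags = np.zeros(n_frames, dtype=bool)
        flags[positions] = True
        series[name_pair] = ContactSeries(pair=name_pair, flags=flags)
        records.append(
            (len(positions) / n_frames, name_pair, [frame_ids[p] for p in positions])
        )
    records.sort(key=lambda r: (-r[0], r[1]))
    table = TimeSeriesTable(["resA", "resB", "frequency", "frames"])
    for freq, (na, nb), frame_list in records:
        table.append(na, nb, float(freq), ",".join(str(f) for f in frame_list))
    return table, series


def run_lengths(flags) -> list[int]:
    """Lengths of maximal runs of True, in order of appearance."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return []
    padded = np.concatenate(([False], flags, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [int(e - s) for s, e in zip(starts, ends)]


def contact_residence_time(series: ContactSeries, gap_tolerance: int = 0):
    """Mean/SD/count of contact run durations (frames) for one pair.

    Runs separated by ≤ gap_tolerance off-frames are merged.  Runs touching
    either trajectory end count as observed (no censoring).  Returns None
    for an all-false series (pair omitted by callers).
    """
    flags = np.asarray(series.flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty contact series")
    if gap_tolerance > 0:
        flags = flags.copy()
        on = np.nonzero(flags)[0]
        # fill gaps of <= gap_tolerance frames strictly between contacts
        for prev, nxt in zip(on[:-1], on[1:]):
            if 1 < nxt - prev <= gap_tolerance + 1:
                flags[prev + 1 : nxt] = True
    durations = run_lengths(flags)
    if not durations:
        return None
    arr = np.asarray(durations, dtype=float)
    return {
        "n_events": len(durations),
        "mean_frames": float(arr.mean()),
        "sd_frames": float(arr.std()),  # population SD; single event → 0
        "total_frames": int(arr.sum()),
    }


def radial_distribution(
    frames,
    sel_a: str,
    sel_b: str,
    atoms: AtomTable,
    bin_width: float = 0.1,
    r_max: float = 10.0,
):
    """g(r) between two selections with minimum-image distances.

    g(r) = ⟨pair count in [r, r+Δr)⟩ / (N_A · ρ_B · 4πr²Δr); self pairs are
    excluded when the selections overlap.  Requires r_max ≤ min(box)/2.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    idx_a = selection_indices(sel_a, atoms)
    idx_b = selection_indices(sel_b, atoms)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty RDF selection")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts = np.zeros(len(edges) - 1)
    n_frames = 0
    vol_sum = 0.0
    same = np.intersect1d(idx_a, idx_b)
    for frame in frames:
        if r_max > frame.box.min() / 2 + 1e-9:
            raise ValueError(
                f"r_max {r_max} exceeds half the smallest box length "
                f"{frame.box.min() / 2:.3f} (minimum-image validity)"
            )
        n_frames += 1
        vol_sum += frame.volume
        dists = _min_image_dists(frame.coords[idx_a], frame.coords[idx_b], frame.box)
        if len(same):
            pos_a = {int(v): i for i, v in enumerate(idx_a)}
            pos_b = {int(v): i for i, v in enumerate(idx_b)}
            for v in same:
                dists[pos_a[int(v)], pos_b[int(v)]] = np.inf
        hist, _ = np.histogram(dists[dists < r_max], bins=edges)
        counts += hist
    if n_frames == 0:
        raise ValueError("no frames")
    volume = vol_sum / n_frames
    rho_b = len(idx_b) / volume
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4 * np.pi * centers**2 * bin_width
    g = counts / (n_frames * len(idx_a) * rho_b * shell)
    table = TimeSeriesTable(["r", "g"])
    for r, value in zip(centers, g):
        table.append(float(r), float(value))
    return table
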
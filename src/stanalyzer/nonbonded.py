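"""Geometric detectors for hydrogen bonds, salt bridges, π-stacking and
water bridges.

All criteria are purely geometric with flag-adjustable cutoffs; outputs
are either frame-sorted interaction records (hydrogen/water bridges) or
frequency-sorted residue pairs with frame lists (salt bridges, π-stacking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .selection import selection_indices
from .tables import TimeSeriesTable
from .topology import AtomTable
from .trajectory import Frame

__all__ = [
    "InteractionRecord",
    "hydrogen_bonds",
    "salt_bridges",
    "pi_stacking",
    "water_bridges",
]

HBOND_DISTANCE_CUTOFF = 3.5   # Å donor–acceptor heavy-atom distance
HBOND_ANGLE_CUTOFF = 150.0    # degrees D–H···A
SALT_BRIDGE_CUTOFF = 4.0      # Å N(+)–O(−)
PI_CENTROID_CUTOFF = 6.0      # Å ring centroid distance
COVALENT_H_CUTOFF = 1.2       # Å: H within this distance is bonded

_POLAR_ELEMENTS = frozenset({"N", "O", "S", "F"})

#: basic (cationic) nitrogen atom names per residue
BASIC_NITROGENS = {
    "ARG": {"NH1", "NH2", "NE"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
#: acidic (anionic) oxygen atom names per residue
ACIDIC_OXYGENS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

#: aromatic ring atom names: (residue, ring label) -> names
AROMATIC_RINGS = {
    ("PHE", "ring"): ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    ("TYR", "ring"): ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    ("TRP", "ring5"): ["CG", "CD1", "CD2", "NE1", "CE2"],
    ("TRP", "ring6"): ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    ("HIS", "ring"): ["CG", "ND1", "CD2", "CE1", "NE2"],
}


@dataclass
class InteractionRecord:
    """One detected pairwise event."""

    frame: int
    kind: str                 # hbond | salt_bridge | pi_* | water_bridge
    donor: str                # atom/residue identifier (or first partner)
    acceptor: str             # atom/residue identifier (or second partner)
    distance: float           # Å
    angle: float | None = None  # degrees
    via: str | None = None      # bridging water for water bridges

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("interaction distance must be > 0")
        if self.angle is not None and not (0.0 <= self.angle <= 180.0):
            raise ValueError("interaction angle must be in [0, 180]")


def _atom_id(i: int, atoms: AtomTable) -> str:
    return (
        f"{str(atoms.segids[i]).strip()}/{str(atoms.resnames[i]).strip()}"
        f"{atoms.resids[i]}/{str(atoms.names[i]).strip()}"
    )


def _res_id(i: int, atoms: AtomTable) -> str:
    return (
        f"{str(atoms.segids[i]).strip()}/{str(atoms.resnames[i]).strip()}"
        f"{atoms.resids[i]}"
    )


def _find_donor_hydrogens(candidates: np.ndarray, atoms: AtomTable, frame: Frame):
    """Map polar donor atom -> bonded hydrogens (distance < 1.2 Å heuristic)."""
    h_all = np.nonzero(atoms.elements == "H")[0]
    donors = {}
    if len(h_all) == 0:
        return donors
    h_pos = frame.coords[h_all]
    for d in candidates:
        if atoms.elements[d] not in _POLAR_ELEMENTS:
            continue
        dist = np.linalg.norm(h_pos - frame.coords[d], axis=1)
        bonded = h_all[dist <= COVALENT_H_CUTOFF]
        if len(bonded):
            donors[int(d)] = [int(h) for h in bonded]
    return donors


def _angle_deg(a, b, c) -> float:
    v1 = a - b
    v2 = c - b
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0:
        return 0.0
    return float(np.degrees(np.arccos(np.clip(v1 @ v2 / denom, -1.0, 1.0))))


def _hbonds_in_frame(
    frame: Frame,
    donors: dict[int, list[int]],
    acceptor_idx: np.ndarray,
    d_cut: float,
    angle_cut: float,
):
    """(donor, hydrogen, acceptor, distance, angle) tuples for one frame."""
    out = []
    if not donors or len(acceptor_idx) == 0:
        return out
    acc_pos = frame.coords[acceptor_idx]
    for d, hydrogens in donors.items():
        d_pos = frame.coords[d]
        dist = np.linalg.norm(acc_pos - d_pos, axis=1)
        for j in np.nonzero(dist <= d_cut)[0]:
            a = int(acceptor_idx[j])
            if a == d:
                continue
            for h in hydrogens:
                if h == a:
                    continue
                ang = _angle_deg(d_pos, frame.coords[h], frame.coords[a])
                if ang >= angle_cut:
                    out.append((d, h, a, float(dist[j]), ang))
    return out


def hydrogen_bonds(
    frames,
    donor_sel: str,
    acceptor_sel: str,
    atoms: AtomTable,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
) -> list[InteractionRecord]:
    """Detect D–H···A hydrogen bonds; records sorted by frame index.

    Criteria: donor–acceptor distance ≤ d_cut and D–H···A angle ≥ angle_cut.
    Donors are N/O/S/F atoms of donor_sel carrying a hydrogen within 1.2 Å;
    acceptors are N/O/S/F atoms of acceptor_sel.
    """
    donor_cand = selection_indices(donor_sel, atoms)
    acceptor_idx = np.array(
        [i for i in selection_indices(acceptor_sel, atoms) if atoms.elements[i] in _POLAR_ELEMENTS],
        dtype=np.int64,
    )
    records: list[InteractionRecord] = []
    donors_map = None
    for frame in frames:
        if donors_map is None:
            donors_map = _find_donor_hydrogens(donor_cand, atoms, frame)
            if not donors_map:
                raise ValueError(
                    "no hydrogens found on donor atoms (explicit H within 1.2 Å required)"
                )
        for d, h, a, dist, ang in _hbonds_in_frame(
            frame, donors_map, acceptor_idx, d_cut, angle_cut
        ):
            records.append(
                InteractionRecord(
                    frame=frame.index,
                    kind="hbond",
                    donor=_atom_id(d, atoms),
                    acceptor=_atom_id(a, atoms),
                    distance=dist,
                    angle=ang,
                    via=_atom_id(h, atoms),
                )
            )
    records.sort(key=lambda r: (r.frame, r.donor, r.acceptor))
    return records


def _frequency_table(hits: dict[tuple, list[int]], n_frames: int, extra_cols=()):
    table = TimeSeriesTable(["resA", "resB", *extra_cols, "frequency", "frames"])
    rows = []
    for key, frame_list in hits.items():
        rows.append((len(frame_list) / n_frames, key, sorted(frame_list)))
    rows.sort(key=lambda r: (-r[0], r[1]))
    for freq, key, frame_list in rows:
        table.append(*key, float(freq), ",".join(map(str, frame_list)))
    return table


def salt_bridges(
    frames, atoms: AtomTable, d_cut: float = SALT_BRIDGE_CUTOFF
) -> TimeSeriesTable:
    """Detect basic-N/acidic-O salt bridges; residue pairs sorted by frequency.

    Basic: Arg NH1/NH2/NE, Lys NZ, His ND1/NE2 and each chain's N-terminal N.
    Acidic: Asp OD1/OD2, Glu OE1/OE2 and each chain's C-terminal OXT/O.
    """
    protein = np.nonzero(atoms.is_protein())[0]
    if len(protein) == 0:
        raise ValueError("no protein atoms")
    groups = atoms.residue_groups(protein)
    seg_first: dict[str, int] = {}
    seg_last: dict[str, int] = {}
    for k, g in enumerate(groups):
        seg = str(atoms.segids[g[0]]).strip()
        seg_first.setdefault(seg, k)
        seg_last[seg] = k
    basic: list[int] = []
    acidic: list[int] = []
    for k, g in enumerate(groups):
        resname = str(atoms.resnames[g[0]]).strip()
        seg = str(atoms.segids[g[0]]).strip()
        names = np.char.strip(atoms.names[g])
        for nm, i in zip(names, g):
            if nm in BASIC_NITROGENS.get(resname, ()):
                basic.append(int(i))
            if nm in ACIDIC_OXYGENS.get(resname, ()):
                acidic.append(int(i))
            if nm == "N" and k == seg_first[seg]:
                basic.append(int(i))
            if nm in ("OXT", "O") and k == seg_last[seg]:
                acidic.append(int(i))
    basic_arr = np.array(sorted(set(basic)), dtype=np.int64)
    acidic_arr = np.array(sorted(set(acidic)), dtype=np.int64)
    hits: dict[tuple, list[int]] = {}
    n_frames = 0
    for frame in frames:
        n_frames += 1
        if len(basic_arr) == 0 or len(acidic_arr) == 0:
            continue
        diff = frame.coords[basic_arr][:, None, :] - frame.coords[acidic_arr][None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        ib, ia = np.nonzero(dist <= d_cut)
        seen = set()
        for b, a in zip(basic_arr[ib], acidic_arr[ia]):
            pair = (_res_id(int(b), atoms), _res_id(int(a), atoms))
            if pair[0] == pair[1] or pair in seen:
                continue
            seen.add(pair)
            hits.setdefault(pair, []).append(frame.index)
    if n_frames == 0:
        raise ValueError("no frames")
    return _frequency_table(hits, n_frames)


def _ring_groups(atoms: AtomTable):
    """[(residue id string, ring label, atom index array), ...]"""
    protein = np.nonzero(atoms.is_protein())[0]
    rings = []
    for g in atoms.residue_groups(protein):
        resname = str(atoms.resnames[g[0]]).strip()
        names = np.char.strip(atoms.names[g])
        for (rn, label), ring_names in AROMATIC_RINGS.items():
            if rn != resname:
                continue
            idx = []
            for nm in ring_names:
                hit = g[names == nm]
                if len(hit) == 0:
                    idx = None
                    break
                idx.append(int(hit[0]))
            if idx is None:
                warnings.warn(
                    f"incomplete aromatic ring in {_res_id(int(g[0]), atoms)}; skipped"
                )
                continue
            rings.append((_res_id(int(g[0]), atoms), label, np.array(idx)))
    return rings


def _plane_normal(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def classify_ring_pair(alpha: float) -> str:
    """Interaction class from the acute interplanar angle (degrees)."""
    if alpha <= 30.0:
        return "pi_parallel"
    if alpha >= 60.0:
        return "pi_tshaped"
    return "pi_oblique"


def pi_stacking(
    frames, atoms: AtomTable, centroid_cut: float = PI_CENTROID_CUTOFF
) -> TimeSeriesTable:
    """Detect aromatic ring stacking; ring pairs sorted by frequency.

    A pair interacts when ring centroids are ≤ centroid_cut apart; the class
    follows the acute angle between SVD-fitted ring normals: parallel ≤ 30°,
    t-shaped ≥ 60°, oblique between.  Trp contributes its 5- and 6-rings
    separately.
    """
    rings = _ring_groups(atoms)
    hits: dict[tuple, list[int]] = {}
    n_frames = 0
    for frame in frames:
        n_frames += 1
        centroids = [frame.coords[idx].mean(axis=0) for _, _, idx in rings]
        normals = [_plane_normal(frame.coords[idx]) for _, _, idx in rings]
        for i in range(len(rings)):
            for j in range(i + 1, len(rings)):
                if rings[i][0] == rings[j][0]:
                    continue  # same residue (Trp ring pair)
                dist = float(np.linalg.norm(centroids[i] - centroids[j]))
                if dist > centroid_cut:
                    continue
                cosa = abs(float(normals[i] @ normals[j]))
                alpha = float(np.degrees(np.arccos(np.clip(cosa, 0.0, 1.0))))
                kind = classify_ring_pair(alpha)
                key = (
                    f"{rings[i][0]}:{rings[i][1]}",
                    f"{rings[j][0]}:{rings[j][1]}",
                    kind,
                )
                hits.setdefault(key, []).append(frame.index)
    if n_frames == 0:
        raise ValueError("no frames")
    return _frequency_table(hits, n_frames, extra_cols=("class",))


def water_bridges(
    frames,
    sel_a: str,
    sel_b: str,
    atoms: AtomTable,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
) -> list[InteractionRecord]:
    """Single-water bridges: one water hydrogen-bonded to both selections.

    A record (resA, water, resB, frame) is emitted when the same water
    simultaneously hydrogen-bonds (either donor/acceptor direction, same
    criteria as :func:`hydrogen_bonds`) to an atom of sel_a and of sel_b.
    Records are sorted by frame index.
    """
    water_mask = atoms.is_water()
    if not water_mask.any():
        raise ValueError("no water in system")
    water_idx = np.nonzero(water_mask)[0]
    idx_a = np.array([i for i in selection_indices(sel_a, atoms) if not water_mask[i]])
    idx_b = np.array([i for i in selection_indices(sel_b, atoms) if not water_mask[i]])
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty water-bridge partner selection")
    water_labels = atoms.residue_keys()[water_idx]
    records: list[InteractionRecord] = []
    donors_w = donors_a = donors_b = None
    polar = lambda arr: np.array(  # noqa: E731
        [i for i in arr if atoms.elements[i] in _POLAR_ELEMENTS], dtype=np.int64
    )
    acc_w, acc_a, acc_b = polar(water_idx), polar(idx_a), polar(idx_b)
    for frame in frames:
        if donors_w is None:
            donors_w = _find_donor_hydrogens(water_idx, atoms, frame)
            donors_a = _find_donor_hydrogens(idx_a, atoms, frame)
            donors_b = _find_donor_hydrogens(idx_b, atoms, frame)

        def bonded_waters(donors_sel, acc_sel, donors_water, acc_water):
            """water residue label -> partner atom index, both directions."""
            out: dict[int, int] = {}
            for d, h, a, dist, ang in _hbonds_in_frame(
                frame, donors_sel, acc_water, d_cut, angle_cut
            ):
                lab = int(atoms.residue_keys()[a])
                out.setdefault(lab, d)
            for d, h, a, dist, ang in _hbonds_in_frame(
                frame, donors_water, acc_sel, d_cut, angle_cut
            ):
                lab = int(atoms.residue_keys()[d])
                out.setdefault(lab, a)
            return out

        side_a = bonded_waters(donors_a, acc_a, donors_w, acc_w)
        side_b = bonded_waters(donors_b, acc_b, donors_w, acc_w)
        for lab in sorted(set(side_a) & set(side_b)):
            atom_a, atom_b = side_a[lab], side_b[lab]
            if _res_id(atom_a, atoms) == _res_id(atom_b, atoms):
                continue
            w_atom = int(water_idx[np.nonzero(water_labels == lab)[0][0]])
            records.append(
                InteractionRecord(
                    frame=frame.index,
                    kind="water_bridge",
                    donor=_res_id(atom_a, atoms),
                    acceptor=_res_id(atom_b, atoms),
                    distance=float(
                        np.linalg.norm(frame.coords[atom_a] - frame.coords[atom_b])
                    ),
                    via=_res_id(w_atom, atoms),
                )
            )
    records.sort(key=lambda r: (r.frame, r.donor, r.acceptor))
    return records


def records_to_table(records: list[InteractionRecord]) -> TimeSeriesTable:
    """Frame-sorted interaction records as a TSV-ready table."""
    table = TimeSeriesTable(["frame", "kind", "donor", "hydrogen_or_via", "acceptor", "distance", "angle"])
    for r in records:
        table.append(
            r.frame,
            r.kind,
            r.donor,
            r.via if r.via is not None else "-",
            r.acceptor,
            float(r.distance),
            float(r.angle) if r.angle is not None else float("nan"),
        )
    return table
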
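"""Deterministic synthetic systems with known ground truth.

Every analysis in the suite has at least one fixture kind here that
exercises it: flat bilayers with prescribed chain orientations, ideal-gas
boxes, random walks with known diffusion, ideal helices/strands, and
hand-placed interaction motifs.  Generators are seeded and byte-reproducible;
each fixture also emits a machine-readable ground-truth table.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Any, Optional

import numpy as np
from pydantic import BaseModel, Field

from .tables import TimeSeriesTable
from .topology import AtomTable
from .trajectory import Frame

__all__ = ["FixtureSpec", "build_system", "build_fixture", "emit_ground_truth"]

FIXTURE_KINDS = (
    "bilayer",
    "ideal_gas",
    "random_walk",
    "helix",
    "sheet",
    "hbond_motif",
    "salt_motif",
    "pi_motif",
    "water_bridge_motif",
    "pore",
)


class FixtureSpec(BaseModel):
    """Parameters for one synthetic system; same spec + seed → same bytes."""

    kind: str
    seed: int = 0
    box: tuple[float, float, float] = (40.0, 40.0, 80.0)
    n_frames: int = 1
    params: dict[str, Any] = Field(default_factory=dict)

    def model_post_init(self, __context) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {FIXTURE_KINDS}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


# ---------------------------------------------------------------------------
# small builders


class _SystemBuilder:
    def __init__(self):
        self.names: list[str] = []
        self.resnames: list[str] = []
        self.resids: list[int] = []
        self.segids: list[str] = []
        self.elements: list[str] = []
        self.coords: list[np.ndarray] = []
        self._resid = 0

    def new_residue(self, resname: str, segid: str = "SYS") -> int:
        self._resid += 1
        self._cur = (resname, self._resid, segid)
        return self._resid

    def atom(self, name: str, element: str, xyz) -> int:
        resname, resid, segid = self._cur
        self.names.append(name)
        self.resnames.append(resname)
        self.resids.append(resid)
        self.segids.append(segid)
        self.elements.append(element)
        self.coords.append(np.asarray(xyz, dtype=float))
        return len(self.names) - 1

    def table(self) -> AtomTable:
        return AtomTable.from_arrays(
            self.names, self.resnames, self.resids, self.segids, self.elements
        )

    def positions(self) -> np.ndarray:
        return np.array(self.coords)


def _nerf(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place point d with |cd|=bond, angle(b,c,d)=angle, dihedral(a,b,c,d)=dihedral."""
    ang = math.radians(angle)
    dih = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.2, 121.7, 120.8


def build_peptide(n_res: int, phi: float, psi: float, omega: float = 180.0):
    """Backbone (N, CA, C, O per residue) of an ideal-geometry peptide.

    Returns a list of per-residue dicts of atom positions.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    residues = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = residues[-1]
        n_next = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca_next = _nerf(prev["CA"], prev["C"], n_next, _B_N_CA, _A_C_N_CA, omega)
        c_next = _nerf(prev["C"], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
        prev["O"] = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    last = residues[-1]
    last["O"] = _nerf(last["N"], last["CA"], last["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    return residues


def _add_peptide(builder: _SystemBuilder, residues, segid: str, resname: str = "ALA"):
    for res in residues:
        builder.new_residue(resname, segid)
        for name in ("N", "CA", "C", "O"):
            builder.atom(name, name[0], res[name])


# ---------------------------------------------------------------------------
# fixture kinds


def _bilayer(spec: FixtureSpec, rng: np.random.Generator):
    p = spec.params
    nx, ny = int(p.get("nx", 4)), int(p.get("ny", 4))
    head_z = float(p.get("head_z", 19.0))
    n_carbons = int(p.get("n_carbons", 4))
    orientation = p.get("ch_orientation", "z")  # z | xy | iso
    lipid_types = list(p.get("lipid_types", ["LIPA"]))
    type_layout = p.get("type_layout", "checkerboard")
    z_jitter = float(p.get("z_jitter", 0.0))
    xy_jitter = float(p.get("xy_jitter", 0.0))
    n_sterols = int(p.get("n_sterols", 0))
    sterol_orientation = p.get("sterol_orientation", "z")  # z | xy | iso

    lx, ly, lz = spec.box
    dx, dy = lx / nx, ly / ny
    builder = _SystemBuilder()
    truth_labels: list[str] = []

    def chain_dirs(n):
        if orientation == "z":
            return np.tile([0.0, 0.0, 1.0], (n, 1))
        if orientation == "xy":
            phis = rng.uniform(0, 2 * np.pi, n)
            return np.stack([np.cos(phis), np.sin(phis), np.zeros(n)], axis=1)
        vec = rng.normal(size=(n, 3))
        return vec / np.linalg.norm(vec, axis=1, keepdims=True)

    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        for j in range(ny):
            for i in range(nx):
                if type_layout == "checkerboard":
                    resname = lipid_types[(i + j) % len(lipid_types)]
                else:
                    resname = lipid_types[(j * nx + i) % len(lipid_types)]
                builder.new_residue(resname, "MEMB")
                x = (i + 0.5) * dx + (rng.uniform(-xy_jitter, xy_jitter) if xy_jitter else 0.0)
                y = (j + 0.5) * dy + (rng.uniform(-xy_jitter, xy_jitter) if xy_jitter else 0.0)
                z_head = sign * head_z + (rng.uniform(-z_jitter, z_jitter) if z_jitter else 0.0)
                builder.atom("P", "P", (x, y, z_head))
                dirs = chain_dirs(n_carbons)
                for k in range(n_carbons):
                    cz = z_head - sign * 1.5 * (k + 1)
                    c_pos = np.array([x, y, cz])
                    builder.atom(f"C{k + 2}", "C", c_pos)
                    u = dirs[k]
                    builder.atom(f"H{k + 2}A", "H", c_pos + 1.09 * u)
                    builder.atom(f"H{k + 2}B", "H", c_pos - 1.09 * u)
                truth_labels.append(leaflet)
    if n_sterols:
        for s in range(n_sterols):
            builder.new_residue("STER", "MEMB")
            x = rng.uniform(0, lx)
            y = rng.uniform(0, ly)
            if sterol_orientation == "z":
                u = np.array([0.0, 0.0, 1.0])
            elif sterol_orientation == "xy":
                phi = rng.uniform(0, 2 * np.pi)
                u = np.array([math.cos(phi), math.sin(phi), 0.0])
            else:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
            base = np.array([x, y, 5.0])
            builder.atom("C3", "C", base)
            builder.atom("C17", "C", base + 8.0 * u)

    atoms = builder.table()
    pos = builder.positions()
    frames = [
        Frame(index=t, coords=pos.copy(), box=np.array(spec.box)) for t in range(spec.n_frames)
    ]
    apl = (lx * ly) / (nx * ny)
    scd = {"z": 1.0, "xy": 0.5, "iso": 0.0}[orientation]
    truth = {
        "apl": (apl, 1e-6),
        "dpp": (2 * head_z, 1e-6 if z_jitter == 0 else 0.1),
        "scd": (scd, 1e-9 if orientation in ("z", "xy") else 0.05),
        "n_lipids_per_leaflet": (nx * ny, 0),
    }
    extras = {"leaflet_labels": truth_labels}
    return atoms, frames, truth, extras


def _ideal_gas(spec: FixtureSpec, rng: np.random.Generator):
    n = int(spec.params.get("n", 500))
    box_jitter = float(spec.params.get("box_jitter", 0.0))  # relative Lx/Ly noise
    builder = _SystemBuilder()
    for _ in range(n):
        builder.new_residue("GAS", "BULK")
        builder.atom("AR", "AR", (0.0, 0.0, 0.0))
    atoms = builder.table()
    box = np.array(spec.box)
    frames = []
    for t in range(spec.n_frames):
        frame_box = box.copy()
        if box_jitter:
            frame_box[:2] *= 1.0 + rng.uniform(-box_jitter, box_jitter, 2)
        frames.append(
            Frame(index=t, coords=rng.uniform(0, 1, (n, 3)) * frame_box, box=frame_box)
        )
    truth = {
        "number_density": (n / float(np.prod(box)), 0.0),
        "gr_plateau": (1.0, 0.05),
    }
    return atoms, frames, truth, {}


def _random_walk(spec: FixtureSpec, rng: np.random.Generator):
    p = spec.params
    n = int(p.get("n", 200))
    sigma = float(p.get("sigma", 0.5))
    dt = float(p.get("dt", 1.0))
    builder = _SystemBuilder()
    for _ in range(n):
        builder.new_residue("WLK", "BULK")
        builder.atom("AR", "AR", (0.0, 0.0, 0.0))
    atoms = builder.table()
    box = np.array(spec.box)
    pos = rng.uniform(0, 1, (n, 3)) * box
    frames = []
    for t in range(spec.n_frames):
        frames.append(Frame(index=t, coords=pos - np.floor(pos / box) * box, box=box.copy()))
        pos = pos + rng.normal(0.0, sigma, (n, 3))
    truth = {
        "diffusion": (sigma**2 / (2 * dt), 0.10),  # per-axis Einstein relation
    }
    return atoms, frames, truth, {}


def _helix(spec: FixtureSpec, rng):
    p = spec.params
    n_res = int(p.get("n_res", 12))
    phi = float(p.get("phi", -57.0))
    psi = float(p.get("psi", -47.0))
    builder = _SystemBuilder()
    residues = build_peptide(n_res, phi, psi)
    _add_peptide(builder, residues, "PROA")
    atoms = builder.table()
    pos = builder.positions()
    center = pos.mean(axis=0)
    pos = pos - center + np.array(spec.box) / 2
    frames = [Frame(index=t, coords=pos.copy(), box=np.array(spec.box)) for t in range(spec.n_frames)]
    truth = {"interior_code": ("H", 0)}
    return atoms, frames, truth, {}


def _sheet(spec: FixtureSpec, rng):
    from .dssp import HBOND_ENERGY_CUTOFF, kabsch_sander_energy

    p = spec.params
    n_res = int(p.get("n_res", 6))
    phi = float(p.get("phi", -139.0))
    psi = float(p.get("psi", 135.0))
    strand1 = build_peptide(n_res, phi, psi)
    strand2 = build_peptide(n_res, phi, psi)

    # strand 2 antiparallel: rotate 180° about the strand (x) axis, reverse
    # direction by rotating 180° about z, then grid-search the rigid offset
    # that maximizes the number of Kabsch–Sander inter-strand H-bonds.
    rot = np.diag([-1.0, 1.0, -1.0])  # 180° about y: reverses x, flips z

    def transformed(offset):
        out = []
        for res in strand2:
            out.append({k: rot @ v + offset for k, v in res.items()})
        return out

    def hb_pairs(s2):
        """Directed inter-strand H-bonds {(donor, acceptor)} (local indices)."""
        bonds = set()
        for tag_a, tag_b, a, b in (("1", "2", strand1, s2), ("2", "1", s2, strand1)):
            for i in range(1, len(a)):
                prev = a[i - 1]
                direction = prev["C"] - prev["O"]
                h = a[i]["N"] + 1.01 * direction / np.linalg.norm(direction)
                for j in range(len(b)):
                    e = kabsch_sander_energy(a[i]["N"], h, b[j]["C"], b[j]["O"])
                    if e < HBOND_ENERGY_CUTOFF:
                        bonds.add((tag_a, i, tag_b, j))
        return bonds

    def score(bonds):
        # reciprocal pairs drive antiparallel bridges; reward them heavily
        reciprocal = sum(
            1
            for (ta, i, tb, j) in bonds
            if ta == "1" and ("2", j, "1", i) in bonds
        )
        return 20 * reciprocal + len(bonds)

    ref = strand1[0]["CA"]
    best = None
    for dx in np.arange(-4.0, 14.01, 0.2):
        for dy in np.arange(3.5, 6.01, 0.2):
            for dz in np.arange(-1.0, 1.01, 0.2):
                offset = ref + np.array([dx, dy, dz]) - (rot @ strand2[0]["CA"])
                bonds = hb_pairs(transformed(offset))
                sc = score(bonds)
                if best is None or sc > best[0]:
                    best = (sc, offset, bonds)
    strand2_placed = transformed(best[1])

    builder = _SystemBuilder()
    _add_peptide(builder, strand1, "PROA")
    _add_peptide(builder, strand2_placed, "PROB")
    atoms = builder.table()
    pos = builder.positions()
    pos = pos - pos.mean(axis=0) + np.array(spec.box) / 2
    frames = [Frame(index=t, coords=pos.copy(), box=np.array(spec.box)) for t in range(spec.n_frames)]
    truth = {"interior_code": ("E", 0), "n_interstrand_hbonds": (len(best[2]), 0)}
    return atoms, frames, truth, {}


def _hbond_motif(spec: FixtureSpec, rng):
    p = spec.params
    d = float(p.get("distance", 2.8))
    angle = float(p.get("angle", 180.0))
    builder = _SystemBuilder()
    builder.new_residue("DON", "MOTF")
    d_pos = np.array([10.0, 10.0, 10.0])
    h_pos = d_pos + np.array([0.96, 0.0, 0.0])
    builder.atom("OD", "O", d_pos)
    builder.atom("HD", "H", h_pos)
    # place acceptor at D–A distance d with D–H–A angle as requested
    beta = math.radians(180.0 - angle)
    u = np.array([math.cos(beta), math.sin(beta), 0.0])
    # solve |h + s·u − d_pos| = d for s > 0
    w = h_pos - d_pos
    b = 2 * float(w @ u)
    c = float(w @ w) - d * d
    disc = b * b - 4 * c
    if disc < 0:
        raise ValueError("no acceptor placement satisfies distance/angle")
    s = (-b + math.sqrt(disc)) / 2
    a_pos = h_pos + s * u
    builder.new_residue("ACC", "MOTF")
    builder.atom("OA", "O", a_pos)
    atoms = builder.table()
    frames = [
        Frame(index=t, coords=builder.positions(), box=np.array(spec.box))
        for t in range(spec.n_frames)
    ]
    truth = {"hbond_distance": (d, 1e-9), "hbond_angle": (angle, 1e-6)}
    return atoms, frames, truth, {}


def _salt_motif(spec: FixtureSpec, rng):
    d = float(spec.params.get("distance", 3.5))
    builder = _SystemBuilder()
    builder.new_residue("LYS", "PROA")
    builder.atom("NZ", "N", (10.0, 10.0, 10.0))
    builder.new_residue("GLU", "PROA")
    builder.atom("OE1", "O", (10.0 + d, 10.0, 10.0))
    atoms = builder.table()
    frames = [
        Frame(index=t, coords=builder.positions(), box=np.array(spec.box))
        for t in range(spec.n_frames)
    ]
    return atoms, frames, {"salt_distance": (d, 1e-9)}, {}


def _hexagon(center, normal_axis: str, radius: float = 1.39) -> list[np.ndarray]:
    pts = []
    for k in range(6):
        ang = k * math.pi / 3
        if normal_axis == "z":
            v = np.array([math.cos(ang), math.sin(ang), 0.0])
        elif normal_axis == "x":
            v = np.array([0.0, math.cos(ang), math.sin(ang)])
        else:
            v = np.array([math.cos(ang), 0.0, math.sin(ang)])
        pts.append(np.asarray(center, dtype=float) + radius * v)
    return pts


def _pi_motif(spec: FixtureSpec, rng):
    p = spec.params
    sep = float(p.get("separation", 3.8))
    geometry = p.get("geometry", "parallel")  # parallel | perpendicular
    ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    builder = _SystemBuilder()
    c1 = np.array([15.0, 15.0, 15.0])
    builder.new_residue("PHE", "PROA")
    for name, xyz in zip(ring_names, _hexagon(c1, "z")):
        builder.atom(name, "C", xyz)
    builder.new_residue("PHE", "PROA")
    if geometry == "parallel":
        c2 = c1 + np.array([0.0, 0.0, sep])
        pts = _hexagon(c2, "z")
    else:
        c2 = c1 + np.array([0.0, 0.0, sep])
        pts = _hexagon(c2, "x")
    for name, xyz in zip(ring_names, pts):
        builder.atom(name, "C", xyz)
    atoms = builder.table()
    frames = [
        Frame(index=t, coords=builder.positions(), box=np.array(spec.box))
        for t in range(spec.n_frames)
    ]
    expected = "pi_parallel" if geometry == "parallel" else "pi_tshaped"
    return atoms, frames, {"pi_class": (expected, 0), "pi_distance": (sep, 1e-9)}, {}


def _water_bridge_motif(spec: FixtureSpec, rng):
    p = spec.params
    d = float(p.get("distance", 2.8))
    n_waters = int(p.get("n_waters", 1))
    builder = _SystemBuilder()
    ow = np.array([15.0, 15.0, 15.0])
    half = math.radians(104.5 / 2)
    u1 = np.array([math.cos(half), math.sin(half), 0.0])
    u2 = np.array([math.cos(half), -math.sin(half), 0.0])
    a_pos = ow + d * u1
    builder.new_residue("MOA", "MOTF")
    builder.atom("OA", "O", a_pos)
    if n_waters == 1:
        builder.new_residue("TIP3", "SOLV")
        builder.atom("OH2", "O", ow)
        builder.atom("H1", "H", ow + 0.96 * u1)
        builder.atom("H2", "H", ow + 0.96 * u2)
        b_pos = ow + d * u2
    else:
        # chain A···w1···w2···B — no single water touches both ends
        builder.new_residue("TIP3", "SOLV")
        builder.atom("OH2", "O", ow)
        builder.atom("H1", "H", ow + 0.96 * u1)
        builder.atom("H2", "H", ow + 0.96 * u2)
        ow2 = ow + d * u2
        builder.new_residue("TIP3", "SOLV")
        builder.atom("OH2", "O", ow2)
        builder.atom("H1", "H", ow2 + 0.96 * u2)
        builder.atom("H2", "H", ow2 + 0.96 * np.array([0.0, 0.0, 1.0]))
        b_pos = ow2 + d * u2
    builder.new_residue("MOB", "MOTF")
    builder.atom("OB", "O", b_pos)
    atoms = builder.table()
    frames = [
        Frame(index=t, coords=builder.positions(), box=np.array(spec.box))
        for t in range(spec.n_frames)
    ]
    truth = {"n_bridges_per_frame": (1 if n_waters == 1 else 0, 0)}
    return atoms, frames, truth, {}


def _pore(spec: FixtureSpec, rng):
    p = spec.params
    rings = p.get("rings", [(-5.0, 5.0), (5.0, 4.0)])  # (z, xy-radius)
    n_ring = int(p.get("atoms_per_ring", 12))
    builder = _SystemBuilder()
    cx, cy = spec.box[0] / 2, spec.box[1] / 2
    for z, radius in rings:
        builder.new_residue("POR", "PORE")
        for k in range(n_ring):
            ang = 2 * math.pi * k / n_ring
            builder.atom(
                "C", "C", (cx + radius * math.cos(ang), cy + radius * math.sin(ang), z)
            )
    atoms = builder.table()
    frames = [
        Frame(index=t, coords=builder.positions(), box=np.array(spec.box))
        for t in range(spec.n_frames)
    ]
    truth = {
        f"pore_radius_z{z:g}": (max(radius - 1.7, 0.0), 1e-9) for z, radius in rings
    }
    return atoms, frames, truth, {}


_BUILDERS = {
    "bilayer": _bilayer,
    "ideal_gas": _ideal_gas,
    "random_walk": _random_walk,
    "helix": _helix,
    "sheet": _sheet,
    "hbond_motif": _hbond_motif,
    "salt_motif": _salt_motif,
    "pi_motif": _pi_motif,
    "water_bridge_motif": _water_bridge_motif,
    "pore": _pore,
}


def build_system(spec: FixtureSpec):
    """In-memory fixture: (AtomTable, [Frame, ...], ground truth dict)."""
    rng = np.random.default_rng(spec.seed)
    atoms, frames, truth, extras = _BUILDERS[spec.kind](spec, rng)
    return atoms, frames, truth, extras


def emit_ground_truth(spec: FixtureSpec) -> TimeSeriesTable:
    """Machine-readable (observable, expected, tolerance) table."""
    _, _, truth, _ = build_system(spec)
    table = TimeSeriesTable(["observable", "expected", "tolerance"])
    for key, (value, tol) in truth.items():
        table.append(key, value, tol)
    return table


# ---------------------------------------------------------------------------
# file output


def _format_pdb_atom(serial, name, resname, segid, resid, xyz, element) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"ATOM  {serial:>5d} {name_field}{'':1s}{resname:<4s}{'':1s}{resid:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}      "
        f"{segid:<4s}{element:>2s}\n"
    )


def write_pdb(atoms: AtomTable, coords: np.ndarray, box, path) -> Path:
    """Write a single-model PDB (v3.3 columns, CHARMM-style segid field)."""
    path = Path(path)
    lines = [
        f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
    ]
    for i in range(atoms.n_atoms):
        lines.append(
            _format_pdb_atom(
                (i + 1) % 100000,
                str(atoms.names[i]).strip(),
                str(atoms.resnames[i]).strip(),
                str(atoms.segids[i]).strip(),
                int(atoms.resids[i]) % 10000,
                coords[i],
                str(atoms.elements[i]).strip(),
            )
        )
    lines.append("END\n")
    path.write_text("".join(lines))
    return path


def write_dcd(frames: list[Frame], path) -> Path:
    """Write frames to a CHARMM-style DCD (fixed remarks: byte-reproducible)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
        from MDAnalysis.coordinates.DCD import DCDWriter

        path = Path(path)
        n_atoms = frames[0].n_atoms
        universe = mda.Universe.empty(n_atoms, trajectory=True)
        with DCDWriter(str(path), n_atoms, remarks="synthetic fixture") as writer:
            for frame in frames:
                universe.atoms.positions = frame.coords.astype(np.float32)
                universe.dimensions = [*frame.box, 90.0, 90.0, 90.0]
                writer.write(universe.atoms)
    return path


def build_fixture(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Write structure PDB + trajectory DCD + ground-truth TSV to out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    atoms, frames, truth, _ = build_system(spec)
    paths = {
        "structure": write_pdb(atoms, frames[0].coords, frames[0].box, out_dir / "structure.pdb"),
        "trajectory": write_dcd(frames, out_dir / "trajectory.dcd"),
    }
    truth_table = TimeSeriesTable(["observable", "expected", "tolerance"])
    for key, (value, tol) in truth.items():
        truth_table.append(key, value, tol)
    paths["ground_truth"] = truth_table.write(out_dir / "ground_truth.tsv")
    return paths
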
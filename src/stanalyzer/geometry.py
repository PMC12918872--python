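"""Shared geometric primitives.

Periodic displacement, mass-weighted centers, optimal rigid superposition,
internal coordinates (distance/angle/dihedral) and periodic 2-D Voronoi
tessellation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi

__all__ = [
    "minimum_image_displacement",
    "center_of_mass",
    "kabsch_superpose",
    "SuperpositionResult",
    "measure_internal",
    "periodic_voronoi",
    "VoronoiDiagram",
]


def minimum_image_displacement(a, b, box) -> np.ndarray:
    """Displacement b−a with each component wrapped into [−L/2, L/2).

    Also accepts arrays of vectors (broadcasting over leading axes).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    disp = b - a
    return disp - np.floor(disp / box + 0.5) * box


def center_of_mass(coords, masses) -> np.ndarray:
    """Mass-weighted mean position Σ m_i x_i / Σ m_i."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("center_of_mass of an empty group")
    if np.any(masses <= 0):
        raise ValueError("masses must be > 0")
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3×3, orthonormal, det=+1
    translation: np.ndarray   # 3-vector: applied after rotation
    rmsd: float

    def apply(self, coords) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(mobile, reference, weights=None) -> SuperpositionResult:
    """Optimal weighted rigid superposition of mobile onto reference.

    Rotation via SVD of the weighted cross-covariance with determinant sign
    correction, so reflections are never returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching k×3 arrays")
    k = mobile.shape[0]
    if k < 1:
        raise ValueError("empty point sets")
    if weights is None:
        weights = np.ones(k)
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()
    mob_c = (weights[:, None] * mobile).sum(axis=0) / wsum
    ref_c = (weights[:, None] * reference).sum(axis=0) / wsum
    p = mobile - mob_c
    q = reference - ref_c
    cov = (weights[:, None] * p).T @ q
    u, s, vt = np.linalg.svd(cov)
    if k >= 3 and s[-1] < 1e-10 * max(s[0], 1e-300):
        warnings.warn("degenerate (collinear/planar-singular) point set in superposition")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_c - rotation @ mob_c
    resid = p @ rotation.T - q
    rmsd = float(np.sqrt((weights * (resid**2).sum(axis=1)).sum() / wsum))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def measure_internal(points) -> float:
    """Distance (2 points, Å), angle (3, degrees) or signed dihedral (4, degrees).

    Dihedral uses the atan2 convention on plane normals; range (−180°, 180°],
    positive clockwise looking from point 2 to point 3.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] not in (2, 3, 4):
        raise ValueError("measure_internal takes 2, 3 or 4 points")
    if pts.shape[0] == 2:
        return float(np.linalg.norm(pts[1] - pts[0]))
    if pts.shape[0] == 3:
        v1 = pts[0] - pts[1]
        v2 = pts[2] - pts[1]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            raise ValueError("angle undefined: coincident points")
        cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
        return float(np.degrees(np.arccos(cosang)))
    b1 = pts[1] - pts[0]
    b2 = pts[2] - pts[1]
    b3 = pts[3] - pts[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0 or np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise ValueError("dihedral undefined: degenerate geometry")
    x = n1 @ n2
    y = np.cross(n1, n2) @ b2 / b2n
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


@dataclass
class VoronoiDiagram:
    sites: np.ndarray                 # M×2 Å (wrapped into the box)
    areas: np.ndarray                 # M cell areas Ų
    neighbors: list[set[int]]         # per-site neighbor site indices
    box: tuple[float, float]


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def periodic_voronoi(sites, box2d) -> VoronoiDiagram:
    """Periodic 2-D Voronoi tessellation via 3×3 image replication.

    Cells and neighbor lists are reported for the central copy only; the
    neighbor relation is symmetric and image neighbors map back to their
    central-copy index.  Duplicate sites are jittered by ~1e-6 Å with a
    warning.  A single site owns the whole box.
    """
    sites = np.asarray(sites, dtype=float).reshape(-1, 2)
    lx, ly = float(box2d[0]), float(box2d[1])
    if lx <= 0 or ly <= 0:
        raise ValueError("box lengths must be positive")
    m = sites.shape[0]
    if m < 1:
        raise ValueError("need at least one site")
    box = np.array([lx, ly])
    wrapped = sites - np.floor(sites / box) * box

    if m == 1:
        return VoronoiDiagram(
            sites=wrapped, areas=np.array([lx * ly]), neighbors=[set()], box=(lx, ly)
        )

    # deterministic de-duplication jitter
    rounded = np.round(wrapped / 1e-7).astype(np.int64)
    seen: dict[tuple, int] = {}
    for i, key in enumerate(map(tuple, rounded)):
        if key in seen:
            warnings.warn("duplicate Voronoi sites: applying 1e-6 Å jitter")
            wrapped[i] += (1e-6 * (seen[key] + 1), 1.3e-6 * (seen[key] + 1))
            seen[key] += 1
        else:
            seen[key] = 0

    shifts = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]
    images = np.concatenate([wrapped + np.array([sx * lx, sy * ly]) for sx, sy in shifts])
    central_offset = shifts.index((0, 0)) * m
    vor = Voronoi(images)

    areas = np.empty(m)
    for i in range(m):
        region = vor.regions[vor.point_region[central_offset + i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded central Voronoi cell (site too close to box edge?)")
        areas[i] = _polygon_area(vor.vertices[region])

    neighbors: list[set[int]] = [set() for _ in range(m)]
    for p1, p2 in vor.ridge_points:
        a, b = int(p1) % m, int(p2) % m
        in_central = (central_offset <= p1 < central_offset + m) or (
            central_offset <= p2 < central_offset + m
        )
        if in_central and a != b:
            neighbors[a].add(b)
            neighbors[b].add(a)
        elif in_central and a == b and p1 != p2:
            pass  # own periodic image: not a neighbor
    return VoronoiDiagram(sites=wrapped, areas=areas, neighbors=neighbors, box=(lx, ly))
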
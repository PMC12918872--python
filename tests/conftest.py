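"""Shared test fixtures: all synthetic, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from stanalyzer.fixtures import FixtureSpec, build_system
from stanalyzer.topology import AtomTable
from stanalyzer.trajectory import Frame


def make_frames(coords_list, box=(40.0, 40.0, 80.0)):
    return [Frame(index=i, coords=c, box=np.array(box)) for i, c in enumerate(coords_list)]


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR with sign fix, det=+1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigid_move(frame: Frame, rotation: np.ndarray, translation: np.ndarray) -> Frame:
    return Frame(
        index=frame.index,
        coords=frame.coords @ rotation.T + translation,
        box=frame.box.copy(),
    )


@pytest.fixture(scope="session")
def bilayer_system():
    """4×4 lattice per leaflet, heads at ±19 Å, C–H along z, 2 lipid types."""
    spec = FixtureSpec(
        kind="bilayer",
        seed=3,
        n_frames=3,
        box=(40.0, 40.0, 80.0),
        params={"nx": 4, "ny": 4, "lipid_types": ["LIPA", "LIPB"], "n_carbons": 3},
    )
    atoms, frames, truth, extras = build_system(spec)
    return atoms, frames, truth, extras


@pytest.fixture(scope="session")
def helix_system():
    spec = FixtureSpec(kind="helix", seed=0, params={"n_res": 12})
    atoms, frames, truth, _ = build_system(spec)
    return atoms, frames


@pytest.fixture(scope="session")
def sheet_system():
    spec = FixtureSpec(kind="sheet", seed=0, params={"n_res": 6})
    atoms, frames, truth, _ = build_system(spec)
    return atoms, frames


@pytest.fixture
def pentapeptide() -> AtomTable:
    """5-residue mini-peptide topology: N, CA, CB per residue (CB on 3)."""
    names, resnames, resids = [], [], []
    for i in range(1, 6):
        for name in ("N", "CA", "CB"):
            names.append(name)
            resnames.append("ALA")
            resids.append(i)
    return AtomTable.from_arrays(names, resnames, resids)
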
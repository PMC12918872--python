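"""Trajectory frame iteration over DCD / multi-model PDB files.

File reading is delegated to MDAnalysis; everything downstream of this
module sees only :class:`Frame` objects and :class:`AtomTable` topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .project import ProjectSettings
from .topology import AtomTable

__all__ = ["Frame", "TrajectoryError", "load_structure", "iterate_frames", "read_frames"]


class TrajectoryError(RuntimeError):
    pass


@dataclass
class Frame:
    """One trajectory snapshot."""

    index: int                    # global 0-based index across files
    coords: np.ndarray            # N×3 Å
    box: np.ndarray               # (Lx, Ly, Lz) Å, orthorhombic
    time: Optional[float] = None  # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be N×3")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive lengths")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def load_structure(path) -> AtomTable:
    """Read a structure file (PDB) into an AtomTable."""
    mda = _import_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(str(path))
    return AtomTable.from_mdanalysis(universe)


def _check_box(dimensions, file: str, local_index: int) -> np.ndarray:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        raise TrajectoryError(f"missing box record in {file} frame {local_index}")
    dims = np.asarray(dimensions, dtype=float)
    angles = dims[3:6]
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise TrajectoryError(
            f"triclinic box in {file} frame {local_index} is unsupported "
            "(orthorhombic boxes only)"
        )
    if np.any(dims[:3] <= 0):
        raise TrajectoryError(f"non-positive box length in {file} frame {local_index}")
    return dims[:3].copy()


def read_frames(structure_path, trajectory_files, atoms: AtomTable) -> Iterator[Frame]:
    """Yield every frame of the file list with a continuous global index."""
    mda = _import_mda()
    index = 0
    for file in trajectory_files:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                universe = mda.Universe(str(structure_path), str(file))
        except Exception as exc:
            raise TrajectoryError(f"cannot open trajectory {file}: {exc}") from exc
        if universe.atoms.n_atoms != atoms.n_atoms:
            raise TrajectoryError(
                f"topology mismatch: trajectory {file} has {universe.atoms.n_atoms} "
                f"atoms, structure has {atoms.n_atoms}"
            )
        for local, ts in enumerate(universe.trajectory):
            try:
                coords = np.asarray(ts.positions, dtype=float)
                box = _check_box(ts.dimensions, str(file), local)
            except TrajectoryError:
                raise
            except Exception as exc:
                raise TrajectoryError(
                    f"corrupt frame {local} in {file}: {exc}"
                ) from exc
            yield Frame(index=index, coords=coords, box=box)
            index += 1


def iterate_frames(settings: ProjectSettings, atoms: AtomTable) -> Iterator[Frame]:
    """Stream frames honoring frame_start/frame_stop (exclusive)/frame_stride.

    Frame indices are global, 0-based and continuous across file boundaries;
    frame times come from ``time_step`` when configured.
    """
    start = settings.frame_start or 0
    stop = settings.frame_stop  # exclusive; None = all
    stride = settings.frame_stride
    if stride < 1:
        raise ValueError("frame_stride must be >= 1")
    files = settings.trajectory_files()
    for frame in read_frames(settings.structure_path, files, atoms):
        if stop is not None and frame.index >= stop:
            return
        if frame.index < start or (frame.index - start) % stride:
            continue
        if settings.time_step is not None:
            frame.time = frame.index * settings.time_step
        yield frame


def slice_frames(frames, start=0, stop=None, stride=1) -> Iterator[Frame]:
    """Apply the same windowing to an in-memory frame iterable (test helper)."""
    if stride < 1:
        raise ValueError("frame_stride must be >= 1")
    for frame in frames:
        if stop is not None and frame.index >= stop:
            return
        if frame.index < start or (frame.index - start) % stride:
            continue
        yield frame
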
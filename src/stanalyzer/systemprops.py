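"""System-level analyses: box-size series, 3-D solution diffusion, and
replicate confidence intervals."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .membrane import _unwrap_com_track, msd_curve, msd_diffusion_fit
from .selection import selection_indices
from .tables import TimeSeriesTable
from .topology import AtomTable

__all__ = ["system_size", "solution_msd", "replicate_confidence_interval"]

ANG2_PER_PS_TO_CM2_PER_S = 1e-4  # 1 Ų/ps = 1e-16 cm² / 1e-12 s


def system_size(frames) -> TimeSeriesTable:
    """Per-frame box dimensions and volume."""
    table = TimeSeriesTable(["frame", "Lx", "Ly", "Lz", "volume"])
    for frame in frames:
        lx, ly, lz = (float(v) for v in frame.box)
        table.append(frame.index, lx, ly, lz, lx * ly * lz)
    if not table.rows:
        raise ValueError("no frames")
    return table


def solution_msd(
    frames,
    sel: str,
    atoms: AtomTable,
    dt: float = 1.0,
    fit_window: tuple[float, float] = (0.2, 0.8),
):
    """3-D MSD(τ) of per-residue COMs and the Einstein diffusion coefficient.

    Returns (table, D in Ų/ps, D in cm²/s); D = MSD slope / 6 over the
    middle ``fit_window`` of lags.
    """
    idx = selection_indices(sel, atoms)
    if len(idx) == 0:
        raise ValueError(f"empty selection: {sel!r}")
    groups = atoms.residue_groups(idx)
    track = _unwrap_com_track(frames, groups, atoms, slice(0, 3))
    if track.shape[0] < 2:
        raise ValueError("need at least 2 frames for MSD")
    msd = msd_curve(track)
    lags = np.arange(len(msd))
    d_ang = msd_diffusion_fit(lags, msd, n_dim=3, dt=dt, fit_window=fit_window)
    table = TimeSeriesTable(["lag", "time", "msd"])
    for tau, value in enumerate(msd):
        table.append(int(tau), float(tau * dt), float(value))
    return table, d_ang, d_ang * ANG2_PER_PS_TO_CM2_PER_S


def replicate_confidence_interval(values, level: float = 0.90) -> tuple[float, float]:
    """(mean, CI halfwidth) from k independent replicate values.

    halfwidth = t_{(1+level)/2, k−1} × SE with SE = sample SD / √k.
    """
    arr = np.asarray(values, dtype=float)
    k = arr.size
    if k < 2:
        raise ValueError("need at least 2 replicate values")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    multiplier = float(stats.t.ppf((1 + level) / 2, df=k - 1))
    se = float(arr.std(ddof=1) / np.sqrt(k))
    return float(arr.mean()), multiplier * se
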
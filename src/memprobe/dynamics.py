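"""Lateral mean-square displacement and Einstein-relation diffusion fitting.

For 2D Brownian motion MSD(t) = 4Dt; the diffusion coefficient is the
slope/4 of an ordinary least-squares line fitted to the time-origin-averaged
MSD on a late-time window (default 11–50 ns, past the sub-linear "cage"
transient of lipid motion).  Before averaging, the mass-weighted lateral
center of mass of the whole system is removed frame by frame.  The MSD uses
the FFT-based correlation identity, verified elsewhere against the O(N²)
time-origin double loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .core_io import (
    DataError, Leaflet, Selection, Trajectory, minimum_image, select,
)
from .units import A2_per_ns_to_um2_per_s


@dataclass
class MSDResult:
    lag_times: np.ndarray       # ns
    msd: np.ndarray             # Å²
    stderr: np.ndarray          # Å², across particles
    n_particles: int
    com_removed: bool


@dataclass
class DiffusionEstimate:
    D: float                    # μm²/s
    stderr: float               # μm²/s
    fit_window: Tuple[float, float]   # ns
    r_squared: float
    intercept: float = 0.0      # Å² (reported, not used)


def unwrap(traj: Trajectory, particle_sel: Optional[Selection] = None) -> np.ndarray:
    """Continuous lateral (x, y) paths for the selected particles, shape (F, n, 2).

    Removes periodic jumps by adding ±L whenever a frame-to-frame
    displacement exceeds half a box edge; the inverse of wrapping provided
    the motion is sampled finely enough.  Raises if any raw displacement
    reaches half a box edge, which the correction cannot distinguish from a
    genuine long jump.
    """
    idx = (np.arange(traj.n_particles) if particle_sel is None
           else select(traj, particle_sel, 0))
    xy = traj.coords[:, idx, :2].astype(float).copy()
    if not traj.periodic or traj.n_frames < 2:
        return xy
    box = traj.box[:-1, None, :2]
    steps = np.diff(xy, axis=0)
    if np.any(np.abs(minimum_image(steps, traj.box[:-1, None, :2])) * 2
              >= box - 1e-9):
        raise DataError(
            "frame-to-frame displacement >= half box edge: trajectory is "
            "undersampled for unwrapping")
    corrected = minimum_image(steps, traj.box[:-1, None, :2])
    out = np.empty_like(xy)
    out[0] = xy[0]
    out[1:] = xy[0] + np.cumsum(corrected, axis=0)
    return out


def _msd_fft_single(x: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of one particle, x shape (F, k) coordinates."""
    n = x.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    s2 = np.zeros(n)
    for c in range(x.shape[1]):
        f = np.fft.rfft(x[:, c], nfft)
        acf = np.fft.irfft(f * np.conj(f), nfft)[:n]
        s2 += acf
    d = (x ** 2).sum(axis=1)
    sumsq = 2.0 * d.sum()
    s1 = np.empty(n)
    for m in range(n):
        s1[m] = sumsq
        sumsq -= d[m] + d[n - 1 - m]
    counts = n - np.arange(n)
    return (s1 - 2.0 * s2) / counts


def compute_msd(traj: Trajectory, particle_sel: Optional[Selection] = None,
                max_lag: Optional[float] = None,
                com_removal: bool = True) -> MSDResult:
    """Time-origin-averaged lateral MSD of the selected particles.

    Paths are unwrapped internally; with ``com_removal`` the mass-weighted
    lateral center of mass of the *entire system* (all particles) is
    subtracted from every coordinate per frame before averaging.  The lag
    grid is every multiple of the frame spacing up to ``max_lag`` (ns;
    default half the trajectory length).  ``stderr`` is the standard error
    across particles.
    """
    if traj.n_frames < 2:
        raise DataError("need at least 2 frames for an MSD")
    times = traj.times - traj.times[0]
    dt = times[1] - times[0]
    if max_lag is None:
        max_lag = times[-1] / 2
    n_lag = int(round(max_lag / dt))
    if n_lag >= traj.n_frames:
        raise DataError("max_lag must be shorter than the trajectory")

    paths = unwrap(traj, particle_sel)                     # (F, n, 2)
    if com_removal:
        all_paths = unwrap(traj, None)
        masses = traj.masses
        com = np.einsum("fij,i->fj", all_paths, masses) / masses.sum()
        paths = paths - com[:, None, :]

    n_part = paths.shape[1]
    msd_all = np.empty((n_part, n_lag + 1))
    for i in range(n_part):
        msd_all[i] = _msd_fft_single(paths[:, i, :])[: n_lag + 1]
    msd = msd_all.mean(axis=0)
    msd[0] = 0.0
    stderr = (msd_all.std(axis=0, ddof=1) / np.sqrt(n_part)
              if n_part > 1 else np.zeros(n_lag + 1))
    return MSDResult(np.arange(n_lag + 1) * dt, msd, stderr, n_part, com_removal)


def fit_diffusion(msd: MSDResult,
                  window: Tuple[float, float] = (11.0, 50.0)) -> DiffusionEstimate:
    """OLS fit of MSD vs lag on a window; D = slope/4, reported in μm²/s.

    The intercept is left free (a caged short-time transient shifts the
    linear regime upward); it is reported but plays no role in D.
    """
    t_min, t_max = window
    mask = (msd.lag_times >= t_min) & (msd.lag_times <= t_max)
    if mask.sum() < 3:
        raise DataError(f"fewer than 3 MSD points in window {window}")
    res = stats.linregress(msd.lag_times[mask], msd.msd[mask])
    d_A2ns = res.slope / 4.0
    return DiffusionEstimate(
        D=A2_per_ns_to_um2_per_s(d_A2ns),
        stderr=A2_per_ns_to_um2_per_s(res.stderr / 4.0),
        fit_window=(t_min, t_max),
        r_squared=float(res.rvalue ** 2),
        intercept=float(res.intercept),
    )


def diffusion_uncertainty(traj: Trajectory, sel: Optional[Selection] = None,
                          n_partitions: int = 8,
                          by_leaflet: bool = False,
                          partition_axis: str = "time",
                          window: Tuple[float, float] = (11.0, 50.0),
                          com_removal: bool = True) -> DiffusionEstimate:
    """Diffusion estimate with a partition-based standard error.

    ``partition_axis='time'`` splits the trajectory into contiguous blocks
    (each must still cover the fit window); ``'particles'`` splits the
    selected particles into groups.  With ``by_leaflet`` the upper and lower
    leaflets are fitted separately and pooled with the partitions.  The
    estimate is the mean of the per-partition D values, the stderr their
    sample SD divided by √n.
    """
    fits = []
    if by_leaflet:
        groups = []
        for leaf in (Leaflet.UPPER, Leaflet.LOWER):
            s = Selection(
                species=sel.species if sel else None,
                role=sel.role if sel else "P",
                leaflet=leaf)
            if len(select(traj, s, 0)):
                groups.append(s)
    else:
        groups = [sel]

    for g in groups:
        if partition_axis == "time":
            frames = np.arange(traj.n_frames)
            for block in np.array_split(frames, n_partitions):
                sub = Trajectory(traj.particles, traj.coords[block],
                                 traj.times[block], traj.box[block], traj.periodic)
                span = sub.times[-1] - sub.times[0]
                if span < window[1]:
                    scale = span / (traj.times[-1] - traj.times[0])
                    raise DataError(
                        f"partition of {span:.3g} ns cannot cover the fit window "
                        f"{window}; rescale the window, e.g. to "
                        f"({window[0] * scale:.3g}, {window[1] * scale:.3g}) ns")
                msd = compute_msd(sub, g, max_lag=window[1], com_removal=com_removal)
                fits.append(fit_diffusion(msd, window).D)
        elif partition_axis == "particles":
            idx = (np.arange(traj.n_particles) if g is None
                   else select(traj, g, 0))
            for part in np.array_split(idx, n_partitions):
                if len(part) == 0:
                    continue
                ids = [traj.particles[i].id for i in part]
                s = Selection(predicate=lambda p, ids=set(ids): p.id in ids)
                msd = compute_msd(traj, s, max_lag=window[1], com_removal=com_removal)
                fits.append(fit_diffusion(msd, window).D)
        else:
            raise ValueError("partition_axis must be 'time' or 'particles'")

    fits = np.array(fits)
    stderr = float(fits.std(ddof=1) / np.sqrt(len(fits))) if len(fits) > 1 else 0.0
    return DiffusionEstimate(float(fits.mean()), stderr, window, np.nan)


def hydrodynamic_correction(d_labeled: float, drag_fraction: float = 0.20) -> float:
    """Correct a dye-labeled diffusion coefficient for the fluorophore's drag.

    A tracer slowed by a fraction f relative to the unlabeled lipid implies
    D_unlabeled = D_labeled × (1 + f).
    """
    if not (0.0 <= drag_fraction < 1.0):
        raise ValueError("drag_fraction must lie in [0, 1)")
    return d_labeled * (1.0 + drag_fraction)
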
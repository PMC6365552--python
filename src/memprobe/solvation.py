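"""Water density, water dipole and electrostatic-potential profiles.

All profiles are z-resolved with respect to a configurable origin — by
default the instantaneous mean z of the upper-leaflet phosphates, so that
positive distances point into bulk water and negative distances into the
bilayer.  The electrostatic potential comes from double cumulative
integration of the (frame-averaged) charge density, with φ = 0 and
dφ/dz = 0 imposed in bulk water; the 2D map applies the same 1D
integration column by column, which treats the bilayer as a stack of
quasi-independent slabs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core_io import (
    DataError, Leaflet, ROLE_O_W, ROLE_P, Selection, Species, Trajectory,
    logger, minimum_image, select,
)
from .units import DEBYE_PER_E_ANGSTROM, E_OVER_EPS0_ANGSTROM_V

DEFAULT_BULK_BAND = (22.0, 28.0)   # Å from the P plane


@dataclass
class ProfileResult:
    axis: str                      # "z_from_P" | "z_from_center" | "z_absolute"
    bin_centers: np.ndarray        # Å
    values: np.ndarray
    units: str
    normalization: str             # "bulk" | "none"
    restriction: Optional[Selection] = None


@dataclass
class PotentialMap2D:
    x_bins: np.ndarray             # Å, centers
    z_bins: np.ndarray             # Å, centers
    phi: np.ndarray                # V, shape (n_x, n_z)
    reference: str = "phi=0 in bulk water"

    def column(self, x: float) -> np.ndarray:
        """1D potential profile of the column nearest lateral position x."""
        return self.phi[int(np.argmin(np.abs(self.x_bins - x)))]


def _origin_per_frame(traj: Trajectory, origin) -> np.ndarray:
    """Per-frame z origin: a float, a callable, or 'P_upper'/'P_lower'/'center'."""
    if callable(origin):
        return np.array([float(origin(traj, fi)) for fi in range(traj.n_frames)])
    if isinstance(origin, str):
        if origin == "center":
            p_idx = traj.indices_where(lambda p: p.role == ROLE_P)
            return traj.coords[:, p_idx, 2].mean(axis=1)
        leaf = {"P_upper": Leaflet.UPPER, "P_lower": Leaflet.LOWER}[origin]
        idx = traj.indices_where(lambda p: p.role == ROLE_P and p.leaflet == leaf)
        if len(idx) == 0:
            raise DataError(f"origin {origin!r} needs labelled phosphates")
        return traj.coords[:, idx, 2].mean(axis=1)
    return np.full(traj.n_frames, float(origin))


def compute_density_profile(traj: Trajectory,
                            water_sel: Optional[Selection] = None,
                            origin="P_upper",
                            z_range: Tuple[float, float] = (-20.0, 20.0),
                            dz: float = 0.5,
                            cylinder=None,
                            bulk_band: Tuple[float, float] = DEFAULT_BULK_BAND,
                            ) -> ProfileResult:
    """Water (oxygen) number density vs signed distance from the P plane.

    The profile is normalized to the bulk density measured from the
    *unrestricted* selection in ``bulk_band``; an optional lateral
    ``cylinder`` (a :class:`memprobe.core_io.Cylinder`) restricts the counts
    to a minimum-image disc about a per-frame reference center, with the
    bin volume reduced accordingly.
    """
    if water_sel is None:
        water_sel = Selection(role=ROLE_O_W)
    edges = np.arange(z_range[0], z_range[1] + dz / 2, dz)
    centers = 0.5 * (edges[:-1] + edges[1:])
    origins = _origin_per_frame(traj, origin)

    counts = np.zeros(len(centers))
    bulk_count = 0.0
    bulk_volume = 0.0
    cyl_area = None
    for fi in range(traj.n_frames):
        idx = select(traj, water_sel, fi)
        z_rel = traj.coords[fi, idx, 2] - origins[fi]
        box = traj.box[fi]
        in_bulk = (z_rel >= bulk_band[0]) & (z_rel <= bulk_band[1])
        bulk_count += in_bulk.sum()
        bulk_volume += box[0] * box[1] * (bulk_band[1] - bulk_band[0])
        if cylinder is not None:
            center = cylinder.resolve_center(traj, fi)
            d = traj.coords[fi, idx, :2] - center
            if traj.periodic:
                d = minimum_image(d, box[:2])
            inside = np.einsum("ij,ij->i", d, d) <= cylinder.radius ** 2
            z_rel = z_rel[inside]
            cyl_area = np.pi * cylinder.radius ** 2
        counts += np.histogram(z_rel, bins=edges)[0]

    if bulk_count == 0:
        raise DataError("no particles in the bulk normalization band")
    bulk_density = bulk_count / bulk_volume
    area = cyl_area if cylinder is not None else float(
        (traj.box[:, 0] * traj.box[:, 1]).mean())
    density = counts / (traj.n_frames * area * dz)
    return ProfileResult("z_from_P" if isinstance(origin, str) and origin != "center"
                         else "z_from_center",
                         centers, density / bulk_density, "bulk-normalized",
                         "bulk", cylinder)


def compute_dipole_profile(traj: Trajectory,
                           water_sel: Optional[Selection] = None,
                           origin="P_upper",
                           z_range: Tuple[float, float] = (-20.0, 20.0),
                           dz: float = 0.5) -> ProfileResult:
    """Mean z-component of the molecular water dipole per z-bin, in Debye.

    The molecular dipole is μ = Σᵢ qᵢ (rᵢ − r_O) over each water molecule's
    sites; molecules are grouped by their lipid_id and binned by the oxygen
    position.
    """
    o_idx = traj.indices_where(
        lambda p: p.species == Species.WATER and p.role == ROLE_O_W)
    if len(o_idx) == 0:
        raise DataError("no water oxygens present")
    h_by_mol = {}
    for i, p in enumerate(traj.particles):
        if p.species == Species.WATER and p.role != ROLE_O_W:
            h_by_mol.setdefault(p.lipid_id, []).append(i)
    if not h_by_mol:
        raise DataError("water molecules lack hydrogen sites")
    h_idx = np.array([sorted(h_by_mol[traj.particles[i].lipid_id]) for i in o_idx])
    if h_idx.shape[1] != 2:
        raise DataError("expected exactly 2 H per water molecule")
    q_h = np.array([[traj.particles[j].charge for j in row] for row in h_idx])

    edges = np.arange(z_range[0], z_range[1] + dz / 2, dz)
    centers = 0.5 * (edges[:-1] + edges[1:])
    origins = _origin_per_frame(traj, origin)
    sums = np.zeros(len(centers))
    counts = np.zeros(len(centers))
    for fi in range(traj.n_frames):
        o_pos = traj.coords[fi, o_idx]
        mu_z = (q_h * (traj.coords[fi, h_idx][:, :, 2] - o_pos[:, 2:3])).sum(axis=1)
        z_rel = o_pos[:, 2] - origins[fi]
        which = np.digitize(z_rel, edges) - 1
        ok = (which >= 0) & (which < len(centers))
        np.add.at(sums, which[ok], mu_z[ok])
        np.add.at(counts, which[ok], 1.0)
    with np.errstate(invalid="ignore"):
        mean_mu = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return ProfileResult("z_from_P" if isinstance(origin, str) and origin != "center"
                         else "z_from_center",
                         centers, mean_mu * DEBYE_PER_E_ANGSTROM, "Debye", "none")


# ---------------------------------------------------------------------------
# Electrostatics
# ---------------------------------------------------------------------------

def _integrate_poisson(rho: np.ndarray, z: np.ndarray,
                       bulk_index: int) -> np.ndarray:
    """φ(z) from ρ(z) (e/Å³) by double integration; φ = dφ/dz = 0 at bulk_index."""
    e_field = cumulative_trapezoid(rho, z, initial=0.0)          # ∝ dφ/dz
    e_field -= e_field[bulk_index]
    phi = -cumulative_trapezoid(e_field, z, initial=0.0)
    phi -= phi[bulk_index]
    return phi * E_OVER_EPS0_ANGSTROM_V


def compute_potential_profile(traj: Trajectory, origin="center",
                              dz: float = 0.5,
                              bulk_z: Optional[float] = None) -> ProfileResult:
    """Electrostatic potential φ(z) across the membrane, in volts.

    All species' point charges are binned into a z-histogram averaged over
    frames, converted to a charge density and integrated twice
    (φ'' = −ρ/ε0), with φ and the field zeroed at ``bulk_z`` (default: the
    top of the box, assumed bulk water).  A non-neutral system is reported
    with a warning — the potential then acquires a tilt — but the profile
    is still returned.
    """
    charges = traj.charges
    if np.abs(charges.sum()) > 1e-6:
        logger.warning("system net charge %.3g e: potential will be tilted",
                       charges.sum())
    origins = _origin_per_frame(traj, origin)
    lz = traj.box[:, 2].min()
    z_lo = -origins.max()
    z_hi = lz - origins.min()
    edges = np.arange(z_lo, z_hi + dz / 2, dz)
    centers = 0.5 * (edges[:-1] + edges[1:])

    hist = np.zeros(len(centers))
    for fi in range(traj.n_frames):
        z_rel = traj.coords[fi, :, 2] - origins[fi]
        hist += np.histogram(z_rel, bins=edges, weights=charges)[0]
    area = float((traj.box[:, 0] * traj.box[:, 1]).mean())
    rho = hist / (traj.n_frames * area * dz)                     # e/Å³

    bulk_index = (len(centers) - 1 if bulk_z is None
                  else int(np.argmin(np.abs(centers - bulk_z))))
    phi = _integrate_poisson(rho, centers, bulk_index)
    axis = "z_from_center" if origin == "center" else "z_from_P"
    return ProfileResult(axis, centers, phi, "V", "none")


def compute_potential_map2d(traj: Trajectory, dx: float = 2.0, dz: float = 0.5,
                            normal_line_x: Optional[float] = None,
                            ) -> Union[PotentialMap2D, Tuple[PotentialMap2D, np.ndarray]]:
    """2D (x, z) electrostatic potential map, averaged over y and frames.

    The charge density is binned on an (x, z) grid and each x-column is
    integrated with the same 1D Poisson scheme as the 1D profile (boundary
    in the topmost z-bin) — a slab approximation, not a full 2D Poisson
    solve.  If ``normal_line_x`` is given the nearest column is also
    returned as a 1D normal-line profile.
    """
    box = traj.box[0]
    if dx > box[0] or dz > box[2]:
        raise DataError("bins coarser than the box")
    x_edges = np.arange(0.0, box[0] + dx / 2, dx)
    z_edges = np.arange(0.0, box[2] + dz / 2, dz)
    x_centers = 0.5 * (x_edges[:-1] + x_edges[1:])
    z_centers = 0.5 * (z_edges[:-1] + z_edges[1:])
    charges = traj.charges

    hist = np.zeros((len(x_centers), len(z_centers)))
    for fi in range(traj.n_frames):
        hist += np.histogram2d(
            np.mod(traj.coords[fi, :, 0], box[0]), traj.coords[fi, :, 2],
            bins=(x_edges, z_edges), weights=charges)[0]
    rho = hist / (traj.n_frames * dx * box[1] * dz)              # e/Å³

    phi = np.empty_like(rho)
    bulk_index = len(z_centers) - 1
    for i in range(len(x_centers)):
        phi[i] = _integrate_poisson(rho[i], z_centers, bulk_index)
    pot_map = PotentialMap2D(x_centers, z_centers, phi)
    if normal_line_x is not None:
        return pot_map, pot_map.column(normal_line_x)
    return pot_map
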
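"""Synthetic bilayers, water slabs, ion fields and FCS traces with known truth.

Everything downstream of the generators is exercised against ground truth
that is stored next to the generated data, so parameter recovery — not
resemblance to any particular force field — is the test.  The default
parameter set mirrors a fluid DOPC bilayer at room temperature carrying a
2% mole fraction of a Rhodamine-B-labelled lipid (RHB): 200 lipids per
leaflet in a ~117 Å box, a 38.6 Å phosphate–phosphate thickness, and
lateral diffusion of 8.4 μm²/s (DOPC) and 6.7 μm²/s (RHB).

Design notes
------------
* Lipids are point tracers for dynamics; acyl-chain CH vectors are attached
  statistical objects (cone construction reproducing a target order
  parameter) rather than mechanically coupled degrees of freedom.
* The optional cage model (harmonically tethered walker whose tether itself
  diffuses) produces the sub-linear short-lag MSD seen in bilayers without
  claiming a particular molecular mechanism; it is off by default.
* Water/ion configurations are resampled independently every frame: they
  model the equilibrium ensemble only, which is all the z-profile and
  coordination analyses consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .core_io import (
    DataError, Leaflet, Particle, ROLE_C, ROLE_H, ROLE_H_W, ROLE_ION,
    ROLE_O_W, ROLE_P, Species, Trajectory,
)
from .units import um2_per_s_to_A2_per_ns

#: simple 3-point water geometry (rigid, TIP3P-like)
WATER_OH_BOND = 0.9572          # Å
WATER_HOH_ANGLE = 104.52        # degrees
DEFAULT_Q_WATER_H = 0.417       # e; O carries -2q


class ParameterError(ValueError):
    """Raised for physically invalid generator parameters."""


@dataclass
class WaterSpec:
    """Water/ion slab parameters.

    ``bulk_density`` is the oxygen number density far from the membrane
    (0.0334 Å⁻³ for liquid water; scaled-down values keep tests cheap).
    ``enhancement`` adds a localized multiplicative excess of amplitude
    ``amplitude`` over the base profile, inside ``z_range`` (Å relative to
    the upper phosphate plane, negative toward the bilayer center) and a
    lateral cylinder of ``radius`` around ``lateral_center``.
    """

    bulk_density: float = 0.0334          # Å^-3
    interface_width: float = 4.0          # Å
    enhancement: Optional[dict] = None    # {amplitude, z_range, lateral_center, radius}
    q_water_h: float = DEFAULT_Q_WATER_H


@dataclass
class SyntheticSpec:
    """Complete ground-truth parameter set for a generated bilayer system."""

    n_lipids_per_leaflet: int = 200
    frac_rhb: float = 0.02
    box_xy: float = 116.79                # Å
    box_z: float = 100.0                  # Å; leaves ~30 Å of water beyond each P plane
    thickness: float = 38.6               # Å (target P–P distance)
    z_jitter: float = 1.0                 # Å, per lipid per frame
    D_by_species: Dict[str, float] = field(
        default_factory=lambda: {"DOPC": 8.4, "RHB": 6.7})  # μm²/s
    cage: Optional[dict] = None           # {trap_strength (1/ns), cage_D (μm²/s)}
    aggregate_rhb: bool = False           # RHB lipids co-move as one rigid cluster
    scd_profile: Optional[Dict[str, Sequence[float]]] = None  # chain -> per-carbon S_CD
    water: Optional[WaterSpec] = None
    dipole_bias: Optional[Dict[Tuple[float, float], float]] = None  # z-band -> mean cosθ
    ion_density: float = 0.0              # Å^-3
    n_frames: int = 1001
    dt: float = 0.1                       # ns
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_rhb <= 1.0):
            raise ParameterError("frac_rhb must lie in [0, 1]")
        if self.thickness <= 0:
            raise ParameterError("thickness must be positive")
        if any(d < 0 for d in self.D_by_species.values()):
            raise ParameterError("diffusion coefficients must be >= 0")
        if self.ion_density < 0:
            raise ParameterError("ion_density must be >= 0")
        if self.z_jitter < 0:
            raise ParameterError("z_jitter must be >= 0")
        if self.n_lipids_per_leaflet < 1 or self.n_frames < 1:
            raise ParameterError("counts must be positive")
        if self.dipole_bias is not None:
            for band, b in self.dipole_bias.items():
                if abs(b) > 1.0 / 3.0 + 1e-12:
                    raise ParameterError(
                        f"dipole bias {b} in band {band} exceeds 1/3; the linear "
                        "orientation density cannot represent it")


@dataclass
class GroundTruth:
    """Generator parameters plus per-lipid labels, stored with the data."""

    spec: SyntheticSpec
    lipid_species: Dict[int, str] = field(default_factory=dict)
    lipid_leaflet: Dict[int, str] = field(default_factory=dict)
    cluster_members: Sequence[int] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["spec"]["dipole_bias"] = (
            None if self.spec.dipole_bias is None
            else {f"{a},{b}": v for (a, b), v in self.spec.dipole_bias.items()})
        return json.dumps(d, indent=2, default=str)


# ---------------------------------------------------------------------------
# Bilayer generator
# ---------------------------------------------------------------------------

def _brownian_paths(rng, n: int, n_frames: int, sigma_step: float,
                    box: float) -> np.ndarray:
    """Independent 2D Brownian walks, wrapped into [0, box). (F, n, 2)."""
    start = rng.uniform(0.0, box, size=(1, n, 2))
    if n_frames == 1 or sigma_step == 0.0:
        steps = np.zeros((n_frames - 1, n, 2))
    else:
        steps = rng.normal(0.0, sigma_step, size=(n_frames - 1, n, 2))
    paths = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    return np.mod(paths, box)


def _caged_paths(rng, n: int, n_frames: int, dt: float, d_local_A2ns: float,
                 trap_strength: float, cage_d_A2ns: float, box: float) -> np.ndarray:
    """Harmonically tethered walkers with a diffusing tether.

    The displacement u from the cage center relaxes as an OU process with
    rate ``trap_strength`` (1/ns) and stationary variance D_local/k per
    axis, while the cage center performs free Brownian motion with
    ``cage_d_A2ns``; the long-lag MSD slope is set by the cage, the short
    lag is sub-linear.
    """
    k = trap_strength
    a = np.exp(-k * dt)
    var_stat = d_local_A2ns / k
    cage = _brownian_paths(rng, n, n_frames, np.sqrt(2.0 * cage_d_A2ns * dt), box)
    u = rng.normal(0.0, np.sqrt(var_stat), size=(n, 2))
    out = np.empty((n_frames, n, 2))
    out[0] = u
    for t in range(1, n_frames):
        u = a * u + rng.normal(0.0, np.sqrt(var_stat * (1 - a * a)), size=(n, 2))
        out[t] = u
    return np.mod(cage + out, box)


def _cone_angle(s: float) -> float:
    """Polar angle Θ with ½(3cos²Θ−1) = s (cone construction)."""
    if not (-0.5 <= s <= 1.0):
        raise ParameterError(f"order parameter target {s} outside [-0.5, 1]")
    return float(np.arccos(np.sqrt((2.0 * s + 1.0) / 3.0)))


def gen_bilayer(spec: SyntheticSpec) -> Tuple[Trajectory, GroundTruth]:
    """Generate a two-leaflet bilayer trajectory with known ground truth.

    Phosphates sit at z = ±thickness/2 with per-frame Gaussian jitter;
    lateral positions evolve as independent per-species 2D Brownian walks
    (optionally caged, optionally with all RHB in the upper leaflet rigidly
    co-moving to emulate a dye aggregate).  If ``scd_profile`` is given,
    each lipid carries one C and one H particle per chain carbon whose CH
    unit vector is drawn on the cone reproducing the target S_CD, azimuth
    uniform and resampled every frame.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_leaf = spec.n_lipids_per_leaflet
    n_lipids = 2 * n_leaf
    n_rhb_per_leaf = int(round(spec.frac_rhb * n_leaf))

    lipid_species, lipid_leaflet = {}, {}
    for lid in range(n_lipids):
        leaflet = "upper" if lid < n_leaf else "lower"
        within = lid if lid < n_leaf else lid - n_leaf
        sp = "RHB" if within < n_rhb_per_leaf else "DOPC"
        lipid_species[lid] = sp
        lipid_leaflet[lid] = leaflet

    d_A2ns = {s: um2_per_s_to_A2_per_ns(v) for s, v in spec.D_by_species.items()}
    lateral = np.empty((spec.n_frames, n_lipids, 2))
    cluster_members: list = []

    for sp in sorted({*lipid_species.values()}):
        ids = np.array([lid for lid in range(n_lipids) if lipid_species[lid] == sp])
        d = d_A2ns.get(sp, 0.0)
        if sp == "RHB" and spec.aggregate_rhb:
            upper = np.array([lid for lid in ids if lipid_leaflet[lid] == "upper"])
            lower = np.array([lid for lid in ids if lipid_leaflet[lid] != "upper"])
            if len(upper):
                # one shared Brownian path; members keep fixed offsets
                center = _brownian_paths(rng, 1, spec.n_frames,
                                         np.sqrt(2.0 * d * spec.dt), spec.box_xy)
                offsets = rng.uniform(-8.0, 8.0, size=(1, len(upper), 2))
                lateral[:, upper, :] = np.mod(center + offsets, spec.box_xy)
                cluster_members = [int(l) for l in upper]
            if len(lower):
                lateral[:, lower, :] = _brownian_paths(
                    rng, len(lower), spec.n_frames,
                    np.sqrt(2.0 * d * spec.dt), spec.box_xy)
            continue
        if spec.cage is not None:
            lateral[:, ids, :] = _caged_paths(
                rng, len(ids), spec.n_frames, spec.dt, d,
                spec.cage["trap_strength"],
                um2_per_s_to_A2_per_ns(spec.cage["cage_D"]), spec.box_xy)
        else:
            lateral[:, ids, :] = _brownian_paths(
                rng, len(ids), spec.n_frames,
                np.sqrt(2.0 * d * spec.dt), spec.box_xy)

    z_center = spec.box_z / 2.0
    z_sign = np.array([+1.0 if lipid_leaflet[l] == "upper" else -1.0
                       for l in range(n_lipids)])
    z_base = z_center + z_sign * spec.thickness / 2.0
    z = z_base[None, :] + rng.normal(0.0, spec.z_jitter,
                                     size=(spec.n_frames, n_lipids))

    particles = [
        Particle(id=lid, species=Species(lipid_species[lid]), role=ROLE_P,
                 lipid_id=lid, leaflet=Leaflet(lipid_leaflet[lid]), mass=94.97)
        for lid in range(n_lipids)
    ]
    coords_parts = [np.concatenate([lateral, z[:, :, None]], axis=2)]

    if spec.scd_profile is not None:
        ch_coords, ch_particles = _gen_chain_vectors(
            rng, spec, lateral, z, lipid_species, lipid_leaflet, len(particles))
        particles.extend(ch_particles)
        coords_parts.append(ch_coords)

    coords = np.concatenate(coords_parts, axis=1)
    times = np.arange(spec.n_frames) * spec.dt
    traj = Trajectory(particles, coords,
                      times, np.array([spec.box_xy, spec.box_xy, spec.box_z]))
    truth = GroundTruth(spec, lipid_species, lipid_leaflet, cluster_members)
    return traj, truth


def _gen_chain_vectors(rng, spec, lateral, z, lipid_species, lipid_leaflet,
                       next_id):
    """C/H particle pairs whose CH vectors realise the target S_CD profile."""
    bond = 1.09  # Å
    particles, blocks = [], []
    n_frames, n_lipids = lateral.shape[0], lateral.shape[1]
    pid = next_id
    for chain, targets in spec.scd_profile.items():
        thetas = np.array([_cone_angle(s) for s in targets])
        for k, theta in enumerate(thetas, start=1):
            phi = rng.uniform(0.0, 2.0 * np.pi, size=(n_frames, n_lipids))
            # CH unit vector on the cone about the membrane normal
            u = np.stack([np.sin(theta) * np.cos(phi),
                          np.sin(theta) * np.sin(phi),
                          np.cos(theta) * np.ones_like(phi)], axis=2)
            c_pos = np.concatenate(
                [lateral, (z - 1.2 * k * np.sign(z - z.mean()))[:, :, None]], axis=2)
            h_pos = c_pos + bond * u
            blocks.append(c_pos)
            blocks.append(h_pos)
            for lid in range(n_lipids):
                particles.append(Particle(
                    id=pid + 2 * lid, species=Species(lipid_species[lid]),
                    role=ROLE_C, lipid_id=lid,
                    leaflet=Leaflet(lipid_leaflet[lid]),
                    mass=12.011, chain=chain, carbon=k))
                particles.append(Particle(
                    id=pid + 2 * lid + 1, species=Species(lipid_species[lid]),
                    role=ROLE_H, lipid_id=lid,
                    leaflet=Leaflet(lipid_leaflet[lid]),
                    mass=1.008, chain=chain, carbon=k))
            pid += 2 * n_lipids
    # interleave C/H per (chain, carbon, lipid) to match particle order
    out = np.empty((n_frames, len(particles), 3))
    col = 0
    for b in range(0, len(blocks), 2):
        c_pos, h_pos = blocks[b], blocks[b + 1]
        n_lip = c_pos.shape[1]
        out[:, col:col + 2 * n_lip:2, :] = c_pos
        out[:, col + 1:col + 2 * n_lip:2, :] = h_pos
        col += 2 * n_lip
    return out, particles


# ---------------------------------------------------------------------------
# Water slab + ions
# ---------------------------------------------------------------------------

def _base_water_profile(z_grid: np.ndarray, z_center: float, thickness: float,
                        water: WaterSpec) -> np.ndarray:
    """Oxygen density vs absolute z: bulk outside, sigmoidal interfacial drop."""
    dist = np.abs(z_grid - z_center) - thickness / 2.0
    return water.bulk_density / (1.0 + np.exp(-dist / water.interface_width))


def _expected_count(z_grid, density, area) -> int:
    dz = z_grid[1] - z_grid[0]
    return int(round(float((density * area * dz).sum())))


def _sample_from_profile(rng, z_grid, density, n):
    """Sample ``n`` z positions from a 1D density profile (inverse CDF)."""
    if n == 0:
        return np.empty(0)
    dz = z_grid[1] - z_grid[0]
    cdf = np.cumsum(density)
    cdf = cdf / cdf[-1]
    idx = np.searchsorted(cdf, rng.uniform(size=n))
    return z_grid[idx] + rng.uniform(-dz / 2, dz / 2, size=n)


def _dipole_cos_theta(rng, n, bias):
    """Sample cosθ from the linear density (1 + 3b·c)/2 on [-1, 1] (mean b)."""
    a = 3.0 * bias
    u = rng.uniform(size=n)
    if abs(a) < 1e-12:
        return 2.0 * u - 1.0
    # invert CDF of (1 + a c)/2: quadratic in c
    return (-1.0 + np.sqrt((1.0 - a) ** 2 + 4.0 * a * u)) / a


def gen_water_slab(spec: SyntheticSpec, traj: Trajectory) -> Trajectory:
    """Append water molecules and ions to a generated bilayer trajectory.

    Oxygen z positions follow the base sigmoidal profile plus the optional
    localized enhancement; each water gets two H at rigid geometry with the
    molecular dipole's polar angle sampled to match ``dipole_bias`` per
    z-band (z measured from the upper phosphate plane, negative inward).
    Ions are placed uniformly at ``ion_density``.  Molecule counts are fixed
    at the profile's expectation (a canonical rather than grand-canonical
    sample, keeping the particle count constant across frames); positions
    are resampled independently each frame — an equilibrium ensemble with
    no water dynamics.
    """
    if spec.water is None:
        raise ParameterError("spec.water must be set")
    water = spec.water
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 7)))
    box = traj.box[0]
    z_center = spec.box_z / 2.0
    z_upper_p = z_center + spec.thickness / 2.0
    z_grid = np.arange(0.25, spec.box_z, 0.5)
    base = _base_water_profile(z_grid, z_center, spec.thickness, water)

    enh = water.enhancement
    if enh is not None:
        r = float(enh["radius"])
        cx, cy = enh["lateral_center"]
        if not (0 <= cx <= box[0] and 0 <= cy <= box[1]) or r > min(box[:2]) / 2:
            raise ParameterError("enhancement cylinder outside the box")
        z_lo = z_upper_p + min(enh["z_range"])
        z_hi = z_upper_p + max(enh["z_range"])
        enh_profile = float(enh["amplitude"]) * base * (
            (z_grid >= z_lo) & (z_grid <= z_hi))

    qh = water.q_water_h
    half = np.deg2rad(WATER_HOH_ANGLE / 2.0)
    area = box[0] * box[1]

    dz_grid = z_grid[1] - z_grid[0]
    w_base = float((base * area * dz_grid).sum())
    w_enh = (float((enh_profile * np.pi * r * r * dz_grid).sum())
             if enh is not None else 0.0)
    n_w = int(round(w_base + w_enh))
    frac_enh = w_enh / (w_base + w_enh)
    n_ion = int(round(spec.ion_density * area * box[2]))

    frames_new = []
    for fi in range(traj.n_frames):
        # fixed total count; per-frame binomial split between the base slab
        # and the enhancement component keeps the expected occupancies exact
        n_enh = rng.binomial(n_w, frac_enh) if frac_enh > 0 else 0
        n_base = n_w - n_enh
        z_o = _sample_from_profile(rng, z_grid, base, n_base)
        xy_o = rng.uniform(0.0, box[:2], size=(n_base, 2))
        if enh is not None:
            z_e = _sample_from_profile(rng, z_grid, enh_profile, n_enh)
            rr = r * np.sqrt(rng.uniform(size=n_enh))
            ang = rng.uniform(0.0, 2 * np.pi, size=n_enh)
            xy_e = np.mod(
                np.stack([cx + rr * np.cos(ang), cy + rr * np.sin(ang)], axis=1),
                box[:2])
            z_o = np.concatenate([z_o, z_e])
            xy_o = np.concatenate([xy_o, xy_e]) if n_enh else xy_o

        # dipole orientations per z-band
        cos_t = 2.0 * rng.uniform(size=n_w) - 1.0
        if spec.dipole_bias:
            z_rel = z_o - z_upper_p
            for (lo, hi), b in spec.dipole_bias.items():
                m = (z_rel >= min(lo, hi)) & (z_rel <= max(lo, hi))
                cos_t[m] = _dipole_cos_theta(rng, int(m.sum()), b)
        sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, 1.0))
        phi = rng.uniform(0.0, 2 * np.pi, size=n_w)
        d_hat = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
        # perpendicular unit vector spanning the HOH plane, random about d
        tmp = rng.normal(size=(n_w, 3))
        tmp -= d_hat * np.einsum("ij,ij->i", tmp, d_hat)[:, None]
        tmp /= np.linalg.norm(tmp, axis=1, keepdims=True)
        o_pos = np.concatenate([xy_o, z_o[:, None]], axis=1)
        h1 = o_pos + WATER_OH_BOND * (np.cos(half) * d_hat + np.sin(half) * tmp)
        h2 = o_pos + WATER_OH_BOND * (np.cos(half) * d_hat - np.sin(half) * tmp)
        ion_pos = rng.uniform(0.0, 1.0, size=(n_ion, 3)) * box[None, :]
        frames_new.append((o_pos, h1, h2, ion_pos))

    n_old = traj.n_particles
    particles = list(traj.particles)
    next_lid = 1 + max((p.lipid_id or 0) for p in particles)
    next_id = 1 + max(p.id for p in particles)
    for w in range(n_w):
        lid = next_lid + w
        particles.append(Particle(next_id, Species.WATER, ROLE_O_W, lid,
                                  charge=-2 * qh, mass=15.999))
        particles.append(Particle(next_id + 1, Species.WATER, ROLE_H_W, lid,
                                  charge=qh, mass=1.008))
        particles.append(Particle(next_id + 2, Species.WATER, ROLE_H_W, lid,
                                  charge=qh, mass=1.008))
        next_id += 3
    next_lid += n_w
    for i in range(n_ion):
        particles.append(Particle(next_id, Species.ION, ROLE_ION, next_lid + i,
                                  charge=1.0, mass=22.99))
        next_id += 1

    coords = np.empty((traj.n_frames, len(particles), 3))
    coords[:, :n_old] = traj.coords
    for fi, (o_pos, h1, h2, ion_pos) in enumerate(frames_new):
        inter = np.stack([o_pos, h1, h2], axis=1).reshape(-1, 3)
        coords[fi, n_old:n_old + 3 * n_w] = inter
        coords[fi, n_old + 3 * n_w:] = ion_pos

    return Trajectory(particles, coords, traj.times, traj.box, traj.periodic)


# ---------------------------------------------------------------------------
# FCS trace generator
# ---------------------------------------------------------------------------

@dataclass
class FCSGroundTruth:
    D: float            # μm²/s
    n_particles: int
    waist_w: float      # μm
    box_size: float     # μm
    brightness: float
    dt: float           # s
    duration: float     # s
    seed: int


def gen_fcs_trace(n_particles: int, D: float, waist_w: float, duration: float,
                  dt: float, brightness: float = 1.0, box_size: float = None,
                  shot_noise: bool = False, seed: int = 0,
                  initial_positions: np.ndarray = None):
    """Simulate an FCS intensity trace from 2D Brownian diffusers.

    Particles diffuse on a periodic plane of edge ``box_size`` (default
    16 w, "much larger than the waist"); the detected intensity is
    F(t) = Σᵢ B·exp(−2 rᵢ²/w²) with rᵢ the minimum-image lateral distance to
    the beam axis at the box center, optionally Poisson shot noise.
    Units: D in μm²/s, waist and box in μm, time in s.

    Returns ``(trace, truth)`` where ``trace`` is a
    :class:`memprobe.fluorescence.FCSTrace`.
    """
    from .fluorescence import FCSTrace

    if min(n_particles, D, waist_w, duration, dt, brightness) < 0 or dt <= 0:
        raise ParameterError("all FCS generator parameters must be positive")
    if box_size is None:
        # the 2D model's 1/τ tail is truncated once particles cross ~half the
        # periodic plane; 40 waists keeps that bias below the fit noise
        box_size = 40.0 * waist_w
    if waist_w >= box_size:
        raise ParameterError("waist must be smaller than the simulation plane")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_steps = int(round(duration / dt))
    sigma = np.sqrt(2.0 * D * dt)
    center = box_size / 2.0
    if initial_positions is not None:
        pos = np.array(initial_positions, dtype=float).reshape(n_particles, 2)
    else:
        pos = rng.uniform(0.0, box_size, size=(n_particles, 2))
    intensity = np.empty(n_steps)

    chunk = max(1, int(2_000_000 // max(n_particles, 1)))
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        steps = rng.normal(0.0, sigma, size=(m, n_particles, 2))
        steps[0] += pos
        paths = np.cumsum(steps, axis=0)
        pos = np.mod(paths[-1], box_size)
        d = np.mod(paths - center, box_size)
        d = np.where(d > box_size / 2, d - box_size, d)
        r2 = np.einsum("tij,tij->ti", d, d)
        intensity[done:done + m] = brightness * np.exp(-2.0 * r2 / waist_w ** 2).sum(axis=1)
        done += m
    if shot_noise:
        intensity = rng.poisson(np.maximum(intensity, 0.0)).astype(float)

    times = np.arange(n_steps) * dt
    truth = FCSGroundTruth(D, n_particles, waist_w, box_size, brightness,
                           dt, duration, seed)
    return FCSTrace(times=times, intensity=intensity, dt=dt), truth
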
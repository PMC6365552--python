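"""Trajectory data model, format readers/writers and the selection engine.

The in-memory container is :class:`Trajectory`: a static topology (a list of
:class:`Particle`) plus a dense ``(n_frames, n_particles, 3)`` coordinate
array, frame times and per-frame box edges.  All coordinates are in Å, times
in ns, charges in elementary charges, masses in amu; readers normalise on
the way in (MDAnalysis stores times in ps).

Supported formats
-----------------
* ``pdb+dcd`` / ``pdb+xtc`` — via MDAnalysis; species/roles are inferred
  from residue and atom names.
* ``frames-csv`` — a dependency-free plain-text dialect used for fixtures:
  per frame, a ``time_ns,Lx,Ly,Lz`` header line, one line with the four
  values, an ``id,x,y,z`` header and one row per particle; frames are
  separated by a blank line.  The topology travels in a companion CSV with
  columns ``id,species,role,lipid_id,leaflet,charge,mass,chain,carbon``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

logger = logging.getLogger("memprobe")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class DataError(ValueError):
    """Raised when well-formed input carries physically inconsistent data."""


class Species(str, Enum):
    DOPC = "DOPC"
    RHB = "RHB"
    WATER = "WATER"
    ION = "ION"


class Leaflet(str, Enum):
    UPPER = "upper"
    LOWER = "lower"
    NONE = "none"


#: canonical role strings; chain carbons additionally carry (chain, carbon)
ROLE_P = "P"
ROLE_C = "C"
ROLE_H = "H"
ROLE_O_W = "O_w"
ROLE_H_W = "H_w"
ROLE_ION = "ion"


@dataclass
class Particle:
    """One particle of the topology.

    ``lipid_id`` groups particles into molecules (lipids and waters alike);
    ``chain``/``carbon`` identify acyl-chain methylene sites (``sn1``/``sn2``,
    1-based carbon index) for order-parameter analysis.
    """

    id: int
    species: Species
    role: str
    lipid_id: Optional[int] = None
    leaflet: Leaflet = Leaflet.NONE
    charge: float = 0.0
    mass: float = 1.0
    chain: Optional[str] = None
    carbon: Optional[int] = None

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        self.leaflet = Leaflet(self.leaflet)
        if not math.isfinite(self.charge):
            raise DataError(f"particle {self.id}: non-finite charge")


@dataclass(frozen=True)
class Frame:
    """Lightweight view of one trajectory frame."""

    time: float          # ns
    box: np.ndarray      # (Lx, Ly, Lz) Å
    coords: np.ndarray   # (n_particles, 3) Å


class Trajectory:
    """Topology + ordered frames.

    Parameters
    ----------
    particles
        Static topology; one entry per particle, order matching ``coords``.
    coords
        ``(n_frames, n_particles, 3)`` array in Å.
    times
        Frame times in ns, strictly increasing.
    box
        Either a single ``(3,)`` box reused for every frame or a
        ``(n_frames, 3)`` array.
    periodic
        Whether minimum-image conventions apply.
    """

    def __init__(
        self,
        particles: Sequence[Particle],
        coords: np.ndarray,
        times: np.ndarray,
        box: np.ndarray,
        periodic: bool = True,
    ) -> None:
        self.particles = list(particles)
        self.coords = np.asarray(coords, dtype=float)
        self.times = np.asarray(times, dtype=float)
        box = np.asarray(box, dtype=float)
        if box.ndim == 1:
            box = np.broadcast_to(box, (len(self.times), 3)).copy()
        self.box = box
        self.periodic = bool(periodic)
        self._validate()

    def _validate(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise DataError("coords must have shape (n_frames, n_particles, 3)")
        if self.coords.shape[1] != len(self.particles):
            raise FormatError(
                f"coordinate count {self.coords.shape[1]} does not match "
                f"topology particle count {len(self.particles)}"
            )
        if self.coords.shape[0] != len(self.times):
            raise DataError("frame count mismatch between coords and times")
        if self.box.shape != (len(self.times), 3):
            raise DataError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise DataError("box edges must be positive")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise DataError("frame times must be strictly increasing")

    # -- basic accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.times[i], self.box[i], self.coords[i])

    def __len__(self) -> int:
        return self.n_frames

    @property
    def charges(self) -> np.ndarray:
        return np.array([p.charge for p in self.particles])

    @property
    def masses(self) -> np.ndarray:
        return np.array([p.mass for p in self.particles])

    def indices_where(self, pred: Callable[[Particle], bool]) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.particles) if pred(p)], dtype=int)

    def with_coords(self, coords: np.ndarray, periodic: Optional[bool] = None) -> "Trajectory":
        return Trajectory(
            self.particles,
            coords,
            self.times,
            self.box,
            self.periodic if periodic is None else periodic,
        )


# ---------------------------------------------------------------------------
# Selection engine
# ---------------------------------------------------------------------------

@dataclass
class Cylinder:
    """Lateral (XY) cylinder restriction.

    ``center`` is a fixed ``(x, y)`` pair, a per-frame callable
    ``f(traj, frame_index) -> (x, y)``, or a :class:`Selection` whose
    centroid in each frame is used as the reference (e.g. a dye cluster).
    Distances honour the minimum-image convention when the trajectory is
    periodic.
    """

    center: Union[Sequence[float], Callable, "Selection"]
    radius: float  # Å

    def resolve_center(self, traj: Trajectory, frame_index: int) -> np.ndarray:
        if isinstance(self.center, Selection):
            idx = select(traj, self.center, frame_index)
            if len(idx) == 0:
                raise DataError("cylinder reference selection is empty")
            return traj.coords[frame_index, idx, :2].mean(axis=0)
        if callable(self.center):
            return np.asarray(self.center(traj, frame_index), dtype=float)
        return np.asarray(self.center, dtype=float)


@dataclass
class Selection:
    """Deterministic predicate over particles plus optional geometry.

    Field filters combine with logical AND; any left as ``None`` is
    ignored.  ``z_range`` and ``cylinder`` are evaluated per frame.
    """

    species: Optional[Union[Species, Iterable[Species]]] = None
    role: Optional[Union[str, Iterable[str]]] = None
    leaflet: Optional[Leaflet] = None
    lipid_ids: Optional[Iterable[int]] = None
    predicate: Optional[Callable[[Particle], bool]] = None
    z_range: Optional[tuple] = None            # (z_min, z_max) Å, absolute
    cylinder: Optional[Cylinder] = None

    def static_mask(self, particles: Sequence[Particle]) -> np.ndarray:
        species = self.species
        if isinstance(species, (Species, str)):
            species = {Species(species)}
        elif species is not None:
            species = {Species(s) for s in species}
        roles = self.role
        if isinstance(roles, str):
            roles = {roles}
        elif roles is not None:
            roles = set(roles)
        lipid_ids = set(self.lipid_ids) if self.lipid_ids is not None else None

        mask = np.ones(len(particles), dtype=bool)
        for i, p in enumerate(particles):
            if species is not None and p.species not in species:
                mask[i] = False
            elif roles is not None and p.role not in roles:
                mask[i] = False
            elif self.leaflet is not None and p.leaflet != Leaflet(self.leaflet):
                mask[i] = False
            elif lipid_ids is not None and p.lipid_id not in lipid_ids:
                mask[i] = False
            elif self.predicate is not None and not self.predicate(p):
                mask[i] = False
        return mask


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement(s) ``d``.

    ``d`` has shape ``(..., k)`` and ``box`` shape ``(k,)``.
    """
    d = np.asarray(d, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def select(traj: Trajectory, selection: Selection, frame_index: int) -> np.ndarray:
    """Indices of particles satisfying ``selection`` in one frame.

    An empty result is not an error (it is logged at DEBUG level).
    """
    if not (0 <= frame_index < traj.n_frames):
        raise IndexError(f"frame index {frame_index} out of range")
    mask = selection.static_mask(traj.particles)
    coords = traj.coords[frame_index]
    box = traj.box[frame_index]
    if selection.z_range is not None:
        z_min, z_max = selection.z_range
        mask &= (coords[:, 2] >= z_min) & (coords[:, 2] <= z_max)
    if selection.cylinder is not None:
        center = selection.cylinder.resolve_center(traj, frame_index)
        d = coords[:, :2] - center
        if traj.periodic:
            d = minimum_image(d, box[:2])
        mask &= np.einsum("ij,ij->i", d, d) <= selection.cylinder.radius ** 2
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        logger.debug("selection matched no particles in frame %d", frame_index)
    return idx


# ---------------------------------------------------------------------------
# Leaflet assignment
# ---------------------------------------------------------------------------

def assign_leaflets(traj: Trajectory, straddle_warn_fraction: float = 0.10) -> Trajectory:
    """Label every lipid upper/lower from its phosphate z relative to the midplane.

    The midplane is the mean z of all phosphate (role ``P``) particles per
    frame; a lipid's leaflet is the sign of its time-averaged offset.  A
    lipid whose instantaneous sign disagrees with its label in more than
    ``straddle_warn_fraction`` of frames triggers a warning — transbilayer
    flip-flop is not modelled.  Labels propagate to all particles sharing
    the lipid_id.  Returns the same trajectory object, relabelled.
    """
    p_idx = traj.indices_where(lambda p: p.role == ROLE_P)
    if len(p_idx) == 0:
        raise DataError("trajectory has no phosphate (role 'P') particles")
    z_p = traj.coords[:, p_idx, 2]                      # (F, nP)
    midplane = z_p.mean(axis=1, keepdims=True)          # (F, 1)
    offset = z_p - midplane
    mean_offset = offset.mean(axis=0)
    labels = [Leaflet.UPPER if m >= 0 else Leaflet.LOWER for m in mean_offset]

    frac_wrong = ((offset >= 0) != (mean_offset >= 0)[None, :]).mean(axis=0)
    by_lipid = {}
    for k, i in enumerate(p_idx):
        lid = traj.particles[i].lipid_id
        by_lipid[lid] = labels[k]
        if frac_wrong[k] > straddle_warn_fraction:
            logger.warning(
                "lipid %s straddles the midplane in %.0f%% of frames; "
                "flip-flop is not modelled", lid, 100 * frac_wrong[k]
            )
    for p in traj.particles:
        if p.lipid_id in by_lipid:
            p.leaflet = Leaflet(by_lipid[p.lipid_id])
    return traj


# ---------------------------------------------------------------------------
# frames-CSV dialect
# ---------------------------------------------------------------------------

_TOPOLOGY_COLUMNS = "id,species,role,lipid_id,leaflet,charge,mass,chain,carbon"


def write_topology_csv(particles: Sequence[Particle], path) -> None:
    lines = [_TOPOLOGY_COLUMNS]
    for p in particles:
        lines.append(
            f"{p.id},{p.species.value},{p.role},"
            f"{'' if p.lipid_id is None else p.lipid_id},{p.leaflet.value},"
            f"{p.charge!r},{p.mass!r},"
            f"{'' if p.chain is None else p.chain},"
            f"{'' if p.carbon is None else p.carbon}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology_csv(path) -> list:
    text = Path(path).read_text().strip().splitlines()
    if not text or text[0].strip() != _TOPOLOGY_COLUMNS:
        raise FormatError(f"{path}: expected topology header '{_TOPOLOGY_COLUMNS}'")
    particles = []
    for line in text[1:]:
        f = line.split(",")
        if len(f) != 9:
            raise FormatError(f"{path}: malformed topology row {line!r}")
        particles.append(
            Particle(
                id=int(f[0]), species=Species(f[1]), role=f[2],
                lipid_id=int(f[3]) if f[3] else None,
                leaflet=Leaflet(f[4]), charge=float(f[5]), mass=float(f[6]),
                chain=f[7] or None, carbon=int(f[8]) if f[8] else None,
            )
        )
    return particles


def _write_frames_csv(traj: Trajectory, path) -> None:
    blocks = []
    for i in range(traj.n_frames):
        rows = ["time_ns,Lx,Ly,Lz",
                f"{float(traj.times[i])!r},{float(traj.box[i,0])!r},"
                f"{float(traj.box[i,1])!r},{float(traj.box[i,2])!r}",
                "id,x,y,z"]
        for j, p in enumerate(traj.particles):
            x, y, z = (float(v) for v in traj.coords[i, j])
            rows.append(f"{p.id},{x!r},{y!r},{z!r}")
        blocks.append("\n".join(rows))
    Path(path).write_text("\n\n".join(blocks) + "\n")


def _read_frames_csv(particles: Sequence[Particle], path) -> Trajectory:
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty frames-CSV file")
    id_to_col = {p.id: k for k, p in enumerate(particles)}
    times, boxes, frames = [], [], []
    for block in text.split("\n\n"):
        lines = block.strip().splitlines()
        if len(lines) < 3 or lines[0].strip() != "time_ns,Lx,Ly,Lz":
            raise FormatError(f"{path}: frame block must start with 'time_ns,Lx,Ly,Lz'")
        t, lx, ly, lz = (float(v) for v in lines[1].split(","))
        if lines[2].strip() != "id,x,y,z":
            raise FormatError(f"{path}: missing 'id,x,y,z' header")
        body = lines[3:]
        if len(body) != len(particles):
            raise FormatError(
                f"{path}: frame has {len(body)} particles, topology has {len(particles)}"
            )
        xyz = np.empty((len(particles), 3))
        for row in body:
            f = row.split(",")
            try:
                col = id_to_col[int(f[0])]
            except KeyError:
                raise FormatError(f"{path}: unknown particle id {f[0]}") from None
            xyz[col] = [float(f[1]), float(f[2]), float(f[3])]
        times.append(t)
        boxes.append([lx, ly, lz])
        frames.append(xyz)
    times = np.array(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise DataError(f"{path}: non-monotonic frame times")
    return Trajectory(list(particles), np.array(frames), times, np.array(boxes))


# ---------------------------------------------------------------------------
# MDAnalysis-backed formats
# ---------------------------------------------------------------------------

_RESNAME_SPECIES = {
    "DOPC": Species.DOPC, "RHB": Species.RHB,
    "TIP3": Species.WATER, "HOH": Species.WATER, "WAT": Species.WATER,
    "SOL": Species.WATER,
    "SOD": Species.ION, "NA": Species.ION, "CLA": Species.ION, "CL": Species.ION,
    "POT": Species.ION, "K": Species.ION,
}


def _role_from_names(species: Species, atom_name: str) -> str:
    n = atom_name.strip().upper()
    if species == Species.WATER:
        return ROLE_O_W if n.startswith("O") else ROLE_H_W
    if species == Species.ION:
        return ROLE_ION
    if n == "P":
        return ROLE_P
    if n.startswith("H"):
        return ROLE_H
    return ROLE_C


def _topology_from_universe(u) -> list:
    particles = []
    for a in u.atoms:
        resname = a.resname.strip().upper()
        species = _RESNAME_SPECIES.get(resname)
        if species is None:
            raise FormatError(f"unknown residue name {a.resname!r}")
        try:
            charge = float(a.charge)
        except Exception:
            charge = 0.0
        try:
            mass = float(a.mass)
        except Exception:
            mass = 1.0
        particles.append(
            Particle(
                id=int(a.ix), species=species,
                role=_role_from_names(species, a.name),
                lipid_id=int(a.resid), charge=charge, mass=mass,
            )
        )
    return particles


def _read_mdanalysis(topology_path, coords_path) -> Trajectory:
    import MDAnalysis as mda

    try:
        u = mda.Universe(str(topology_path), str(coords_path))
    except (ValueError, IOError) as exc:
        raise FormatError(f"cannot pair {topology_path} with {coords_path}: {exc}") from exc
    particles = _topology_from_universe(u)
    coords, times, boxes = [], [], []
    for ts in u.trajectory:
        coords.append(ts.positions.astype(float).copy())
        times.append(float(ts.time) / 1000.0)  # ps -> ns
        boxes.append(np.asarray(ts.dimensions[:3], dtype=float).copy())
    times = np.array(times)
    if len(times) > 1 and np.all(np.diff(times) == 0):
        # some writers do not persist times; fall back to frame index in ns
        times = np.arange(len(times), dtype=float)
    if np.any(np.diff(times) <= 0):
        raise DataError(f"{coords_path}: non-monotonic frame times")
    return Trajectory(particles, np.array(coords), times, np.array(boxes))


def _write_mdanalysis(traj: Trajectory, topology_path, coords_path) -> None:
    import MDAnalysis as mda

    n = traj.n_particles
    resids = np.array(
        [p.lipid_id if p.lipid_id is not None else (i + 1)
         for i, p in enumerate(traj.particles)]
    )
    _, resix = np.unique(resids, return_inverse=True)
    n_res = resix.max() + 1
    u = mda.Universe.empty(
        n, n_residues=n_res, atom_resindex=resix,
        residue_segindex=np.zeros(n_res, dtype=int), trajectory=True,
    )
    names, resnames = [], [""] * n_res
    for i, p in enumerate(traj.particles):
        if p.role == ROLE_P:
            names.append("P")
        elif p.role == ROLE_O_W:
            names.append("OH2")
        elif p.role == ROLE_H_W:
            names.append("H1")
        elif p.role == ROLE_ION:
            names.append("SOD")
        else:
            names.append(f"{p.role}{p.carbon or ''}"[:4] or "X")
        rn = {Species.WATER: "TIP3", Species.ION: "SOD"}.get(p.species, p.species.value)
        resnames[resix[i]] = rn
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.unique(resids))
    u.atoms.positions = traj.coords[0]
    u.dimensions = [*traj.box[0], 90.0, 90.0, 90.0]
    u.atoms.write(str(topology_path))

    with mda.Writer(str(coords_path), n) as w:
        for i in range(traj.n_frames):
            u.atoms.positions = traj.coords[i]
            u.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
            u.trajectory.ts.time = traj.times[i] * 1000.0  # ns -> ps
            u.trajectory.ts.frame = i
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# Public I/O entry points
# ---------------------------------------------------------------------------

_FORMATS = {"frames-csv", "pdb+dcd", "pdb+xtc"}


def read_trajectory(topology_path, coords_path, format: str = "frames-csv") -> Trajectory:
    """Read a trajectory, normalising units to Å and ns.

    For ``frames-csv`` the topology path is the companion topology CSV;
    for ``pdb+dcd``/``pdb+xtc`` it is the PDB file.
    """
    if format not in _FORMATS:
        raise FormatError(f"unsupported format {format!r}; one of {sorted(_FORMATS)}")
    for p in (topology_path, coords_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    if format == "frames-csv":
        return _read_frames_csv(read_topology_csv(topology_path), coords_path)
    return _read_mdanalysis(topology_path, coords_path)


def write_trajectory(traj: Trajectory, topology_path, coords_path,
                     format: str = "frames-csv") -> None:
    """Write a trajectory in one of the supported formats."""
    if format not in _FORMATS:
        raise FormatError(f"unsupported format {format!r}; one of {sorted(_FORMATS)}")
    if format == "frames-csv":
        write_topology_csv(traj.particles, topology_path)
        _write_frames_csv(traj, coords_path)
    else:
        _write_mdanalysis(traj, topology_path, coords_path)
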
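"""Structural observables of a lipid bilayer trajectory.

Area per lipid, phosphate–phosphate thickness, per-leaflet lateral radial
distribution functions, deuterium order parameters S_CD, ion coordination
numbers and dye contact/cluster detection.  Uncertainties of scalar
observables come from standard errors over contiguous frame partitions
(8 by default, matching common bilayer-analysis practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core_io import (
    DataError, Leaflet, ROLE_C, ROLE_H, ROLE_P, Selection, Species,
    Trajectory, logger, minimum_image, select,
)

N_PARTITIONS_DEFAULT = 8


@dataclass
class ScalarObservable:
    name: str
    value: float
    stderr: float
    units: str

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise DataError("stderr must be >= 0")


@dataclass
class RDFResult:
    r_bin_centers: np.ndarray      # Å
    g: np.ndarray
    pair_spec: tuple
    n_frames: int
    leaflet_mode: str              # "per_leaflet_averaged" | "combined"


@dataclass
class OrderParameterProfile:
    chain: str                                  # "sn1" | "sn2"
    carbons: np.ndarray                         # carbon index k
    scd: np.ndarray
    stderr: np.ndarray


@dataclass
class ClusterReport:
    contact_cutoff: float                        # Å
    components: List[List[List[int]]]            # per frame: list of lipid-id lists


def _partition_stderr(per_frame: np.ndarray, n_partitions: int) -> float:
    """SE of the mean over contiguous frame blocks (0 if fewer frames than blocks)."""
    n = len(per_frame)
    if n < n_partitions or n_partitions < 2:
        return 0.0
    blocks = np.array_split(per_frame, n_partitions)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_partitions))


def compute_area_per_lipid(traj: Trajectory, leaflet: str = "upper",
                           n_partitions: int = N_PARTITIONS_DEFAULT) -> ScalarObservable:
    """Mean lateral box area divided by the number of lipids in one leaflet."""
    leaflet = Leaflet(leaflet)
    lipids = {p.lipid_id for p in traj.particles
              if p.role == ROLE_P and p.leaflet == leaflet}
    if not lipids:
        raise DataError(f"no lipids in {leaflet.value} leaflet")
    per_frame = traj.box[:, 0] * traj.box[:, 1] / len(lipids)
    return ScalarObservable("area_per_lipid", float(per_frame.mean()),
                            _partition_stderr(per_frame, n_partitions), "Å^2")


def compute_thickness(traj: Trajectory,
                      n_partitions: int = N_PARTITIONS_DEFAULT) -> ScalarObservable:
    """Mean distance between the leaflet phosphate planes."""
    idx_up = traj.indices_where(lambda p: p.role == ROLE_P and p.leaflet == Leaflet.UPPER)
    idx_lo = traj.indices_where(lambda p: p.role == ROLE_P and p.leaflet == Leaflet.LOWER)
    if len(idx_up) == 0 or len(idx_lo) == 0:
        raise DataError("both leaflets must be populated (run assign_leaflets?)")
    per_frame = (traj.coords[:, idx_up, 2].mean(axis=1)
                 - traj.coords[:, idx_lo, 2].mean(axis=1))
    return ScalarObservable("thickness", float(per_frame.mean()),
                            _partition_stderr(per_frame, n_partitions), "Å")


# ---------------------------------------------------------------------------
# Radial distribution functions
# ---------------------------------------------------------------------------

def _lateral_distances(a: np.ndarray, b: np.ndarray, box_xy: np.ndarray,
                       periodic: bool, same: bool) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    if periodic:
        d = minimum_image(d, box_xy)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    if same:
        r = r[~np.eye(len(a), dtype=bool)]
    return np.ravel(r)


def _rdf_one_group(traj, idx_a, idx_b, r_max, dr, mode3d=False):
    edges = np.arange(0.0, r_max + dr / 2, dr)
    hist = np.zeros(len(edges) - 1)
    same = np.array_equal(idx_a, idx_b)
    norm = 0.0
    for fi in range(traj.n_frames):
        box = traj.box[fi]
        if mode3d:
            d = traj.coords[fi, idx_a][:, None, :] - traj.coords[fi, idx_b][None, :, :]
            if traj.periodic:
                d = minimum_image(d, box)
            r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
            if same:
                r = r[~np.eye(len(idx_a), dtype=bool)]
            r = np.ravel(r)
        else:
            r = _lateral_distances(traj.coords[fi, idx_a, :2],
                                   traj.coords[fi, idx_b, :2],
                                   box[:2], traj.periodic, same)
        hist += np.histogram(r, bins=edges)[0]
        area = box[0] * box[1]
        n_b_eff = len(idx_b) - (1 if same else 0)
        if mode3d:
            norm += len(idx_a) * n_b_eff / (area * box[2])
        else:
            norm += len(idx_a) * n_b_eff / area
    centers = 0.5 * (edges[:-1] + edges[1:])
    if mode3d:
        shell = 4.0 * np.pi * centers ** 2 * dr
    else:
        shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = hist / (norm * shell)
    return centers, np.nan_to_num(g)


def compute_rdf(traj: Trajectory, sel_a: Selection, sel_b: Selection,
                r_max: float = 20.0, dr: float = 0.1,
                leaflet_mode: str = "per_leaflet_averaged",
                dimensionality: str = "2d") -> RDFResult:
    """Pair distribution of (lateral, by default) distances, minimum image.

    With ``per_leaflet_averaged`` the two leaflets are analysed separately
    against a per-leaflet areal density and the g(r) curves averaged, which
    matches the quasi-planar geometry of a bilayer; ``combined`` uses the
    selections as-is.  ``dimensionality`` switches between 2D annulus and
    3D shell normalization.
    """
    if r_max > min(traj.box[:, 0].min(), traj.box[:, 1].min()) / 2:
        raise DataError("r_max exceeds half the smallest lateral box edge")
    mode3d = dimensionality.lower() == "3d"

    def _indices(sel, leaflet=None):
        if leaflet is not None:
            sel = Selection(species=sel.species, role=sel.role, leaflet=leaflet,
                            lipid_ids=sel.lipid_ids, predicate=sel.predicate,
                            z_range=sel.z_range, cylinder=sel.cylinder)
        return select(traj, sel, 0)

    if leaflet_mode == "per_leaflet_averaged":
        curves = []
        for leaf in (Leaflet.UPPER, Leaflet.LOWER):
            ia, ib = _indices(sel_a, leaf), _indices(sel_b, leaf)
            if len(ia) == 0 or len(ib) == 0:
                continue
            centers, g = _rdf_one_group(traj, ia, ib, r_max, dr, mode3d)
            curves.append(g)
        if not curves:
            raise DataError("selections empty in both leaflets")
        g = np.mean(curves, axis=0)
    else:
        ia, ib = _indices(sel_a), _indices(sel_b)
        if len(ia) == 0 or len(ib) == 0:
            raise DataError("empty selection for RDF")
        centers, g = _rdf_one_group(traj, ia, ib, r_max, dr, mode3d)
    return RDFResult(centers, g, (sel_a, sel_b), traj.n_frames, leaflet_mode)


# ---------------------------------------------------------------------------
# Deuterium order parameters
# ---------------------------------------------------------------------------

def compute_scd(traj: Trajectory, species: Species = Species.DOPC,
                chain: str = "sn1",
                n_partitions: int = N_PARTITIONS_DEFAULT,
                lipid_ids: Optional[Sequence[int]] = None) -> OrderParameterProfile:
    """Per-carbon S_CD = ⟨½(3cos²Θ − 1)⟩ of CH bonds vs the membrane normal.

    CH vectors are built from paired C/H particles sharing (lipid, chain,
    carbon); the average runs over lipids and frames, the standard error
    over contiguous frame partitions.  Carbons lacking vectors are omitted
    with a warning.
    """
    species = Species(species)
    by_carbon = {}
    for i, p in enumerate(traj.particles):
        if p.species == species and p.chain == chain and p.carbon is not None:
            if lipid_ids is not None and p.lipid_id not in lipid_ids:
                continue
            slot = by_carbon.setdefault(p.carbon, {})
            slot.setdefault(p.role, {})[p.lipid_id] = i
    if not by_carbon:
        raise DataError(f"no CH vectors for species={species.value} chain={chain}")

    carbons, values, errors = [], [], []
    for k in sorted(by_carbon):
        slot = by_carbon[k]
        lids = sorted(set(slot.get(ROLE_C, {})) & set(slot.get(ROLE_H, {})))
        if not lids:
            logger.warning("carbon %d has no complete CH pairs; omitted", k)
            continue
        ic = np.array([slot[ROLE_C][l] for l in lids])
        ih = np.array([slot[ROLE_H][l] for l in lids])
        v = traj.coords[:, ih, :] - traj.coords[:, ic, :]      # (F, n, 3)
        cos2 = v[:, :, 2] ** 2 / np.einsum("fij,fij->fi", v, v)
        s_frame = (0.5 * (3.0 * cos2 - 1.0)).mean(axis=1)
        carbons.append(k)
        values.append(float(s_frame.mean()))
        errors.append(_partition_stderr(s_frame, n_partitions))
    return OrderParameterProfile(chain, np.array(carbons),
                                 np.array(values), np.array(errors))


# ---------------------------------------------------------------------------
# Coordination number and cluster detection
# ---------------------------------------------------------------------------

def coordination_number(traj: Trajectory, center_sel: Selection,
                        neighbor_sel: Selection, cutoff: float,
                        n_partitions: int = N_PARTITIONS_DEFAULT) -> ScalarObservable:
    """Mean neighbour count within a 3D cutoff of each center (minimum image)."""
    if cutoff > traj.box.min() / 2:
        raise DataError("cutoff exceeds half the smallest box edge")
    per_frame = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        ic = select(traj, center_sel, fi)
        im = select(traj, neighbor_sel, fi)
        if len(ic) == 0:
            raise DataError("empty center selection for coordination number")
        if len(im) == 0:
            per_frame[fi] = 0.0
            continue
        d = traj.coords[fi, ic][:, None, :] - traj.coords[fi, im][None, :, :]
        if traj.periodic:
            d = minimum_image(d, traj.box[fi])
        r2 = np.einsum("ijk,ijk->ij", d, d)
        per_frame[fi] = (r2 <= cutoff ** 2).sum(axis=1).mean()
    return ScalarObservable("coordination_number", float(per_frame.mean()),
                            _partition_stderr(per_frame, n_partitions), "count")


def detect_clusters(traj: Trajectory, species: Species = Species.RHB,
                    contact_cutoff: float = 4.5) -> ClusterReport:
    """Connected components of dye lipids under a same-leaflet contact criterion.

    Two lipids are in contact when any pair of their particles lies closer
    than the cutoff (3D minimum image); contacts never bridge leaflets.
    """
    species = Species(species)
    lipids = sorted({p.lipid_id for p in traj.particles if p.species == species})
    if len(lipids) < 2:
        raise DataError("need at least 2 dye lipids for cluster detection")
    lipid_particles = {l: [] for l in lipids}
    lipid_leaflet = {}
    for i, p in enumerate(traj.particles):
        if p.species == species:
            lipid_particles[p.lipid_id].append(i)
            lipid_leaflet[p.lipid_id] = p.leaflet
    groups = [np.array(lipid_particles[l]) for l in lipids]

    components = []
    n = len(lipids)
    for fi in range(traj.n_frames):
        rows, cols = [], []
        for a in range(n):
            for b in range(a + 1, n):
                if lipid_leaflet[lipids[a]] != lipid_leaflet[lipids[b]]:
                    continue
                d = (traj.coords[fi, groups[a]][:, None, :]
                     - traj.coords[fi, groups[b]][None, :, :])
                if traj.periodic:
                    d = minimum_image(d, traj.box[fi])
                if np.einsum("ijk,ijk->ij", d, d).min() < contact_cutoff ** 2:
                    rows.append(a)
                    cols.append(b)
        adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
        comp = [[] for _ in range(n_comp)]
        for k, lab in enumerate(labels):
            comp[lab].append(lipids[k])
        components.append(comp)
    return ClusterReport(contact_cutoff, components)
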
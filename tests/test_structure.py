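"""Structural observables against closed forms and brute-force oracles."""

import numpy as np
import pytest

from memprobe import (
    DataError, Leaflet, Particle, Selection, Species, Trajectory,
    compute_area_per_lipid, compute_rdf, compute_scd, compute_thickness,
    coordination_number, detect_clusters, minimum_image,
)

from conftest import make_static_trajectory


def _p_bilayer(z_upper, z_lower, n_per_leaflet=2, box=(100.0, 100.0, 100.0),
               n_frames=1, boxes=None, times=None):
    parts, coords = [], []
    for i in range(n_per_leaflet):
        parts.append(Particle(i, Species.DOPC, "P", lipid_id=i,
                              leaflet=Leaflet.UPPER))
        coords.append([10.0 * i, 0.0, z_upper])
    for i in range(n_per_leaflet):
        parts.append(Particle(n_per_leaflet + i, Species.DOPC, "P",
                              lipid_id=n_per_leaflet + i, leaflet=Leaflet.LOWER))
        coords.append([10.0 * i, 5.0, z_lower])
    coords = np.broadcast_to(np.array(coords), (n_frames, 2 * n_per_leaflet, 3)).copy()
    box_arr = np.asarray(boxes if boxes is not None else box, dtype=float)
    t = np.arange(n_frames, dtype=float) if times is None else times
    return Trajectory(parts, coords, t, box_arr)


# ---------------------------------------------------------------------------
# area per lipid / thickness
# ---------------------------------------------------------------------------

def test_area_per_lipid_value_and_zero_stderr_for_constant_box():
    traj = _p_bilayer(19.3, -19.3, n_per_leaflet=200,
                      box=(116.79, 116.79, 100.0), n_frames=16)
    obs = compute_area_per_lipid(traj, "upper")
    assert obs.value == pytest.approx(116.79 ** 2 / 200)
    assert round(obs.value, 1) == 68.2
    assert obs.stderr == 0.0


def test_area_per_lipid_alternating_boxes():
    boxes = np.array([[100.0, 100.0, 50.0], [110.0, 110.0, 50.0]] * 4)
    traj = _p_bilayer(10.0, -10.0, n_per_leaflet=100, boxes=boxes, n_frames=8)
    obs = compute_area_per_lipid(traj, "upper")
    assert obs.value == pytest.approx((100.0 + 121.0) / 2)


def test_area_per_lipid_empty_leaflet_errors():
    traj = _p_bilayer(19.3, -19.3)
    for p in traj.particles:
        p.leaflet = Leaflet.UPPER
    with pytest.raises(DataError):
        compute_area_per_lipid(traj, "lower")


def test_thickness_flat_leaflets_and_translation_invariance():
    traj = _p_bilayer(19.3, -19.3, n_per_leaflet=50)
    assert compute_thickness(traj).value == pytest.approx(38.6)
    traj.coords[:, :, 2] += 5.0
    assert compute_thickness(traj).value == pytest.approx(38.6)


def test_thickness_with_gaussian_noise_tight():
    rng = np.random.default_rng(6)
    traj = _p_bilayer(19.3, -19.3, n_per_leaflet=200, n_frames=50)
    traj.coords[:, :, 2] += rng.normal(0.0, 1.0, size=traj.coords.shape[:2])
    obs = compute_thickness(traj)
    assert obs.value == pytest.approx(38.6, abs=0.1)


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def _rdf_brute_force(traj, idx, r_max, dr):
    """O(N²) per-leaflet lateral RDF oracle."""
    edges = np.arange(0.0, r_max + dr / 2, dr)
    hist = np.zeros(len(edges) - 1)
    norm = 0.0
    for fi in range(traj.n_frames):
        box = traj.box[fi]
        for a in idx:
            for b in idx:
                if a == b:
                    continue
                d = traj.coords[fi, a, :2] - traj.coords[fi, b, :2]
                d = minimum_image(d, box[:2])
                r = np.hypot(*d)
                if r < edges[-1]:
                    hist[int(r // dr)] += 1
        norm += len(idx) * (len(idx) - 1) / (box[0] * box[1])
    shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    return hist / (norm * shell)


def test_rdf_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    n, f = 50, 5
    parts = [Particle(i, Species.DOPC, "P", lipid_id=i, leaflet=Leaflet.UPPER)
             for i in range(n)]
    coords = np.concatenate(
        [rng.uniform(0, 60, size=(f, n, 2)), np.full((f, n, 1), 20.0)], axis=2)
    traj = Trajectory(parts, coords, np.arange(f, dtype=float),
                      np.array([60.0, 60.0, 60.0]))
    sel = Selection(role="P")
    res = compute_rdf(traj, sel, sel, r_max=15.0, dr=0.5)
    oracle = _rdf_brute_force(traj, np.arange(n), 15.0, 0.5)
    np.testing.assert_allclose(res.g, oracle, atol=1e-10)


def test_rdf_two_fixed_particles_single_bin():
    parts = [Particle(i, Species.DOPC, "P", lipid_id=i, leaflet=Leaflet.UPPER)
             for i in range(2)]
    coords = np.array([[[10.0, 10.0, 0.0], [17.0, 10.0, 0.0]]])
    traj = Trajectory(parts, coords, np.array([0.0]), np.array([50.0, 50.0, 50.0]))
    sel = Selection(role="P")
    res = compute_rdf(traj, sel, sel, r_max=10.0, dr=0.1)
    nonzero = np.nonzero(res.g)[0]
    assert len(nonzero) == 1
    assert res.r_bin_centers[nonzero[0]] == pytest.approx(7.05, abs=0.051)


def test_rdf_of_poisson_process_is_flat():
    rng = np.random.default_rng(9)
    n, f = 300, 20
    parts = [Particle(i, Species.DOPC, "P", lipid_id=i, leaflet=Leaflet.UPPER)
             for i in range(n)]
    coords = np.concatenate(
        [rng.uniform(0, 100, size=(f, n, 2)), np.zeros((f, n, 1))], axis=2)
    traj = Trajectory(parts, coords, np.arange(f, dtype=float),
                      np.array([100.0, 100.0, 100.0]))
    sel = Selection(role="P")
    res = compute_rdf(traj, sel, sel, r_max=20.0, dr=0.5)
    centers = res.r_bin_centers
    rho = n / 100.0 ** 2
    expected_counts = f * n * rho * np.pi * ((centers + 0.25) ** 2 - (centers - 0.25) ** 2)
    # ordered pairs are counted twice, doubling the variance of each bin
    sigma_g = 3.0 * np.sqrt(2.0 / expected_counts)
    mask = centers > 0.5
    assert np.all(np.abs(res.g[mask] - 1.0) < sigma_g[mask])


def test_rdf_r_max_beyond_half_box_rejected(small_bilayer):
    traj, _, _ = small_bilayer
    with pytest.raises(DataError):
        compute_rdf(traj, Selection(role="P"), Selection(role="P"), r_max=100.0)


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------

def _ch_trajectory(theta_deg):
    """One lipid, one CH pair at fixed polar angle."""
    theta = np.deg2rad(theta_deg)
    parts = [
        Particle(0, Species.DOPC, "P", lipid_id=0, leaflet=Leaflet.UPPER),
        Particle(1, Species.DOPC, "C", lipid_id=0, leaflet=Leaflet.UPPER,
                 chain="sn1", carbon=2),
        Particle(2, Species.DOPC, "H", lipid_id=0, leaflet=Leaflet.UPPER,
                 chain="sn1", carbon=2),
    ]
    c = np.array([5.0, 5.0, 10.0])
    h = c + 1.09 * np.array([np.sin(theta), 0.0, np.cos(theta)])
    coords = np.array([[[5.0, 5.0, 15.0], c, h]])
    return Trajectory(parts, coords, np.array([0.0]), np.array([20.0, 20.0, 40.0]))


@pytest.mark.parametrize("theta,expected", [
    (0.0, 1.0),
    (90.0, -0.5),
    (np.degrees(np.arccos(np.sqrt(1 / 3))), 0.0),   # magic angle 54.7356°
])
def test_scd_trivial_angles(theta, expected):
    prof = compute_scd(_ch_trajectory(theta), "DOPC", "sn1")
    assert prof.scd[0] == pytest.approx(expected, abs=1e-6)
    assert prof.carbons[0] == 2


def test_scd_isotropic_vectors_average_to_zero():
    rng = np.random.default_rng(10)
    n = 4000
    parts, coords = [], []
    for i in range(n):
        parts.append(Particle(2 * i, Species.DOPC, "C", lipid_id=i,
                              leaflet=Leaflet.UPPER, chain="sn1", carbon=1))
        parts.append(Particle(2 * i + 1, Species.DOPC, "H", lipid_id=i,
                              leaflet=Leaflet.UPPER, chain="sn1", carbon=1))
        c = rng.uniform(0, 50, size=3)
        v = rng.normal(size=3)
        coords += [c, c + 1.09 * v / np.linalg.norm(v)]
    traj = Trajectory(parts, np.array(coords)[None, :, :], np.array([0.0]),
                      np.array([60.0, 60.0, 60.0]))
    prof = compute_scd(traj, "DOPC", "sn1")
    assert abs(prof.scd[0]) < 3.0 / np.sqrt(n)


# ---------------------------------------------------------------------------
# coordination number
# ---------------------------------------------------------------------------

def _coordination_brute_force(traj, centers, neighbors, cutoff):
    vals = []
    for fi in range(traj.n_frames):
        for c in centers:
            cnt = 0
            for m in neighbors:
                d = traj.coords[fi, c] - traj.coords[fi, m]
                d = minimum_image(d, traj.box[fi])
                if (d ** 2).sum() <= cutoff ** 2:
                    cnt += 1
            vals.append(cnt)
    return float(np.mean(vals))


def test_coordination_uniform_ions_matches_poisson_expectation():
    rng = np.random.default_rng(11)
    box = 60.0
    n_centers, n_ions, f = 20, 120, 40
    parts = [Particle(i, Species.DOPC, "P", lipid_id=i) for i in range(n_centers)]
    parts += [Particle(n_centers + i, Species.ION, "ion", n_centers + i, charge=1.0)
              for i in range(n_ions)]
    coords = rng.uniform(0, box, size=(f, n_centers + n_ions, 3))
    traj = Trajectory(parts, coords, np.arange(f, dtype=float),
                      np.array([box, box, box]))
    cutoff = 6.0
    obs = coordination_number(traj, Selection(role="P"),
                              Selection(species="ION"), cutoff)
    expected = n_ions / box ** 3 * 4 / 3 * np.pi * cutoff ** 3
    assert obs.value == pytest.approx(expected, abs=4 * obs.stderr + 0.02)
    oracle = _coordination_brute_force(
        traj, np.arange(n_centers), n_centers + np.arange(n_ions), cutoff)
    assert obs.value == pytest.approx(oracle, abs=1e-12)


def test_coordination_zero_ions_is_zero():
    parts = [Particle(0, Species.DOPC, "P", lipid_id=0)]
    traj = Trajectory(parts, np.zeros((3, 1, 3)) + 5.0,
                      np.arange(3, dtype=float), np.array([20.0, 20.0, 20.0]))
    obs = coordination_number(traj, Selection(role="P"),
                              Selection(species="ION"), 6.0)
    assert obs.value == 0.0


def test_coordination_cutoff_beyond_half_box_rejected(small_bilayer):
    traj, _, _ = small_bilayer
    with pytest.raises(DataError):
        coordination_number(traj, Selection(role="P"), Selection(role="P"), 1000.0)


# ---------------------------------------------------------------------------
# cluster detection
# ---------------------------------------------------------------------------

def _rhb_points(points, leaflets=None):
    n = len(points)
    leaflets = leaflets or [Leaflet.UPPER] * n
    parts = [Particle(i, Species.RHB, "P", lipid_id=i, leaflet=leaflets[i])
             for i in range(n)]
    coords = np.asarray(points, dtype=float)[None, :, :]
    return Trajectory(parts, coords, np.array([0.0]),
                      np.array([200.0, 200.0, 100.0]))


def test_separated_dyes_are_singletons():
    pts = [[25.0 * i, 25.0 * i, 50.0] for i in range(8)]
    rep = detect_clusters(_rhb_points(pts), contact_cutoff=4.5)
    assert sorted(len(c) for c in rep.components[0]) == [1] * 8


def test_chained_dyes_form_one_component():
    pts = [[10.0 + 4.0 * i, 10.0, 50.0] for i in range(8)]
    rep = detect_clusters(_rhb_points(pts), contact_cutoff=4.5)
    assert sorted(len(c) for c in rep.components[0]) == [8]


def test_contacts_do_not_bridge_leaflets():
    pts = [[10.0, 10.0, 60.0], [10.0, 10.0, 40.0]]
    rep = detect_clusters(
        _rhb_points(pts, [Leaflet.UPPER, Leaflet.LOWER]), contact_cutoff=50.0)
    assert sorted(len(c) for c in rep.components[0]) == [1, 1]


def _union_find_oracle(points, cutoff, box):
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d = minimum_image(np.asarray(points[i]) - np.asarray(points[j]),
                              np.asarray(box))
            if (d ** 2).sum() < cutoff ** 2:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted(frozenset(c) for c in comps.values())


def test_random_placements_match_union_find_oracle():
    rng = np.random.default_rng(13)
    for trial in range(5):
        pts = np.column_stack([rng.uniform(0, 60, size=(12, 2)),
                               np.full(12, 50.0)])
        rep = detect_clusters(_rhb_points(list(pts)), contact_cutoff=8.0)
        got = sorted(frozenset(c) for c in rep.components[0])
        want = _union_find_oracle(list(pts), 8.0, [200.0, 200.0, 100.0])
        assert got == want


def test_components_partition_the_dye_set():
    rng = np.random.default_rng(14)
    pts = np.column_stack([rng.uniform(0, 80, size=(10, 2)), np.full(10, 50.0)])
    rep = detect_clusters(_rhb_points(list(pts)), contact_cutoff=10.0)
    flat = sorted(l for comp in rep.components[0] for l in comp)
    assert flat == list(range(10))
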
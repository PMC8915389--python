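"""RDF normalization, coordination numbers, inter-duplex contact RDFs."""
import numpy as np
import pytest

import dnacage as dc
from dnacage.model import RegionSelection, Trajectory, minimum_image_vectors

from conftest import make_point_system


def brute_force_shell_counts(frame, ids_a, ids_b, edges, box):
    """Independent double-loop histogram oracle."""
    hist = np.zeros(len(edges) - 1)
    for a in ids_a:
        for b in ids_b:
            if a == b:
                continue
            v = minimum_image_vectors(frame[b] - frame[a], box)
            d = float(np.linalg.norm(v))
            k = int(d / (edges[1] - edges[0]))
            if k < len(hist):
                hist[k] += 1
    return hist


def test_rdf_matches_brute_force_three_atoms():
    box = np.array([20.0, 20.0, 20.0])
    system = make_point_system(
        [[1.0, 1.0, 1.0], [4.0, 1.0, 1.0], [1.0, 6.5, 1.0]], box=box
    )
    traj = Trajectory.single_frame(system)
    A = RegionSelection("a", np.array([0]))
    B = RegionSelection("b", np.array([1, 2]))
    r = dc.compute_rdf(traj, A, B, dr=0.1, r_max=10.0)
    oracle = brute_force_shell_counts(traj.frames[0], A.atom_ids, B.atom_ids,
                                      r.r_edges, box)
    assert np.array_equal(r.p_counts * len(A), oracle)
    # normalization of the occupied bins follows the pair-distribution form
    mid = r.r_mid
    expected = oracle / len(A) * np.prod(box) * len(A) / (
        4 * np.pi * mid**2 * 0.1 * r.n_pairs
    )
    assert np.allclose(r.g, expected)


def test_rdf_matches_brute_force_random_200(rng):
    box = np.array([25.0, 25.0, 25.0])
    pts = rng.uniform(0, 25, size=(200, 3))
    system = make_point_system(pts, box=box)
    traj = Trajectory.single_frame(system)
    A = RegionSelection("a", np.arange(100))
    B = RegionSelection("b", np.arange(100, 200))
    r = dc.compute_rdf(traj, A, B, dr=0.1, r_max=12.0)
    oracle = brute_force_shell_counts(traj.frames[0], A.atom_ids, B.atom_ids,
                                      r.r_edges, box)
    assert np.abs(r.p_counts * len(A) - oracle).max() <= 1


def test_default_bin_width(dd20_bundle):
    system = dd20_bundle["system"]
    traj = dd20_bundle["traj"]
    spd = dc.select_region(system, None, "polyamine_heavy")
    minor = dc.select_region(system, system.duplexes[0], "minor")
    r = dc.compute_rdf(traj, spd, minor)
    assert np.allclose(np.diff(r.r_edges), 0.1)


def test_ideal_gas_limit(rng):
    """Homogeneous cross selections: g -> 1 away from the bin-count floor."""
    box = np.array([50.0, 50.0, 50.0])
    frames = rng.uniform(0, 50, size=(6, 4000, 3))
    system = make_point_system(frames[0], box=box)
    traj = Trajectory(frames, np.arange(6, dtype=float), system)
    A = RegionSelection("a", np.arange(2000))
    B = RegionSelection("b", np.arange(2000, 4000))
    r = dc.compute_rdf(traj, A, B, dr=0.1, r_max=25.0)
    window = (r.r_mid > 3.0) & (r.r_mid < 12.5)
    assert np.abs(r.g[window] - 1.0).max() <= 0.05


def test_eq1_self_consistency(dd20_bundle):
    system, traj = dd20_bundle["system"], dd20_bundle["traj"]
    spd = dc.select_region(system, None, "polyamine_heavy")
    ph = dc.select_region(system, system.duplexes[0], "phosphate")
    r = dc.compute_rdf(traj, spd, ph)
    ok = r.r_mid > 0
    assert np.abs(r.recompute_g()[ok] - r.g[ok]).max() < 1e-12 * max(1, r.g.max())


def test_cn_monotone_in_cutoff(rng):
    box = np.array([20.0, 20.0, 20.0])
    system = make_point_system(rng.uniform(0, 20, (80, 3)), box=box)
    traj = Trajectory.single_frame(system)
    A = RegionSelection("a", np.arange(40))
    B = RegionSelection("b", np.arange(40, 80))
    r = dc.compute_rdf(traj, A, B, dr=0.1, r_max=9.0)
    cns = [dc.coordination_number(r, rc) for rc in np.arange(0.5, 9.0, 0.25)]
    assert np.all(np.diff(cns) >= 0)


def test_cn_single_pair_inside_outside():
    system = make_point_system([[0, 0, 0], [3.0, 0, 0]],
                               box=np.array([30.0, 30.0, 30.0]))
    traj = Trajectory.single_frame(system)
    A = RegionSelection("a", np.array([0]))
    B = RegionSelection("b", np.array([1]))
    r = dc.compute_rdf(traj, A, B, dr=0.1, r_max=10.0)
    assert dc.coordination_number(r, 4.55) == 1.0
    assert dc.coordination_number(r, 2.0) == 0.0
    with pytest.warns(UserWarning, match="below the first bin"):
        assert dc.coordination_number(r, 0.05) == 0.0


def test_rdf_symmetry_equal_selections(rng):
    box = np.array([20.0, 20.0, 20.0])
    system = make_point_system(rng.uniform(0, 20, (60, 3)), box=box)
    traj = Trajectory.single_frame(system)
    A = RegionSelection("a", np.arange(30))
    B = RegionSelection("b", np.arange(30, 60))
    r_ab = dc.compute_rdf(traj, A, B, dr=0.1, r_max=9.0)
    r_ba = dc.compute_rdf(traj, B, A, dr=0.1, r_max=9.0)
    assert np.allclose(r_ab.g, r_ba.g)


def test_per_residue_cn_locality(dd20_bundle):
    """A polyamine parked by the minor groove of one bp registers only
    in a narrow neighbourhood of that bp."""
    import copy

    from dnacage.model import region_atoms_by_bp

    system = dd20_bundle["system"]
    d1 = system.duplexes[0]
    frame = system.coordinates.copy()
    per_bp = region_atoms_by_bp(system, d1, "minor")
    target = per_bp[5]  # bp 6
    p = system.polyamines[0]
    shift = frame[target].mean(axis=0) + np.array([3.0, 0.0, 0.0]) - frame[p.central_N]
    ids = np.asarray(p.atom_ids)
    frame[ids] += shift
    # move every other polyamine far away
    for q in system.polyamines[1:]:
        frame[np.asarray(q.atom_ids)] += 300.0
    big_box = np.array([1000.0, 1000.0, 1000.0])
    sys2 = copy.copy(system)
    sys2.box = big_box
    traj = Trajectory(frame[None], np.array([0.0]), sys2)
    spd = dc.select_region(system, None, "polyamine_heavy")
    prof = dc.per_residue_cn(traj, spd, d1, "minor", r_cut=4.55)
    assert prof.values.sum() > 0
    hot = np.flatnonzero(prof.values > 0) + 1
    assert all(abs(bp - 6) <= 2 for bp in hot)
    assert prof.r_cut == 4.55


def test_rdf_dd_far_duplexes_no_short_contacts():
    spec = dc.SystemSpec(separation=30.0, n_polyamine=0, n_K=0, n_Cl=0,
                         n_water=0)
    system, _ = dc.assemble_two_duplex_system(spec, fraction_caged=0.0, seed=2)
    traj = Trajectory.single_frame(system)
    res = dc.rdf_dd(traj, system.duplexes[0], system.duplexes[1], r_max=12.0)
    short = res.rdf.r_mid < 8.0
    assert np.all(res.rdf.g[short] == 0.0)


def test_rdf_dd_constructed_contact_pair():
    """One cross-duplex P-P pair moved to 5.5 A: first occupied bin is at
    5.5 A and the involved phosphates get per-P CN = 1."""
    spec = dc.SystemSpec(separation=30.0, n_polyamine=0, n_K=0, n_Cl=0,
                         n_water=0)
    system, _ = dc.assemble_two_duplex_system(spec, fraction_caged=0.0, seed=2)
    d1, d2 = system.duplexes
    p1 = d1.phosphate_P[d1.chain_i][10]
    p2 = d2.phosphate_P[d2.chain_i][10]
    frame = system.coordinates.copy()
    outward = frame[p1] - np.array([0.0, 0.0, frame[p1][2]])  # radial from axis
    outward /= np.linalg.norm(outward)
    frame[p2] = frame[p1] + 5.5 * outward
    all_p1 = np.concatenate([np.asarray(v) for v in d1.phosphate_P.values()])
    all_p2 = np.concatenate([np.asarray(v) for v in d2.phosphate_P.values()])
    cross = np.linalg.norm(
        frame[all_p1][:, None] - frame[all_p2][None, :], axis=-1
    )
    assert cross.min() == pytest.approx(5.5, abs=1e-9)  # construction holds
    traj = Trajectory(frame[None], np.array([0.0]), system)
    res = dc.rdf_dd(traj, d1, d2, r_max=12.0)
    occupied = np.flatnonzero(res.rdf.p_counts)
    assert res.rdf.r_edges[occupied[0]] == pytest.approx(5.5, abs=0.1)
    per = res.per_nucleotide
    touched = per[per.cn > 0]
    assert len(touched) == 2
    assert set(touched.cn) == {1.0}


def test_rdf_dd_same_duplex_rejected(bdna22):
    traj = Trajectory.single_frame(bdna22)
    with pytest.raises(ValueError, match="distinct"):
        dc.rdf_dd(traj, bdna22.duplexes[0], bdna22.duplexes[0])


def test_rdf_against_mdanalysis_interrdf(rng, tmp_path):
    """Independent cross-check: MDAnalysis InterRDF on the same fixture."""
    import MDAnalysis as mda
    from MDAnalysis.analysis.rdf import InterRDF

    box = np.array([24.0, 24.0, 24.0])
    pts = rng.uniform(0, 24, size=(300, 3))
    system = make_point_system(pts, box=box)
    traj = Trajectory.single_frame(system)
    A = RegionSelection("a", np.arange(150))
    B = RegionSelection("b", np.arange(150, 300))
    mine = dc.compute_rdf(traj, A, B, dr=0.1, r_max=10.0)

    u = mda.Universe.empty(300, trajectory=True)
    u.atoms.positions = pts
    u.dimensions = [24.0, 24.0, 24.0, 90.0, 90.0, 90.0]
    ref = InterRDF(u.atoms[:150], u.atoms[150:], nbins=100, range=(0.0, 10.0))
    ref.run()
    # raw shell counts agree exactly; g agrees up to the shell-volume
    # convention (4 pi r^2 dr here, exact spherical shell in MDAnalysis)
    assert np.allclose(mine.p_counts * mine.n_A, ref.results.count, atol=1e-9)
    far = mine.r_mid > 2.0
    assert np.allclose(mine.g[far], ref.results.rdf[far], rtol=1e-2)
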
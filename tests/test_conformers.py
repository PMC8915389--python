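"""End-to-end conformers, bridge detection, interaction-mode labels."""
import numpy as np
import pytest

import dnacage as dc
from dnacage.model import AtomRecord, Duplex, MolecularSystem, PolyamineMolecule
from dnacage.synthetic import spermidine_template


def _rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def test_end_to_end_zero_and_invariance(dd20_bundle, rng):
    system = dd20_bundle["system"]
    p = system.polyamines[0]
    frame = system.coordinates.copy()
    frame[p.terminal_N[1]] = frame[p.terminal_N[0]]
    assert dc.end_to_end(p, frame) == 0.0
    frame2 = system.coordinates
    ee = dc.end_to_end(p, frame2)
    moved = frame2 @ _rotation(rng).T + np.array([7.0, -3.0, 11.0])
    assert abs(dc.end_to_end(p, moved) - ee) < 1e-9


@pytest.mark.parametrize(
    "ee,expected",
    [(6.9, "folded"), (9.1, "elongated"), (8.0, "intermediate"),
     (7.0, "intermediate"), (9.0, "intermediate")],
)
def test_classify_conformer_thresholds(ee, expected):
    assert dc.classify_conformer(ee) == expected


def test_ee_distribution_partitions_sum_to_one(dd20_bundle):
    traj, crit = dd20_bundle["traj"], dd20_bundle["crit"]
    series = dc.state_series(traj, crit, 25.0)
    dist = dc.ee_distribution(traj, series)
    assert dist.fractions  # at least one populated partition
    for state, fracs in dist.fractions.items():
        assert sum(fracs.values()) == pytest.approx(1.0)
    total = sum(sum(c.values()) for c in dist.counts.values())
    assert total == series.n_molecules * series.n_samples


def test_ee_distribution_all_elongated_single_state(dd20_bundle):
    """Identical elongated conformers: elongated fraction 1.0 in every
    populated partition; the empty partition is absent, not 0/0."""
    system = dd20_bundle["system"]
    frame = system.coordinates.copy()
    template = spermidine_template(folded=False)
    for p in system.polyamines:
        frame[np.asarray(p.atom_ids)] = template + frame[p.central_N]
    traj = dc.Trajectory(frame[None], np.array([0.0]), system)
    states = np.zeros((len(system.polyamines), 1), dtype=bool)  # all uncaged
    series = dc.StateSeries(states, 25.0, times=np.array([0.0]))
    dist = dc.ee_distribution(traj, series)
    assert dist.fractions["uncaged"]["elongated"] == 1.0
    assert "caged" not in dist.fractions


def test_ee_fraction_recovery_within_3se():
    """20% folded placements recovered from the trajectory within 3 SE
    (folded/elongated assignment is per molecule)."""
    spec = dc.SystemSpec.dd(25.0)
    system, states0 = dc.assemble_two_duplex_system(
        spec, fraction_caged=0.5, seed=21, folded_fraction=0.2
    )
    dyn = dc.DynamicsSpec(p_enter=0.1, p_exit=0.1, noise_sigma=0.5,
                          n_frames=21, seed=22)
    traj, truth = dc.generate_trajectory(system, dyn, initial_states=states0)
    dist = dc.ee_distribution(traj, truth)
    folded = sum(c["folded"] for c in dist.counts.values())
    total = sum(sum(c.values()) for c in dist.counts.values())
    se = np.sqrt(0.2 * 0.8 / len(system.polyamines))
    assert abs(folded / total - 0.2) <= 3 * se


def _bridge_fixture():
    """Hand-built geometry: two straight 'backbones' with P/O atoms, one
    polyamine; duplex 1 runs along z at x=0, duplex 2 along y at x=30."""
    atoms = []
    aid = 1

    def add(name, resname, resid, chain, xyz):
        nonlocal aid
        atoms.append(AtomRecord(aid, name, resname, resid, chain,
                                np.asarray(xyz, float)))
        aid += 1
        return aid - 2  # atom table index

    pP1, pO1_1, pO2_1 = [], [], []
    for k in range(8):  # duplex 1 backbone along z
        pP1.append(add("P", "DA", k + 2, "A", [0.0, 0.0, 3.4 * k]))
        pO1_1.append(add("O1P", "DA", k + 2, "A", [1.3, 0.0, 3.4 * k]))
        pO2_1.append(add("O2P", "DA", k + 2, "A", [-1.3, 0.0, 3.4 * k]))
    pP2, pO1_2, pO2_2 = [], [], []
    for k in range(8):  # duplex 2 backbone along y
        pP2.append(add("P", "DA", k + 2, "C", [30.0, 3.4 * k, 6.0]))
        pO1_2.append(add("O1P", "DA", k + 2, "C", [28.7, 3.4 * k, 6.0]))
        pO2_2.append(add("O2P", "DA", k + 2, "C", [31.3, 3.4 * k, 6.0]))
    d1 = Duplex("A" * 8, "A", "B", [(i + 1, 8 - i) for i in range(8)],
                bp_center_atoms=[pP1[0]] * 8,
                phosphate_P={"A": pP1}, phosphate_O1P={"A": pO1_1},
                phosphate_O2P={"A": pO2_1})
    d2 = Duplex("A" * 8, "C", "D", [(i + 1, 8 - i) for i in range(8)],
                bp_center_atoms=[pP2[0]] * 8,
                phosphate_P={"C": pP2}, phosphate_O1P={"C": pO1_2},
                phosphate_O2P={"C": pO2_2})
    spd_ids = []
    template = spermidine_template(folded=False)
    for name, xyz in zip(
        ["N1", "C2", "C3", "C4", "N5", "C6", "C7", "C8", "C9", "N10"], template
    ):
        spd_ids.append(add(name, "SPD", 1, "S", xyz + [15.0, 15.0, 15.0]))
    poly = PolyamineMolecule(1, spd_ids, (spd_ids[0], spd_ids[-1]), spd_ids[4])
    system = MolecularSystem(atoms=atoms, duplexes=[d1, d2], polyamines=[poly])
    return system, poly, d1, d2


def test_single_n_bridge_detected():
    system, poly, d1, d2 = _bridge_fixture()
    frame = system.coordinates.copy()
    # put an O of each duplex 2.9 A from the first terminal N
    n_pos = frame[poly.terminal_N[0]]
    o1 = d1.phosphate_O1P["A"][0]
    o2 = d2.phosphate_O1P["C"][0]
    frame[o1] = n_pos + [2.9, 0.0, 0.0]
    frame[o2] = n_pos + [-2.9, 0.0, 0.0]
    bridges = dc.detect_bridges(frame, system, (d1, d2))
    assert len(bridges) == 1
    assert bridges[0].kind == "single_N"
    assert bridges[0].amino_N == (poly.terminal_N[0],)
    assert bridges[0].contacts_d1[0][1] == pytest.approx(2.9)


def test_no_bridge_beyond_cutoff():
    system, poly, d1, d2 = _bridge_fixture()
    frame = system.coordinates.copy()
    n_pos = frame[poly.terminal_N[0]]
    frame[d1.phosphate_O1P["A"][0]] = n_pos + [5.0, 0.0, 0.0]
    frame[d2.phosphate_O1P["C"][0]] = n_pos + [-5.0, 0.0, 0.0]
    assert dc.detect_bridges(frame, system, (d1, d2)) == []


def test_molecule_level_bridge():
    system, poly, d1, d2 = _bridge_fixture()
    frame = system.coordinates.copy()
    frame[d1.phosphate_O1P["A"][0]] = frame[poly.terminal_N[0]] + [0, 0, 3.0]
    frame[d2.phosphate_O1P["C"][0]] = frame[poly.terminal_N[1]] + [0, 0, 3.0]
    bridges = dc.detect_bridges(frame, system, (d1, d2))
    assert len(bridges) == 1
    assert bridges[0].kind == "molecule"
    assert set(bridges[0].amino_N) == set(poly.terminal_N)


def test_bridges_match_all_pairs_oracle(dd20_bundle):
    """Contact sets equal an independent all-(amino N)x(phosphate O) scan."""
    system = dd20_bundle["system"]
    traj = dd20_bundle["traj"]
    d1, d2 = system.duplexes
    cutoff = 6.0  # enlarged so the random fixture produces contacts

    def oracle(frame):
        o_by_d = []
        for d in (d1, d2):
            ids = []
            for dd in (d.phosphate_O1P, d.phosphate_O2P):
                for v in dd.values():
                    ids.extend(v)
            o_by_d.append(np.array(sorted(ids)))
        found = set()
        for p in system.polyamines:
            per_n = {}
            for n in p.amino_N:
                c = []
                for ids in o_by_d:
                    vec = frame[ids] - frame[n]
                    vec -= system.box * np.round(vec / system.box)
                    c.append(set(ids[np.linalg.norm(vec, axis=1) <= cutoff]))
                per_n[n] = c
            for n, (c1, c2) in per_n.items():
                if c1 and c2:
                    found.add((p.molecule_id, "single_N", n))
            if not any(c1 and c2 for c1, c2 in per_n.values()):
                ns1 = [n for n, (c1, _) in per_n.items() if c1]
                ns2 = [n for n, (_, c2) in per_n.items() if c2]
                if any(a != b for a in ns1 for b in ns2):
                    found.add((p.molecule_id, "molecule", None))
        return found

    hits = 0
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        got = set()
        for b in dc.detect_bridges(frame, system, (d1, d2), cutoff=cutoff):
            if b.kind == "single_N":
                got.add((b.molecule_id, "single_N", b.amino_N[0]))
            else:
                got.add((b.molecule_id, "molecule", None))
        assert got == oracle(frame)
        hits += len(got)
    assert hits > 0  # the fixture really exercises the detector


def test_classify_mode_pp_and_c_shape(rng):
    system, poly, d1, d2 = _bridge_fixture()
    ids = np.asarray(poly.atom_ids)

    # pp: elongated molecule along duplex-1's backbone (z), bridging both;
    # duplex 2 backbone runs along y, perpendicular.
    frame = system.coordinates.copy()
    template = spermidine_template(folded=False)
    rot = np.array([[0.0, 0, 1], [0, 1, 0], [-1, 0, 0]])  # x -> z
    frame[ids] = template @ rot.T + np.array([2.0, 0.0, 10.0])
    frame[d1.phosphate_O1P["A"][3]] = frame[poly.terminal_N[0]] + [1.5, 0, 0]
    frame[d2.phosphate_O1P["C"][3]] = frame[poly.terminal_N[1]] + [1.5, 0, 0]
    label = dc.classify_mode(poly, frame, system, (d1, d2))
    assert label.label == "pp"
    a_par, a_perp = sorted(label.backbone_angles)
    assert a_par <= 30.0 and a_perp >= 60.0

    # c_shape: folded conformer bridging both duplexes
    frame2 = system.coordinates.copy()
    frame2[ids] = spermidine_template(folded=True) + np.array([15.0, 10.0, 5.0])
    frame2[d1.phosphate_O1P["A"][0]] = frame2[poly.terminal_N[0]] + [0, 0, 2.8]
    frame2[d2.phosphate_O1P["C"][0]] = frame2[poly.terminal_N[1]] + [0, 0, 2.8]
    label2 = dc.classify_mode(poly, frame2, system, (d1, d2))
    assert label2.label == "c_shape"

    # non-bridging molecule
    label3 = dc.classify_mode(poly, system.coordinates, system, (d1, d2))
    assert label3.label == "other"
    assert not label3.bridged

    # rigid-motion invariance of the labels
    q = _rotation(rng)
    t = np.array([3.0, -8.0, 5.0])
    assert dc.classify_mode(poly, frame @ q.T + t, system, (d1, d2)).label == "pp"
    assert dc.classify_mode(poly, frame2 @ q.T + t, system, (d1, d2)).label == "c_shape"
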
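"""Caged/uncaged classification, state series, summaries, residence."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dnacage as dc
from dnacage.caging import segment_duplexes
from dnacage.model import AtomRecord, Duplex, MolecularSystem, PolyamineMolecule


def _toy_pair(d_to_1, d_to_2):
    """Minimal frame: one bp center per duplex + one 3-N polyamine whose
    central N sits at the requested distances from the two centers."""
    sep = 20.0
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = np.array([sep, 0.0, 0.0])
    # solve for a point at distance d1 from c1 and d2 from c2
    x = (d_to_1**2 - d_to_2**2 + sep**2) / (2 * sep)
    y2 = d_to_1**2 - x**2
    assert y2 >= 0, "distances not realizable at this separation"
    pos = np.array([x, np.sqrt(y2), 0.0])
    atoms = [
        AtomRecord(1, "N1", "DA", 1, "A", c1),
        AtomRecord(2, "N1", "DA", 1, "C", c2),
        AtomRecord(3, "N1", "SPD", 1, "S", pos + [-1.0, 0, 0]),
        AtomRecord(4, "N5", "SPD", 1, "S", pos),
        AtomRecord(5, "N10", "SPD", 1, "S", pos + [1.0, 0, 0]),
    ]
    mk = lambda chain, center: Duplex(
        sequence="A", chain_i=chain, chain_ii=chain + "x",
        base_pairs=[(1, 1)], bp_center_atoms=[center],
    )
    system = MolecularSystem(atoms=atoms)
    poly = PolyamineMolecule(1, [2, 3, 4], (2, 4), 3)
    return system, poly, (mk("A", 0), mk("C", 1))


@pytest.mark.parametrize("threshold", [15.0, 19.0, 23.0, 22.0])
def test_strict_boundary_at_threshold(threshold):
    crit = dc.CageCriterion(threshold)
    for d1, d2, expected in [
        (threshold - 1.0, threshold - 1.0, True),
        (threshold - 1.0, threshold + 5.0, False),  # AND over both duplexes
        (threshold, threshold, False),  # ties go uncaged (strict <)
    ]:
        system, poly, pair = _toy_pair(d1, d2)
        got = dc.classify_caged(system.coordinates, poly, pair, crit)
        assert got is expected, (threshold, d1, d2)


def test_threshold_defaults_per_system():
    assert dc.CageCriterion.for_system("dd20").threshold == 15.0
    assert dc.CageCriterion.for_system("dd25").threshold == 19.0
    assert dc.CageCriterion.for_system("dd30").threshold == 23.0
    assert dc.CageCriterion.for_system("nucleosome").threshold == 22.0
    with pytest.raises(ValueError, match="dd20"):
        dc.CageCriterion.for_system("dd99")


def test_threshold_monotonicity(dd20_bundle):
    """Raising the threshold can only move molecules uncaged -> caged."""
    system = dd20_bundle["system"]
    frame = dd20_bundle["traj"].frames[-1]
    pair = (system.duplexes[0], system.duplexes[1])
    prev = None
    for t in np.arange(5.0, 35.0, 2.5):
        cur = {
            p.molecule_id
            for p in system.polyamines
            if dc.classify_caged(frame, p, pair, dc.CageCriterion(t), system.box)
        }
        if prev is not None:
            assert prev <= cur
        prev = cur


def test_state_series_sampling_counts(dd20_bundle):
    """21 frames at 25 ns: sampling every 25 ns keeps all 21 (t=0 included);
    every 50 ns keeps 11."""
    traj, crit = dd20_bundle["traj"], dd20_bundle["crit"]
    assert dc.state_series(traj, crit, 25.0).n_samples == 21
    assert dc.state_series(traj, crit, 50.0).n_samples == 11
    assert dc.state_series(traj, crit, 25.0, include_t0=False).n_samples == 20


def test_state_series_partition(dd20_bundle):
    traj, crit = dd20_bundle["traj"], dd20_bundle["crit"]
    series = dc.state_series(traj, crit, 25.0)
    counts = dc.caged_count_series(series)
    uncaged = (~series.states).sum(axis=0)
    assert np.all(counts + uncaged == len(traj.topology.polyamines))


def test_state_series_incommensurate_interval(dd20_bundle):
    traj, crit = dd20_bundle["traj"], dd20_bundle["crit"]
    with pytest.raises(ValueError, match="nearest valid"):
        dc.state_series(traj, crit, 30.0)


def test_single_frame_single_sample(bdna22, dd20_bundle):
    system = dd20_bundle["system"]
    traj = dc.Trajectory.single_frame(system)
    series = dc.state_series(traj, dd20_bundle["crit"], 25.0)
    assert series.n_samples == 1


def _series_from_counts(n_ac, n_au, n_mixed, n_samples=20):
    states = np.zeros((n_ac + n_au + n_mixed, n_samples), dtype=bool)
    states[:n_ac] = True
    for k in range(n_mixed):
        row = n_ac + n_au + k
        states[row, (k % (n_samples - 1)) + 1 :] = True  # enters caged late
    return dc.StateSeries(states, sample_interval=25.0)


@pytest.mark.parametrize(
    "counts,expected",
    [((11, 15, 4), 6.5), ((7, 13, 10), 2.0), ((18, 57, 25), 3.0),
     ((0, 0, 30), 0.0)],
)
def test_single_to_mixed_ratio_worked_examples(counts, expected):
    """The four published per-molecule splits give ratios 6.5 / 2.0 / 3.0 / 0."""
    summ = dc.state_summary(_series_from_counts(*counts))
    assert summ.ratio_single_to_mixed == expected
    assert summ.n_molecules == sum(counts)


def test_ratio_undefined_without_mixed_molecules():
    summ = dc.state_summary(_series_from_counts(5, 5, 0))
    assert summ.ratio_single_to_mixed is None
    assert not summ.ratio_defined


def test_state_summary_t_start_window():
    """A molecule mixed only before the burn-in counts as single-state
    once t_start excludes the early samples."""
    states = np.zeros((1, 21), dtype=bool)
    states[0, :4] = True  # caged during 0-75 ns only... then uncaged
    series = dc.StateSeries(states, sample_interval=25.0)
    assert dc.state_summary(series).n_mixed == 1
    assert dc.state_summary(series, t_start=100.0).n_always_uncaged == 1
    with pytest.raises(ValueError, match="beyond"):
        dc.state_summary(series, t_start=1000.0)


def test_caged_count_normalization():
    states = np.zeros((36, 2), dtype=bool)
    states[:36, 0] = True
    states[:12, 1] = True
    series = dc.StateSeries(states, sample_interval=25.0)
    counts = dc.caged_count_series(series, normalization=3.0)
    assert counts[0] == 12.0  # 36 caged / 3, the nucleosome convention
    assert dc.caged_count_series(series)[1] == 12.0


def test_residence_constant_and_alternating():
    const = dc.StateSeries(np.ones((1, 20), dtype=bool), 25.0)
    r = dc.residence_stats(const)
    assert r.n_transitions[0] == 0
    assert r.mean_caged_dwell[0] == 20.0
    alt = dc.StateSeries((np.arange(20) % 2 == 0)[None, :], 25.0)
    r2 = dc.residence_stats(alt)
    assert r2.n_transitions[0] == 19
    assert r2.mean_caged_dwell[0] == 1.0
    never = dc.StateSeries(np.zeros((1, 5), dtype=bool), 25.0)
    assert np.isnan(dc.residence_stats(never).mean_caged_dwell[0])


def test_segment_duplexes_excludes_linker(superhelix_mod):
    d = superhelix_mod.duplexes[0]
    seg1, seg2 = segment_duplexes(d, ((1, 67), (80, 146)))
    assert seg1.n_bp == 67 and seg2.n_bp == 67
    linker = set(d.bp_center_atoms[67:79])
    assert not linker & set(seg1.bp_center_atoms)
    assert not linker & set(seg2.bp_center_atoms)
    # phosphate slices follow the bp ranges on both strands
    assert len(seg1.phosphate_P[d.chain_i]) == 66  # residues 2..67
    assert len(seg2.phosphate_P[d.chain_i]) == 67  # residues 80..146


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
    st.integers(2, 8),
)
def test_state_summary_partition_property(n_ac, n_au, n_mixed, n_samples):
    """Counts always partition the molecules; the ratio follows its
    defining formula whenever mixed molecules exist."""
    if n_ac + n_au + n_mixed == 0:
        return
    series = _series_from_counts(n_ac, n_au, n_mixed, n_samples)
    summ = dc.state_summary(series)
    assert summ.n_always_caged + summ.n_always_uncaged + summ.n_mixed \
        == series.n_molecules
    if summ.n_mixed:
        assert summ.ratio_single_to_mixed == pytest.approx(
            (summ.n_always_caged + summ.n_always_uncaged) / summ.n_mixed
        )
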
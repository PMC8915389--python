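"""Caged/uncaged classification of polyamines between parallel DNA helices.

A polyamine is *caged* when its central amino nitrogen lies within a
system-specific threshold distance of at least one base-pair center of
*each* of the two parallel duplexes (strict ``<`` at the threshold; ties
count as uncaged).  From the per-sample state matrix the module derives
the caged-count evolution, the single-state / mixed-state ratio, and
residence statistics on the sampled two-state chain.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Duplex, MolecularSystem, PolyamineMolecule, Trajectory, minimum_image_vectors

__all__ = [
    "CageCriterion",
    "StateSeries",
    "StateSummary",
    "ResidenceStats",
    "classify_caged",
    "state_series",
    "state_summary",
    "caged_count_series",
    "residence_stats",
    "segment_duplexes",
]


@dataclass(frozen=True)
class CageCriterion:
    """Caging distance threshold (Angstrom) for one system geometry.

    Defaults reflect the axis separations studied: 15 A at 20 A separation,
    19 A at 25 A, 23 A at 30 A, and 22 A for the nucleosomal gyre pair.
    """

    threshold: float
    system_tag: str = ""

    DEFAULTS = {"dd20": 15.0, "dd25": 19.0, "dd30": 23.0, "nucleosome": 22.0}

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("caging threshold must be positive")

    @classmethod
    def for_system(cls, tag: str) -> "CageCriterion":
        try:
            return cls(cls.DEFAULTS[tag], tag)
        except KeyError:
            raise ValueError(
                f"no default threshold for system '{tag}'; "
                f"known: {sorted(cls.DEFAULTS)}"
            ) from None


@dataclass
class StateSeries:
    """Per-molecule caged(True)/uncaged(False) matrix at uniform sampling."""

    states: np.ndarray  # (n_molecules, n_samples) bool
    sample_interval: float  # ns
    molecule_ids: list[int] = field(default_factory=list)
    times: np.ndarray | None = None  # ns, sample times

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.ndim != 2:
            raise ValueError("states must be a (molecule x sample) matrix")
        if not self.molecule_ids:
            self.molecule_ids = list(range(1, self.states.shape[0] + 1))
        if self.times is None:
            self.times = np.arange(self.states.shape[1]) * self.sample_interval
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_molecules(self) -> int:
        return self.states.shape[0]

    @property
    def n_samples(self) -> int:
        return self.states.shape[1]


@dataclass
class StateSummary:
    """Molecule-level occupancy classes over the analyzed window."""

    n_always_caged: int
    n_always_uncaged: int
    n_mixed: int
    ratio_single_to_mixed: float | None  # None when n_mixed == 0 (undefined)
    normalization_factor: float = 1.0
    t_start: float = 0.0

    @property
    def n_molecules(self) -> int:
        return self.n_always_caged + self.n_always_uncaged + self.n_mixed

    @property
    def ratio_defined(self) -> bool:
        return self.ratio_single_to_mixed is not None


def _min_center_distance(
    coords: np.ndarray,
    central_n: int,
    duplex: Duplex,
    box: np.ndarray | None,
) -> float:
    centers = coords[np.asarray(duplex.bp_center_atoms, dtype=int)]
    vecs = minimum_image_vectors(centers - coords[central_n], box)
    return float(np.min(np.linalg.norm(vecs, axis=1)))


def classify_caged(
    frame: np.ndarray,
    polyamine: PolyamineMolecule,
    duplexes: tuple[Duplex, Duplex],
    crit: CageCriterion,
    box: np.ndarray | None = None,
) -> bool:
    """True iff the central N is strictly within the threshold of at least
    one bp center of *both* duplexes (segment pair for the nucleosome)."""
    if len(duplexes) != 2:
        raise ValueError("caging requires exactly two duplexes (or segments)")
    if polyamine.central_N is None:  # defensive; dataclass normally forbids
        raise ValueError(f"polyamine {polyamine.molecule_id}: central N missing")
    frame = np.asarray(frame, dtype=float)
    return all(
        _min_center_distance(frame, polyamine.central_N, d, box) < crit.threshold
        for d in duplexes
    )


def _cage_duplexes(system: MolecularSystem) -> tuple[Duplex, Duplex]:
    if len(system.duplexes) == 2:
        return (system.duplexes[0], system.duplexes[1])
    if len(system.duplexes) == 1 and system.duplexes[0].n_bp >= 100:
        return segment_duplexes(system.duplexes[0])
    raise ValueError(
        "cannot infer the duplex pair for caging; pass `duplexes=` explicitly"
    )


def state_series(
    traj: Trajectory,
    crit: CageCriterion,
    sample_interval: float,
    duplexes: tuple[Duplex, Duplex] | None = None,
    include_t0: bool = True,
) -> StateSeries:
    """Classify every polyamine at every sampled frame.

    ``sample_interval`` (ns) must be a multiple of the trajectory frame
    spacing.  Samples run ``t = 0, dt, 2 dt, ...`` inclusive of t=0 by
    default (set ``include_t0=False`` to start at the first interval).
    """
    if duplexes is None:
        duplexes = _cage_duplexes(traj.topology)
    times = traj.times
    if traj.n_frames == 1:
        stride, start = 1, 0
    else:
        frame_dt = float(times[1] - times[0])
        ratio = sample_interval / frame_dt
        stride = int(round(ratio))
        if stride < 1 or abs(ratio - stride) > 1e-6:
            raise ValueError(
                f"sample interval {sample_interval} ns is not a multiple of the "
                f"frame interval {frame_dt} ns; nearest valid value: "
                f"{max(1, stride) * frame_dt} ns"
            )
        start = 0 if include_t0 else stride
    idx = np.arange(start, traj.n_frames, stride)
    box = traj.topology.box
    polys = traj.topology.polyamines
    states = np.zeros((len(polys), idx.size), dtype=bool)
    for js, j in enumerate(idx):
        frame = traj.frames[j]
        for ip, p in enumerate(polys):
            states[ip, js] = classify_caged(frame, p, duplexes, crit, box)
    return StateSeries(
        states,
        sample_interval=sample_interval,
        molecule_ids=[p.molecule_id for p in polys],
        times=times[idx],
    )


def state_summary(
    series: StateSeries,
    normalization: float = 1.0,
    t_start: float = 0.0,
) -> StateSummary:
    """Classify molecules as always-caged / always-uncaged / mixed over the
    samples with ``t >= t_start`` and form the single-to-mixed ratio.

    The ratio is ``(n_always_caged + n_always_uncaged) / n_mixed``; it is 0
    when no molecule is single-state, and *undefined* (None) when no
    molecule is mixed.
    """
    if series.n_samples == 0:
        raise ValueError("empty state series")
    if t_start > series.times[-1]:
        raise ValueError(
            f"t_start={t_start} ns is beyond the last sample at "
            f"{series.times[-1]} ns"
        )
    window = series.states[:, series.times >= t_start]
    caged_counts = window.sum(axis=1)
    n_samp = window.shape[1]
    n_ac = int(np.sum(caged_counts == n_samp))
    n_au = int(np.sum(caged_counts == 0))
    n_mixed = window.shape[0] - n_ac - n_au
    if n_mixed > 0:
        ratio = (n_ac + n_au) / n_mixed
    else:
        ratio = None
    return StateSummary(
        n_always_caged=n_ac,
        n_always_uncaged=n_au,
        n_mixed=n_mixed,
        ratio_single_to_mixed=ratio,
        normalization_factor=normalization,
        t_start=t_start,
    )


def caged_count_series(
    series: StateSeries, normalization: float = 1.0
) -> np.ndarray:
    """Number of caged molecules per sample time, divided by
    ``normalization`` (3 for the nucleosome-to-22mer comparison)."""
    counts = series.states.sum(axis=0).astype(float)
    return counts / normalization


@dataclass
class ResidenceStats:
    """Residence statistics on the sampled two-state chain (units: samples)."""

    n_transitions: np.ndarray  # per molecule
    mean_caged_dwell: np.ndarray  # per molecule; NaN if never caged
    transition_probability: float  # pooled per-step flip probability

    @property
    def total_transitions(self) -> int:
        return int(self.n_transitions.sum())


def residence_stats(series: StateSeries) -> ResidenceStats:
    """Per-molecule caged-dwell lengths and caged<->uncaged transition counts.

    Dwell lengths are maximal runs of consecutive caged samples, in units of
    the sample interval; transitions are state flips between consecutive
    samples.  The pooled transition probability is
    ``total flips / (n_molecules * (n_samples - 1))``.
    """
    if series.n_samples < 2:
        raise ValueError("residence statistics require at least 2 samples")
    s = series.states
    flips = s[:, 1:] != s[:, :-1]
    n_trans = flips.sum(axis=1)
    dwells = np.full(s.shape[0], np.nan)
    for i in range(s.shape[0]):
        runs = _run_lengths(s[i])
        if runs:
            dwells[i] = float(np.mean(runs))
    p = float(flips.sum()) / (s.shape[0] * (s.shape[1] - 1))
    return ResidenceStats(n_trans, dwells, p)


def _run_lengths(row: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a boolean vector."""
    runs, count = [], 0
    for v in row:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def segment_duplexes(
    duplex: Duplex,
    ranges: tuple[tuple[int, int], tuple[int, int]] = ((1, 67), (80, 146)),
) -> tuple[Duplex, Duplex]:
    """Split one long duplex into two pseudo-duplexes (1-based bp ranges,
    inclusive), e.g. the parallel gyres of nucleosomal DNA; bps between the
    ranges are excluded from every bp-center list."""
    n = duplex.n_bp
    out = []
    for lo, hi in ranges:
        if not (1 <= lo < hi <= n):
            raise ValueError(f"bp range {lo}-{hi} invalid for a {n}-bp duplex")
        sl = slice(lo - 1, hi)
        # strand II residues paired to bps lo..hi, and their phosphates:
        # residue r on strand s has a phosphate iff r >= 2 (list index r-2)
        pP, pO1, pO2 = {}, {}, {}
        for strand, (rlo, rhi) in (
            (duplex.chain_i, (lo, hi)),
            (duplex.chain_ii, (n + 1 - hi, n + 1 - lo)),
        ):
            a, b = max(rlo, 2) - 2, rhi - 1
            pP[strand] = duplex.phosphate_P.get(strand, [])[a:b]
            pO1[strand] = duplex.phosphate_O1P.get(strand, [])[a:b]
            pO2[strand] = duplex.phosphate_O2P.get(strand, [])[a:b]
        out.append(
            Duplex(
                sequence=duplex.sequence[sl],
                chain_i=duplex.chain_i,
                chain_ii=duplex.chain_ii,
                base_pairs=duplex.base_pairs[sl],
                bp_center_atoms=duplex.bp_center_atoms[sl],
                phosphate_P=pP,
                phosphate_O1P=pO1,
                phosphate_O2P=pO2,
                atom_ids=duplex.atom_ids,
            )
        )
    return (out[0], out[1])
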
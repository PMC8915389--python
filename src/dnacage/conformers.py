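"""Polyamine conformational state and DNA-DNA bridging interaction modes.

End-to-end distance (EE) between the terminal amino nitrogens classifies a
polyamine as folded (EE < 7 A), intermediate, or elongated (EE > 9 A).
Bridges are amino-N to phosphate-O contacts spanning the two duplexes,
detected on heavy-atom distances (no hydrogens required).  A bridging
molecule is labelled ``pp`` (parallel-perpendicular) when it is elongated
and its principal axis is parallel to one backbone and perpendicular to
the other, ``c_shape`` when it bridges while folded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .caging import StateSeries
from .model import (
    Duplex,
    MolecularSystem,
    PolyamineMolecule,
    Trajectory,
    minimum_image_vectors,
)

__all__ = [
    "ConformerThresholds",
    "BridgeContact",
    "ModeLabel",
    "end_to_end",
    "classify_conformer",
    "ee_distribution",
    "detect_bridges",
    "classify_mode",
]

CONFORMER_STATES = ("folded", "intermediate", "elongated")


@dataclass(frozen=True)
class ConformerThresholds:
    folded_max: float = 7.0  # Angstrom
    elongated_min: float = 9.0

    def __post_init__(self):
        if not self.folded_max < self.elongated_min:
            raise ValueError("folded_max must be < elongated_min")


def end_to_end(
    polyamine: PolyamineMolecule,
    frame: np.ndarray,
    box: np.ndarray | None = None,
) -> float:
    """Distance between the terminal nitrogens (minimum image if periodic)."""
    frame = np.asarray(frame, float)
    i, j = polyamine.terminal_N
    vec = minimum_image_vectors(frame[j] - frame[i], box)
    return float(np.linalg.norm(vec))


def classify_conformer(ee: float, thr: ConformerThresholds = ConformerThresholds()) -> str:
    if ee < 0:
        raise ValueError("end-to-end distance must be >= 0")
    if ee < thr.folded_max:
        return "folded"
    if ee > thr.elongated_min:
        return "elongated"
    return "intermediate"


@dataclass
class EEDistribution:
    """Conformer fractions partitioned by caged state.

    ``fractions[state]`` maps conformer -> fraction (sums to 1); a caged
    state with no molecule-samples is absent from the dict, never 0/0.
    """

    fractions: dict[str, dict[str, float]]
    counts: dict[str, dict[str, int]]
    n_samples: int


def ee_distribution(
    traj: Trajectory,
    series: StateSeries,
    thr: ConformerThresholds = ConformerThresholds(),
) -> EEDistribution:
    """Conformer fractions over molecule-samples, split caged/uncaged.

    The state series must be sampled on trajectory frame times; each
    molecule-sample lands in exactly one caged-state partition.
    """
    frame_idx = []
    for t in series.times:
        hits = np.flatnonzero(np.isclose(traj.times, t))
        if hits.size != 1:
            raise ValueError(
                f"state sample at t={t} ns has no matching trajectory frame"
            )
        frame_idx.append(int(hits[0]))
    box = traj.topology.box
    counts = {
        "caged": dict.fromkeys(CONFORMER_STATES, 0),
        "uncaged": dict.fromkeys(CONFORMER_STATES, 0),
    }
    for js, jf in enumerate(frame_idx):
        frame = traj.frames[jf]
        for ip, p in enumerate(traj.topology.polyamines):
            state = "caged" if series.states[ip, js] else "uncaged"
            conf = classify_conformer(end_to_end(p, frame, box), thr)
            counts[state][conf] += 1
    fractions = {}
    for state, c in counts.items():
        total = sum(c.values())
        if total:
            fractions[state] = {k: v / total for k, v in c.items()}
    return EEDistribution(fractions, counts, n_samples=len(frame_idx))


@dataclass
class BridgeContact:
    """One bridging contact between a polyamine and both duplexes.

    ``kind`` is ``"single_N"`` (one amino N touches phosphate oxygens of
    both duplexes) or ``"molecule"`` (two amino N of the same molecule each
    touch a different duplex).  Contacts are (O atom index, N-O distance)
    pairs, one list per duplex.
    """

    molecule_id: int
    kind: str
    amino_N: tuple[int, ...]
    contacts_d1: list[tuple[int, float]]
    contacts_d2: list[tuple[int, float]]
    frame_index: int = 0

    def __post_init__(self):
        if not self.contacts_d1 or not self.contacts_d2:
            raise ValueError("a bridge needs contacted oxygens on both duplexes")


def _phosphate_O_ids(duplex: Duplex) -> np.ndarray:
    ids = []
    for d in (duplex.phosphate_O1P, duplex.phosphate_O2P):
        for v in d.values():
            ids.extend(v)
    return np.asarray(sorted(ids), dtype=int)


def _n_contacts(frame, n_id, o_ids, cutoff, box):
    vecs = minimum_image_vectors(frame[o_ids] - frame[n_id], box)
    d = np.linalg.norm(vecs, axis=1)
    hit = d <= cutoff
    return [(int(o), float(x)) for o, x in zip(o_ids[hit], d[hit])]


def detect_bridges(
    frame: np.ndarray,
    system: MolecularSystem,
    duplexes: tuple[Duplex, Duplex] | None = None,
    cutoff: float = 3.5,
    frame_index: int = 0,
) -> list[BridgeContact]:
    """All polyamine bridges between the two duplexes in one frame.

    The 3.5 A N...O cutoff is the standard heavy-atom hydrogen-bond
    distance; it stands in for the O-HNH-O contact without needing
    hydrogen positions.
    """
    if duplexes is None:
        if len(system.duplexes) != 2:
            raise ValueError("pass duplexes= when the system is not a duplex pair")
        duplexes = (system.duplexes[0], system.duplexes[1])
    frame = np.asarray(frame, float)
    box = system.box
    o1 = _phosphate_O_ids(duplexes[0])
    o2 = _phosphate_O_ids(duplexes[1])
    bridges = []
    for p in system.polyamines:
        per_n = {}
        for n_id in p.amino_N:
            per_n[n_id] = (
                _n_contacts(frame, n_id, o1, cutoff, box),
                _n_contacts(frame, n_id, o2, cutoff, box),
            )
        single = False
        for n_id, (c1, c2) in per_n.items():
            if c1 and c2:
                bridges.append(
                    BridgeContact(p.molecule_id, "single_N", (n_id,), c1, c2,
                                  frame_index)
                )
                single = True
        if not single:
            ns1 = [n for n, (c1, _) in per_n.items() if c1]
            ns2 = [n for n, (_, c2) in per_n.items() if c2]
            spanning = [(a, b) for a in ns1 for b in ns2 if a != b]
            if spanning:
                a, b = spanning[0]
                bridges.append(
                    BridgeContact(
                        p.molecule_id, "molecule", (a, b),
                        per_n[a][0], per_n[b][1], frame_index,
                    )
                )
    return bridges


@dataclass
class ModeLabel:
    """Deterministic interaction-mode label with its supporting geometry."""

    label: str  # "pp", "c_shape", or "other"
    ee: float
    conformer: str
    bridged: bool
    backbone_angles: tuple[float, float] | None = None  # deg, per duplex
    angle_gates: tuple[float, float] = (30.0, 60.0)


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(np.cov(centered.T))
    return vecs[:, -1]  # leading eigenvector


def _backbone_tangent(frame, duplex: Duplex, near_point, box) -> np.ndarray:
    """Unit vector between the P atoms two residues up/downstream of the
    phosphate nearest to ``near_point``."""
    best = None
    for chain, plist in duplex.phosphate_P.items():
        ids = np.asarray(plist, int)
        if ids.size == 0:
            continue
        d = np.linalg.norm(
            minimum_image_vectors(frame[ids] - near_point, box), axis=1
        )
        k = int(np.argmin(d))
        if best is None or d[k] < best[0]:
            best = (float(d[k]), ids, k)
    _, ids, k = best
    a = ids[max(0, k - 2)]
    b = ids[min(ids.size - 1, k + 2)]
    vec = minimum_image_vectors(frame[b] - frame[a], box)
    return vec / np.linalg.norm(vec)


def _axis_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between undirected axes, in [0, 90] degrees."""
    c = abs(float(np.dot(u, v))) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def classify_mode(
    polyamine: PolyamineMolecule,
    frame: np.ndarray,
    system: MolecularSystem,
    duplexes: tuple[Duplex, Duplex] | None = None,
    thr: ConformerThresholds = ConformerThresholds(),
    cutoff: float = 3.5,
    angle_parallel: float = 30.0,
    angle_perpendicular: float = 60.0,
) -> ModeLabel:
    """Interaction-mode label for one molecule in one frame.

    ``pp``: elongated, bridging, principal axis within ``angle_parallel``
    of one backbone tangent and beyond ``angle_perpendicular`` of the
    other.  ``c_shape``: folded and bridging.  Everything else: ``other``.
    """
    if duplexes is None:
        if len(system.duplexes) != 2:
            raise ValueError("pass duplexes= when the system is not a duplex pair")
        duplexes = (system.duplexes[0], system.duplexes[1])
    frame = np.asarray(frame, float)
    box = system.box
    ee = end_to_end(polyamine, frame, box)
    conformer = classify_conformer(ee, thr)
    gates = (angle_parallel, angle_perpendicular)
    bridges = [
        b
        for b in detect_bridges(frame, system, duplexes, cutoff)
        if b.molecule_id == polyamine.molecule_id
    ]
    if not bridges:
        return ModeLabel("other", ee, conformer, False, None, gates)
    if conformer == "folded":
        return ModeLabel("c_shape", ee, conformer, True, None, gates)
    axis = _principal_axis(frame[np.asarray(polyamine.atom_ids)])
    centroid = frame[np.asarray(polyamine.atom_ids)].mean(axis=0)
    angles = tuple(
        _axis_angle(axis, _backbone_tangent(frame, d, centroid, box))
        for d in duplexes
    )
    if conformer == "elongated" and (
        (angles[0] <= angle_parallel and angles[1] >= angle_perpendicular)
        or (angles[1] <= angle_parallel and angles[0] >= angle_perpendicular)
    ):
        return ModeLabel("pp", ee, conformer, True, angles, gates)
    return ModeLabel("other", ee, conformer, True, angles, gates)
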
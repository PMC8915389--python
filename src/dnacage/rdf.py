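"""Radial distribution functions and coordination numbers.

The RDF follows the standard pair-distribution normalization

    g(r) = p(r) / (4 pi r^2 dr) / (N_p / V)

where p(r) is the average per-shell pair count, N_p the number of selected
atom pairs, and V the cell volume; the stored per-shell counts are
normalized per sel_A atom so that their cumulative sum up to a cutoff is
directly the coordination number (mean neighbour count of an A atom).
Bin width defaults to 0.1 A.  A pair exactly at an integration cutoff
counts inside (closed upper edge).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Duplex, RegionSelection, Trajectory, minimum_image_vectors

__all__ = [
    "RDFResult",
    "CNProfile",
    "RDFDDResult",
    "compute_rdf",
    "coordination_number",
    "per_residue_cn",
    "rdf_dd",
]

_EDGE_EPS = 1e-9


@dataclass
class RDFResult:
    """Binned g(r) plus the raw quantities it is normalized from."""

    r_edges: np.ndarray  # (n_bins + 1,), uniform width dr
    g: np.ndarray  # (n_bins,)
    p_counts: np.ndarray  # average neighbours of one sel_A atom per shell
    n_pairs: int  # N_p: |A|*|B| minus self-pairs
    volume: float  # V, Angstrom^3
    n_A: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r_edges = np.asarray(self.r_edges, float)
        self.g = np.asarray(self.g, float)
        self.p_counts = np.asarray(self.p_counts, float)
        if self.g.size != self.r_edges.size - 1:
            raise ValueError("len(g) must equal len(r_edges) - 1")

    @property
    def dr(self) -> float:
        return float(self.r_edges[1] - self.r_edges[0])

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    def recompute_g(self) -> np.ndarray:
        """g(r) from the stored p(r), N_p and V (self-consistency check)."""
        shell = 4.0 * np.pi * self.r_mid**2 * self.dr
        return self.p_counts * self.n_A * self.volume / (shell * self.n_pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r_mid": self.r_mid, "g": self.g, "p": self.p_counts}
        )


@dataclass
class CNProfile:
    """Per-base-pair (or per-residue) coordination numbers."""

    values: np.ndarray
    r_cut: float
    region_tag: str
    labels: list[str] = field(default_factory=list)
    defined: np.ndarray | None = None  # False where the region was empty

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.defined is None:
            self.defined = np.ones(self.values.size, dtype=bool)
        if np.any(self.values[self.defined] < 0):
            raise ValueError("coordination numbers must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(1, self.values.size + 1),
                "label": self.labels or [""] * self.values.size,
                "cn": self.values,
                "defined": self.defined,
            }
        )


def _volume(traj: Trajectory) -> float:
    box = traj.topology.box
    if box is not None:
        return float(np.prod(box))
    warnings.warn(
        "no periodic box; using the trajectory bounding-box volume for "
        "RDF normalization"
    )
    lo = traj.frames.min(axis=(0, 1))
    hi = traj.frames.max(axis=(0, 1))
    return float(np.prod(hi - lo))


def compute_rdf(
    traj: Trajectory,
    sel_A: RegionSelection,
    sel_B: RegionSelection,
    dr: float = 0.1,
    r_max: float | None = None,
) -> RDFResult:
    """Time-averaged RDF between two atom selections.

    Self-pairs are excluded when the selections overlap.  ``r_max`` defaults
    to half the shortest box edge (periodic) or 20 A (non-periodic).
    """
    box = traj.topology.box
    if r_max is None:
        r_max = float(np.min(box) / 2.0) if box is not None else 20.0
    if box is not None and r_max > np.min(box) / 2.0 + _EDGE_EPS:
        raise ValueError(
            f"r_max={r_max} exceeds half the shortest box edge "
            f"({np.min(box) / 2.0:.2f} A)"
        )
    ids_a, ids_b = sel_A.atom_ids, sel_B.atom_ids
    shared = np.intersect1d(ids_a, ids_b)
    n_pairs = ids_a.size * ids_b.size - shared.size
    if n_pairs < 1:
        raise ValueError("selections define no distinct atom pairs")
    n_bins = int(round(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    hist = np.zeros(n_bins)
    self_mask = ids_a[:, None] == ids_b[None, :] if shared.size else None
    for frame in traj.frames:
        vecs = frame[ids_b][None, :, :] - frame[ids_a][:, None, :]
        d = np.linalg.norm(minimum_image_vectors(vecs, box), axis=-1)
        if self_mask is not None:
            d = d[~self_mask]
        hist += np.histogram(d, bins=edges)[0]
    p_counts = hist / (traj.n_frames * ids_a.size)
    volume = _volume(traj)
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * r_mid**2 * dr
    g = p_counts * ids_a.size * volume / (shell * n_pairs)
    return RDFResult(
        r_edges=edges,
        g=g,
        p_counts=p_counts,
        n_pairs=int(n_pairs),
        volume=volume,
        n_A=int(ids_a.size),
        meta={"sel_A": sel_A.region_tag, "sel_B": sel_B.region_tag},
    )


def coordination_number(rdf: RDFResult, r_cut: float) -> float:
    """CN = cumulative per-A-atom neighbour count up to ``r_cut`` (direct
    integration of the RDF; closed upper edge at the cutoff)."""
    if r_cut > rdf.r_edges[-1] + _EDGE_EPS:
        raise ValueError(
            f"r_cut={r_cut} beyond the histogram range {rdf.r_edges[-1]}"
        )
    if r_cut < rdf.r_edges[1] - _EDGE_EPS:
        warnings.warn(f"r_cut={r_cut} below the first bin; CN is 0")
        return 0.0
    inside = rdf.r_edges[1:] <= r_cut + _EDGE_EPS
    return float(rdf.p_counts[inside].sum())


def _pair_count_within(
    frames: np.ndarray, ids_a, ids_b, r_cut, box
) -> float:
    """Frame-averaged number of (A, B) pairs with distance <= r_cut."""
    total = 0.0
    for frame in frames:
        vecs = frame[ids_b][None, :, :] - frame[ids_a][:, None, :]
        d = np.linalg.norm(minimum_image_vectors(vecs, box), axis=-1)
        total += np.count_nonzero(d <= r_cut + _EDGE_EPS)
    return total / frames.shape[0]


def per_residue_cn(
    traj: Trajectory,
    polyamine_heavy: RegionSelection,
    duplexes: Duplex | list[Duplex],
    region_tag: str,
    r_cut: float = 4.55,
) -> CNProfile:
    """Per-base-pair coordination number of polyamine heavy atoms around a
    groove/backbone region (default integration cutoff 4.55 A).

    The CN of bp *i* is the frame-averaged count of (region atom of bp i,
    polyamine heavy atom) pairs within the cutoff.  When several duplexes
    are passed, the per-duplex profiles are averaged position-wise
    (profiles, not selections, are pooled).
    """
    from .model import region_atoms_by_bp

    if region_tag not in ("minor", "major", "phosphate"):
        raise ValueError(
            "per-residue CN regions are 'minor', 'major' or 'phosphate'"
        )
    if isinstance(duplexes, Duplex):
        duplexes = [duplexes]
    box = traj.topology.box
    ids_b = polyamine_heavy.atom_ids
    profiles = []
    defined_all = []
    for duplex in duplexes:
        per_bp = region_atoms_by_bp(traj.topology, duplex, region_tag)
        vals = np.zeros(len(per_bp))
        defined = np.ones(len(per_bp), dtype=bool)
        for i, ids_a in enumerate(per_bp):
            if ids_a.size == 0:
                defined[i] = False
                continue
            vals[i] = _pair_count_within(traj.frames, ids_a, ids_b, r_cut, box)
        if not defined.all():
            warnings.warn(
                f"region '{region_tag}' empty on base pairs "
                f"{list(np.flatnonzero(~defined) + 1)}; CN reported as 0"
            )
        profiles.append(vals)
        defined_all.append(defined)
    values = np.mean(profiles, axis=0)
    defined = np.logical_and.reduce(defined_all)
    d0 = duplexes[0]
    labels = [
        f"{d0.sequence[i]}-{_complement(d0.sequence[i])}"
        for i in range(d0.n_bp)
    ]
    return CNProfile(values, r_cut, region_tag, labels, defined)


def _complement(b: str) -> str:
    return {"A": "T", "T": "A", "G": "C", "C": "G"}[b]


@dataclass
class RDFDDResult:
    """Inter-duplex phosphate RDF with its contact-site statistics."""

    rdf: RDFResult  # averaged over the two directions
    cn_total: float  # per-P CN up to r_cut_total
    per_nucleotide: pd.DataFrame  # columns: duplex, chain, residue, cn
    r_cut_total: float
    r_cut_per_P: float


def rdf_dd(
    traj: Trajectory,
    duplex1: Duplex,
    duplex2: Duplex,
    dr: float = 0.1,
    r_max: float | None = None,
    r_cut_total: float = 6.4,
    r_cut_per_P: float = 6.5,
) -> RDFDDResult:
    """RDF between the backbone P atoms of two duplexes, averaged over the
    two directions, plus per-nucleotide contact CNs (cutoff 6.5 A) locating
    the close DNA-DNA contact sites."""
    p1 = np.concatenate([np.asarray(v, int) for v in duplex1.phosphate_P.values()])
    p2 = np.concatenate([np.asarray(v, int) for v in duplex2.phosphate_P.values()])
    if duplex1 is duplex2 or np.array_equal(np.sort(p1), np.sort(p2)):
        raise ValueError("rdf_dd requires two distinct duplexes")
    sel1 = RegionSelection("P", p1)
    sel2 = RegionSelection("P", p2)
    r12 = compute_rdf(traj, sel1, sel2, dr=dr, r_max=r_max)
    r21 = compute_rdf(traj, sel2, sel1, dr=dr, r_max=r_max)
    avg = RDFResult(
        r_edges=r12.r_edges,
        g=0.5 * (r12.g + r21.g),
        p_counts=0.5 * (r12.p_counts + r21.p_counts),
        n_pairs=r12.n_pairs,
        volume=r12.volume,
        n_A=r12.n_A,
        meta={"sel_A": "P(DNA1)", "sel_B": "P(DNA2)", "averaged": True},
    )
    cn_total = coordination_number(avg, r_cut_total)
    box = traj.topology.box
    rows = []
    for tag, duplex, other_ids in (
        ("DNA1", duplex1, p2),
        ("DNA2", duplex2, p1),
    ):
        for chain, plist in duplex.phosphate_P.items():
            for k, pid in enumerate(plist):
                cn = _pair_count_within(
                    traj.frames, np.array([pid]), other_ids, r_cut_per_P, box
                )
                rows.append(
                    {"duplex": tag, "chain": chain, "residue": k + 2, "cn": cn}
                )
    return RDFDDResult(
        rdf=avg,
        cn_total=cn_total,
        per_nucleotide=pd.DataFrame(rows),
        r_cut_total=r_cut_total,
        r_cut_per_P=r_cut_per_P,
    )
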
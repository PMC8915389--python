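"""Domain types for DNA/polyamine systems and region selections.

The containers here are deliberately light: coordinates live in plain numpy
arrays, atoms are flat records, and duplexes/polyamines hold *indices* into
the system's atom table.  All distances are in Angstrom, all times in ns.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "Duplex",
    "PolyamineMolecule",
    "MolecularSystem",
    "Trajectory",
    "RegionSelection",
    "REGION_TAGS",
    "WATSON_CRICK",
    "complement",
    "select_region",
    "region_atoms_by_bp",
    "minimum_image_vectors",
]

#: Watson-Crick pairing over the one-letter alphabet.
WATSON_CRICK = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Atom-name sets defining the groove/backbone regions of the double helix.
#: Minor groove: base edge atoms N3 (purines), N2 (G), O2 (pyrimidines).
#: Major groove: C8, N7, C5 (purines), O6 (G), N4 (C), C5, C6 (pyrimidines);
#: the C5 entry covers both purine and pyrimidine C5 atoms.
REGION_ATOM_NAMES = {
    "minor": {"N3", "N2", "O2"},
    "major": {"C8", "N7", "C5", "O6", "N4", "C6"},
    "phosphate": {"O1P", "O2P"},
    "P": {"P"},
}

REGION_TAGS = ("minor", "major", "phosphate", "P", "bp_center", "polyamine_heavy")

PURINES = {"A", "G"}


def complement(base: str) -> str:
    return WATSON_CRICK[base]


@dataclass
class AtomRecord:
    """One atom of the system (PDB naming conventions)."""

    atom_id: int
    atom_name: str
    residue_name: str
    residue_index: int  # 1-based, per chain, 5'->3' for DNA strands
    chain_id: str
    xyz: np.ndarray  # (3,) Angstrom

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_id}")


@dataclass
class Duplex:
    """A DNA double helix (or one parallel segment of a larger molecule).

    ``sequence`` is strand I read 5'->3'.  ``base_pairs`` lists, per bp,
    the (strand-I residue index, strand-II residue index); residue indices
    are 1-based within each chain.  ``bp_center_atoms`` holds one atom index
    per bp (the purine N1 by default).  Phosphate atom indices are stored
    per strand, 5'->3' (the 5'-terminal residue carries no phosphate).
    """

    sequence: str
    chain_i: str
    chain_ii: str
    base_pairs: list[tuple[int, int]]
    bp_center_atoms: list[int]
    phosphate_P: dict[str, list[int]] = field(default_factory=dict)
    phosphate_O1P: dict[str, list[int]] = field(default_factory=dict)
    phosphate_O2P: dict[str, list[int]] = field(default_factory=dict)
    atom_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        if len(self.base_pairs) != len(self.sequence):
            raise ValueError("base_pairs and sequence lengths differ")
        bad = [b for b in self.sequence if b not in WATSON_CRICK]
        if bad:
            raise ValueError(f"non-ACGT bases in duplex sequence: {bad}")

    @property
    def n_bp(self) -> int:
        return len(self.base_pairs)


@dataclass
class PolyamineMolecule:
    """A spermidine(3+) molecule: N1-(CH2)3-N5-(CH2)4-N10."""

    molecule_id: int
    atom_ids: list[int]
    terminal_N: tuple[int, int]
    central_N: int
    formal_charge: int = 3

    def __post_init__(self):
        if self.central_N in self.terminal_N:
            raise ValueError(
                f"polyamine {self.molecule_id}: central N coincides with a terminal N"
            )

    @property
    def amino_N(self) -> tuple[int, int, int]:
        """All three (protonated) amino nitrogens."""
        return (self.terminal_N[0], self.central_N, self.terminal_N[1])


@dataclass
class MolecularSystem:
    """Atoms + topology annotations + ion/water bookkeeping.

    ``box`` is an orthorhombic cell (3 lengths, Angstrom) or None for
    non-periodic fixtures.  Water is counted, never instantiated.
    """

    atoms: list[AtomRecord]
    duplexes: list[Duplex] = field(default_factory=list)
    polyamines: list[PolyamineMolecule] = field(default_factory=list)
    n_K: int = 0
    n_Cl: int = 0
    n_water: int = 0
    box: np.ndarray | None = None

    def __post_init__(self):
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def n_phosphates(self) -> int:
        return sum(
            len(idx) for d in self.duplexes for idx in d.phosphate_P.values()
        )

    def net_charge(self) -> int:
        """Formal charge: -1 per phosphate, +3 per polyamine, +1/-1 per K/Cl."""
        return (
            -self.n_phosphates()
            + sum(p.formal_charge for p in self.polyamines)
            + self.n_K
            - self.n_Cl
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # ns, strictly increasing
    topology: MolecularSystem

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("frames and times lengths differ")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology atom "
                f"count {self.topology.n_atoms}"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @classmethod
    def single_frame(cls, system: MolecularSystem, time: float = 0.0) -> "Trajectory":
        return cls(system.coordinates[None, :, :], np.array([time]), system)


@dataclass
class RegionSelection:
    """A tagged set of atom indices used as RDF/contact reference atoms."""

    region_tag: str
    atom_ids: np.ndarray

    def __post_init__(self):
        self.atom_ids = np.asarray(self.atom_ids, dtype=int)
        if self.atom_ids.size == 0:
            raise ValueError(f"empty selection for region '{self.region_tag}'")

    def __len__(self) -> int:
        return self.atom_ids.size


def minimum_image_vectors(vecs: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Orthorhombic cells only; with ``box=None`` the vectors pass through
    unchanged (non-periodic fixture).
    """
    if box is None:
        return vecs
    return vecs - box * np.round(vecs / box)


def _duplex_atom_index(system: MolecularSystem, duplex: Duplex):
    """Map (chain, residue_index) -> {atom_name: atom table index}."""
    wanted = {duplex.chain_i, duplex.chain_ii}
    table: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(system.atoms):
        if a.chain_id in wanted:
            table.setdefault((a.chain_id, a.residue_index), {})[a.atom_name] = i
    return table


def region_atoms_by_bp(
    system: MolecularSystem, duplex: Duplex, region_tag: str
) -> list[np.ndarray]:
    """Per-base-pair atom indices for a groove/backbone region.

    For ``minor``/``major`` the atoms of both residues of the pair are
    pooled; for ``phosphate``/``P`` the backbone atoms of both paired
    residues are pooled (terminal residues may contribute none).
    """
    if region_tag not in REGION_ATOM_NAMES:
        raise ValueError(
            f"unknown region tag '{region_tag}'; per-bp regions are "
            f"{sorted(REGION_ATOM_NAMES)}"
        )
    names = REGION_ATOM_NAMES[region_tag]
    table = _duplex_atom_index(system, duplex)
    out = []
    for res_i, res_ii in duplex.base_pairs:
        ids = []
        for chain, res in ((duplex.chain_i, res_i), (duplex.chain_ii, res_ii)):
            atoms = table.get((chain, res), {})
            ids.extend(idx for name, idx in atoms.items() if name in names)
        out.append(np.array(sorted(ids), dtype=int))
    return out


def select_region(
    system: MolecularSystem,
    duplex: Duplex | None,
    region_tag: str,
) -> RegionSelection:
    """Build the reference-atom selection for one analysis region.

    ``minor``/``major``: base-edge atoms lining the groove; ``phosphate``:
    the O1P/O2P oxygens; ``P``: backbone phosphorus atoms; ``bp_center``:
    one purine N1 per base pair; ``polyamine_heavy``: all C and N atoms of
    every polyamine (``duplex`` is ignored and may be None).
    """
    if region_tag not in REGION_TAGS:
        raise ValueError(
            f"unknown region tag '{region_tag}'; valid tags: {list(REGION_TAGS)}"
        )
    if region_tag == "polyamine_heavy":
        ids = []
        for p in system.polyamines:
            for i in p.atom_ids:
                if system.atoms[i].atom_name[0] in ("C", "N"):
                    ids.append(i)
        return RegionSelection(region_tag, np.array(sorted(ids), dtype=int))
    if duplex is None:
        raise ValueError(f"region '{region_tag}' requires a duplex")
    if region_tag == "bp_center":
        return RegionSelection(region_tag, np.array(duplex.bp_center_atoms, dtype=int))
    per_bp = region_atoms_by_bp(system, duplex, region_tag)
    ids = np.concatenate([b for b in per_bp if b.size]) if per_bp else np.array([], int)
    if region_tag in ("phosphate", "P") and ids.size == 0:
        warnings.warn(f"duplex {duplex.chain_i}/{duplex.chain_ii} has no {region_tag} atoms")
    return RegionSelection(region_tag, np.unique(ids))
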
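"""Structure and trajectory I/O (PDB, multi-model PDB, DCD) via MDAnalysis.

Readers produce the package's own containers (:class:`MolecularSystem`,
:class:`Trajectory`); duplexes are auto-detected from chain complementarity
and polyamines from a configurable residue name (default ``SPD``).
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import MDAnalysis as mda

from .model import (
    AtomRecord,
    Duplex,
    MolecularSystem,
    PolyamineMolecule,
    Trajectory,
    WATSON_CRICK,
)

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
]

# residue-name dialects
_DNA_RESNAMES = {}
for _b in "ATGC":
    for _n in (f"D{_b}", f"D{_b}5", f"D{_b}3", _b):
        _DNA_RESNAMES[_n] = _b
_K_NAMES = {"K", "K+", "POT"}
_CL_NAMES = {"CL", "CL-", "CLA"}
_WATER_NAMES = {"HOH", "WAT", "SOL", "TIP3"}

# old-style <-> new-style phosphate oxygen names
_ATOM_ALIASES = {"OP1": "O1P", "OP2": "O2P"}

_BOND_CUTOFF = 1.85  # Angstrom, heavy-atom covalent bond


def _normalize_name(name: str) -> str:
    return _ATOM_ALIASES.get(name, name)


def _chain_of(atom) -> str:
    cid = getattr(atom, "chainID", "") or ""
    if not cid.strip():
        cid = (atom.segid or "X").strip()
    return cid.strip() or "X"


def _scan_nwater_remark(path: Path) -> int | None:
    """Pick up the water-count bookkeeping remark written by this package."""
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith(("REMARK", "TITLE")) and "NWATER" in line:
                    toks = line.split()
                    k = toks.index("NWATER")
                    if k + 1 < len(toks) and toks[k + 1].isdigit():
                        return int(toks[k + 1])
                if line.startswith(("ATOM", "HETATM")):
                    break
    except (OSError, UnicodeDecodeError):
        pass
    return None


def _detect_polyamine(mol_id: int, atom_ids: list[int], atoms: list[AtomRecord],
                      coords: np.ndarray) -> PolyamineMolecule:
    """Identify terminal/central amino N by graph position (bond graph from
    heavy-atom distances), falling back to N1/N5/N10 atom names."""
    heavy = [i for i in atom_ids if not atoms[i].atom_name.startswith("H")]
    nitro = [i for i in heavy if atoms[i].atom_name.startswith("N")]
    if len(nitro) != 3:
        raise ValueError(
            f"polyamine {mol_id}: expected 3 nitrogen atoms, found {len(nitro)}"
        )
    xyz = coords[heavy]
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    deg = ((d < _BOND_CUTOFF) & (d > 0.1)).sum(axis=1)
    degree = dict(zip(heavy, deg))
    term = [i for i in nitro if degree[i] == 1]
    cent = [i for i in nitro if degree[i] == 2]
    if len(term) == 2 and len(cent) == 1:
        return PolyamineMolecule(mol_id, heavy, (term[0], term[1]), cent[0])
    by_name = {atoms[i].atom_name: i for i in nitro}
    if {"N1", "N5", "N10"} <= set(by_name):
        return PolyamineMolecule(
            mol_id, heavy, (by_name["N1"], by_name["N10"]), by_name["N5"]
        )
    raise ValueError(
        f"polyamine {mol_id}: cannot identify terminal/central nitrogens"
    )


def _pair_dna_chains(chains: dict[str, list[tuple[int, str]]]):
    """Pair DNA chains by length + Watson-Crick reverse complementarity."""
    seqs = {c: "".join(b for _, b in residues) for c, residues in chains.items()}
    unpaired = sorted(seqs)
    pairs = []
    while unpaired:
        c1 = unpaired.pop(0)
        mate = None
        for c2 in unpaired:
            if len(seqs[c1]) != len(seqs[c2]):
                continue
            if all(
                WATSON_CRICK.get(a) == b
                for a, b in zip(seqs[c1], reversed(seqs[c2]))
            ):
                mate = c2
                break
        if mate is None:
            raise ValueError(
                f"DNA chain '{c1}' has no complementary partner chain "
                "(unpaired strand)"
            )
        unpaired.remove(mate)
        pairs.append((c1, mate))
    return pairs


def _build_duplex(chain_i: str, chain_ii: str, chains, atoms_by_res, atoms):
    seq = "".join(b for _, b in chains[chain_i])
    n = len(seq)
    base_pairs = [(i, n + 1 - i) for i in range(1, n + 1)]
    seq_ii = "".join(b for _, b in chains[chain_ii])
    centers = []
    for bp, (ri, rii) in enumerate(base_pairs):
        if seq[bp] in ("A", "G"):
            chain, res = chain_i, ri
        else:
            chain, res = chain_ii, rii
        names = atoms_by_res.get((chain, res), {})
        if "N1" in names:
            centers.append(names["N1"])
        else:
            raise ValueError(
                f"base pair {bp + 1} of duplex {chain_i}/{chain_ii}: "
                "purine N1 atom missing"
            )
    pP, pO1, pO2, atom_ids = {}, {}, {}, []
    for chain, seq_c in ((chain_i, seq), (chain_ii, seq_ii)):
        pP[chain], pO1[chain], pO2[chain] = [], [], []
        for res in range(1, len(seq_c) + 1):
            names = atoms_by_res.get((chain, res), {})
            atom_ids.extend(names.values())
            if "P" in names:
                pP[chain].append(names["P"])
            if "O1P" in names:
                pO1[chain].append(names["O1P"])
            if "O2P" in names:
                pO2[chain].append(names["O2P"])
    return Duplex(
        sequence=seq,
        chain_i=chain_i,
        chain_ii=chain_ii,
        base_pairs=base_pairs,
        bp_center_atoms=centers,
        phosphate_P=pP,
        phosphate_O1P=pO1,
        phosphate_O2P=pO2,
        atom_ids=sorted(atom_ids),
    )


def system_from_atoms(
    atoms: list[AtomRecord],
    box: np.ndarray | None = None,
    polyamine_resname: str = "SPD",
    n_water: int = 0,
) -> MolecularSystem:
    """Classify a flat atom list into duplexes/polyamines/ions and assemble
    a :class:`MolecularSystem`.  DNA strands are renumbered 1..n per chain
    in file order (5'->3')."""
    coords = np.array([a.xyz for a in atoms])
    dna_chains: dict[str, list[tuple[int, str]]] = {}
    atoms_by_res: dict[tuple[str, int], dict[str, int]] = {}
    poly_residues: dict[tuple[str, int], list[int]] = {}
    n_K = n_Cl = 0
    n_water_atoms_res: set = set()
    other: set[str] = set()

    seen_res: dict[tuple[str, int], int] = {}  # (chain, original resindex)->new
    per_chain_count: dict[str, int] = {}
    for i, a in enumerate(atoms):
        rn = a.residue_name.strip().upper()
        key = (a.chain_id, a.residue_index)
        if rn in _DNA_RESNAMES:
            if key not in seen_res:
                per_chain_count[a.chain_id] = per_chain_count.get(a.chain_id, 0) + 1
                seen_res[key] = per_chain_count[a.chain_id]
                dna_chains.setdefault(a.chain_id, []).append(
                    (seen_res[key], _DNA_RESNAMES[rn])
                )
            a.residue_index = seen_res[key]
            atoms_by_res.setdefault((a.chain_id, a.residue_index), {})[
                a.atom_name
            ] = i
        elif rn == polyamine_resname.upper():
            poly_residues.setdefault(key, []).append(i)
        elif rn in _K_NAMES:
            n_K += 1
        elif rn in _CL_NAMES:
            n_Cl += 1
        elif rn in _WATER_NAMES:
            n_water_atoms_res.add(key)
        else:
            other.add(rn)
    if other:
        warnings.warn(
            f"unknown residue names classified as 'other': {sorted(other)}"
        )
    duplexes = []
    if dna_chains:
        for c1, c2 in _pair_dna_chains(dna_chains):
            duplexes.append(_build_duplex(c1, c2, dna_chains, atoms_by_res, atoms))
    polyamines = [
        _detect_polyamine(mid, ids, atoms, coords)
        for mid, ids in enumerate(poly_residues.values(), start=1)
    ]
    return MolecularSystem(
        atoms=atoms,
        duplexes=duplexes,
        polyamines=polyamines,
        n_K=n_K,
        n_Cl=n_Cl,
        n_water=n_water or len(n_water_atoms_res),
        box=box,
    )


def read_structure(path, polyamine_resname: str = "SPD") -> MolecularSystem:
    """Read a PDB structure into a :class:`MolecularSystem`.

    Duplexes are detected by chain complementarity; polyamines by residue
    name; K+/Cl-/water are counted.  A ``REMARK ... NWATER n`` line (written
    by this package's generator) overrides the instantiated-water count.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = []
    for a in u.atoms:
        atoms.append(
            AtomRecord(
                atom_id=int(a.id),
                atom_name=_normalize_name(a.name.strip()),
                residue_name=a.resname.strip(),
                residue_index=int(a.resid),
                chain_id=_chain_of(a),
                xyz=a.position.astype(float),
            )
        )
    box = None
    dims = u.dimensions
    if dims is not None and np.all(dims[:3] > 1.0):
        box = np.asarray(dims[:3], dtype=float)
    n_water = _scan_nwater_remark(path) or 0
    return system_from_atoms(
        atoms, box=box, polyamine_resname=polyamine_resname, n_water=n_water
    )


def _to_universe(system: MolecularSystem) -> mda.Universe:
    """Materialize a MolecularSystem as an in-memory MDAnalysis Universe."""
    n = system.n_atoms
    res_keys: list[tuple[str, int, str]] = []
    res_of_atom = []
    for a in system.atoms:
        key = (a.chain_id, a.residue_index, a.residue_name)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        res_of_atom.append(len(res_keys) - 1)
    seg_ids: list[str] = []
    seg_of_res = []
    for chain, _, _ in res_keys:
        if not seg_ids or seg_ids[-1] != chain:
            seg_ids.append(chain)
        seg_of_res.append(len(seg_ids) - 1)
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(res_keys),
        n_segments=len(seg_ids),
        atom_resindex=np.array(res_of_atom),
        residue_segindex=np.array(seg_of_res),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.atom_name for a in system.atoms])
    u.add_TopologyAttr("ids", [a.atom_id for a in system.atoms])
    u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
    u.add_TopologyAttr("resids", [k[1] for k in res_keys])
    u.add_TopologyAttr("segids", seg_ids)
    u.add_TopologyAttr("chainIDs", [a.chain_id[:1] for a in system.atoms])
    u.atoms.positions = system.coordinates
    if system.box is not None:
        u.dimensions = np.array(
            [system.box[0], system.box[1], system.box[2], 90.0, 90.0, 90.0]
        )
    return u


def write_structure(system: MolecularSystem, path) -> None:
    """Write a single-frame PDB, embedding the water count as a REMARK."""
    path = Path(path)
    u = _to_universe(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.coordinates.PDB.PDBWriter(
            str(path), remarks=f"NWATER {system.n_water}"
        ) as w:
            w.write(u.atoms)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB (``.pdb``) or DCD (``.dcd``)."""
    path = Path(path)
    u = _to_universe(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() == ".pdb":
            writer = mda.coordinates.PDB.MultiPDBWriter(
                str(path), multiframe=True, remarks=f"NWATER {traj.topology.n_water}"
            )
        else:
            writer = mda.Writer(str(path), n_atoms=traj.topology.n_atoms)
        with writer as w:
            for frame in traj.frames:
                u.atoms.positions = frame
                w.write(u.atoms)


def read_trajectory(
    system: MolecularSystem, path, frame_dt: float | None = None
) -> Trajectory:
    """Read coordinate frames (multi-model PDB or DCD) over ``system``.

    Times are ``0, frame_dt, 2*frame_dt, ...`` ns when ``frame_dt`` is
    given; otherwise times recorded in the file are used, falling back to
    unit spacing.
    """
    path = Path(path)
    u = _to_universe(system)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path))
    except (ValueError, OSError, EOFError, IndexError) as exc:
        n_file = _count_file_atoms(path)
        if n_file is not None and n_file != system.n_atoms:
            raise ValueError(
                f"trajectory atom count {n_file} does not match topology "
                f"atom count {system.n_atoms}"
            ) from exc
        raise ValueError(f"cannot read trajectory '{path}': {exc}") from exc
    frames, file_times = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float).copy())
            file_times.append(float(ts.time))
    if not frames:
        raise ValueError(f"trajectory '{path}' contains no frames")
    n = len(frames)
    if frame_dt is not None:
        times = np.arange(n) * float(frame_dt)
    else:
        times = np.asarray(file_times)
        if n > 1 and not np.all(np.diff(times) > 0):
            times = np.arange(n, dtype=float)
    return Trajectory(np.array(frames), times, system)


def _count_file_atoms(path: Path) -> int | None:
    """Atom count of the first model of a PDB-like file, for error messages."""
    if path.suffix.lower() not in (".pdb", ".ent", ".pdbqt"):
        return None
    count = 0
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith(("ATOM", "HETATM")):
                    count += 1
                elif line.startswith(("ENDMDL", "END")) and count:
                    break
    except OSError:
        return None
    return count or None
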
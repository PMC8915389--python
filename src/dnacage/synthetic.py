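"""Idealized structures and pseudo-trajectories emulating the MD systems.

Two parallel 22-bp B-DNA duplexes at a chosen axis separation, spermidine
molecules exchanging between caged (inter-duplex) and uncaged positions via
a two-state Markov chain with positional noise, and a 146-bp nucleosome-like
superhelical duplex whose minor-groove width oscillates with a configurable
period.  Every generated system satisfies the topology invariants of
:mod:`dnacage.model` (complementarity, charge accounting), and the
generator returns its ground-truth state matrix alongside the trajectory.

The fiber model is a cylindrical idealization: base pairs are stacked with
constant rise and twist, and each residue carries only the atoms the
analyses reference (P, O1P, O2P, glycosidic N, purine N1 at the pair
center, and the minor/major groove edge atoms).  No hydrogens are built;
all hydrogen-bond style criteria downstream are heavy-atom based.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .caging import CageCriterion, StateSeries, classify_caged, segment_duplexes
from .io import system_from_atoms
from .model import (
    AtomRecord,
    Duplex,
    MolecularSystem,
    Trajectory,
    WATSON_CRICK,
)

__all__ = [
    "SystemSpec",
    "DynamicsSpec",
    "SuperhelixSpec",
    "DD_SEQUENCE",
    "build_bdna",
    "build_superhelix",
    "assemble_two_duplex_system",
    "assemble_nucleosome_system",
    "generate_trajectory",
    "spermidine_template",
]

#: The 22-mer studied: two Drew-Dickerson dodecamer motifs, two A-tracts.
DD_SEQUENCE = "CGCGAATTCGCGCGAATTCGCG"

# -- fiber-model constants (canonical B-DNA idealization) --------------------
RISE = 3.38  # Angstrom / bp
TWIST = 36.0  # degrees / bp
P_RADIUS = 9.4  # phosphorus radial distance from helix axis
P_GAMMA = 77.0  # azimuthal half-offset of the two backbones (degrees)
P_ZOFF = 1.0  # phosphorus axial offset from the bp plane
CLASH_DISTANCE = 1.5

# per-residue atom templates: name -> (radius, azimuth offset deg, z offset).
# The strand-II copy of a residue is mirrored (azimuth and z negated).
_BACKBONE = {"P": (P_RADIUS, P_GAMMA, P_ZOFF),
             "O1P": (10.2, P_GAMMA - 6.0, P_ZOFF + 0.6),
             "O2P": (10.2, P_GAMMA + 6.0, P_ZOFF - 0.6)}
_BASE_ATOMS = {
    # purines: glycosidic N9, ring N1 near the pair center, groove-edge atoms
    "A": {"N9": (5.9, 45.0, 0.0), "N1": (0.8, 10.0, 0.0),
          "N3": (4.8, 12.0, 0.0),
          "C8": (6.2, 170.0, 0.0), "N7": (5.8, 160.0, 0.0),
          "C5": (5.2, 165.0, 0.0)},
    "G": {"N9": (5.9, 45.0, 0.0), "N1": (0.8, 10.0, 0.0),
          "N3": (4.8, 12.0, 0.0), "N2": (5.4, 2.0, 0.0),
          "C8": (6.2, 170.0, 0.0), "N7": (5.8, 160.0, 0.0),
          "C5": (5.2, 165.0, 0.0), "O6": (4.6, 172.0, 0.0)},
    # pyrimidines: glycosidic N1, groove-edge atoms
    "C": {"N1": (5.9, 45.0, 0.0), "O2": (4.9, 14.0, 0.0),
          "N4": (4.6, 168.0, 0.0), "C5": (5.3, 162.0, 0.0),
          "C6": (5.9, 155.0, 0.0)},
    "T": {"N1": (5.9, 45.0, 0.0), "O2": (4.9, 14.0, 0.0),
          "C5": (5.3, 162.0, 0.0), "C6": (5.9, 155.0, 0.0)},
}
_RESNAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}


def _validate_sequence(sequence: str) -> None:
    for i, b in enumerate(sequence):
        if b not in WATSON_CRICK:
            raise ValueError(
                f"invalid base '{b}' at position {i + 1} of sequence"
            )


@dataclass
class SystemSpec:
    """Composition and geometry of a two-duplex simulation box."""

    sequence: str = DD_SEQUENCE
    separation: float = 20.0  # axis-to-axis, Angstrom
    n_polyamine: int = 30
    n_K: int = 84
    n_Cl: int = 90
    n_water: int = 31308  # bookkeeping only, never instantiated
    box: np.ndarray | None = None

    def __post_init__(self):
        _validate_sequence(self.sequence)
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        for name in ("n_polyamine", "n_K", "n_Cl", "n_water"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @classmethod
    def dd(cls, separation: float) -> "SystemSpec":
        """The studied stoichiometry (30 Spd3+, 84 K+, 90 Cl-, 31308 waters)
        at a given axis separation (20, 25 or 30 A)."""
        return cls(separation=separation)


@dataclass
class DynamicsSpec:
    """Two-state Markov kinetics + positional noise for pseudo-dynamics."""

    p_enter: float = 0.1  # per-step uncaged -> caged
    p_exit: float = 0.1  # per-step caged -> uncaged
    noise_sigma: float = 0.8  # Angstrom, per-atom Gaussian noise
    n_frames: int = 21
    frame_dt: float = 25.0  # ns
    seed: int = 0

    def __post_init__(self):
        for name in ("p_enter", "p_exit"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_frames < 1 or self.frame_dt <= 0:
            raise ValueError("need n_frames >= 1 and frame_dt > 0")


@dataclass
class SuperhelixSpec:
    """Nucleosome-like superhelical duplex with modulated minor groove."""

    n_bp: int = 146
    modulation_period: float = 10.0  # bp
    modulation_amplitude: float = 2.0  # Angstrom
    superhelix_radius: float = 41.9  # Angstrom
    pitch: float = 25.0  # Angstrom per superhelical turn
    sequence: str | None = None  # random (seeded) when None
    seed: int = 0

    def __post_init__(self):
        if self.modulation_period < 2:
            raise ValueError("modulation_period must be >= 2 bp")
        if self.modulation_amplitude < 0:
            raise ValueError("modulation_amplitude must be >= 0")
        if self.n_bp < 2 * self.modulation_period:
            raise ValueError("need n_bp >= 2 * modulation_period")
        if self.sequence is not None:
            _validate_sequence(self.sequence)
            if len(self.sequence) != self.n_bp:
                raise ValueError("sequence length != n_bp")


# -- duplex construction -----------------------------------------------------

def _duplex_atoms(
    sequence: str,
    origins: np.ndarray,  # (n, 3) bp frame origins
    ex: np.ndarray,  # (n, 3) in-plane axis of each bp frame
    ey: np.ndarray,
    ez: np.ndarray,  # local helix axis of each bp frame
    theta: np.ndarray,  # (n,) accumulated twist, radians
    gamma: np.ndarray,  # (n,) backbone half-offset per bp, radians
    chain_ids: tuple[str, str],
    start_atom_id: int = 1,
    p_radius: np.ndarray | None = None,  # per-bp P radial distance
):
    """Place the reference atoms of every residue of both strands."""
    n = len(sequence)
    seq_ii_by_bp = [WATSON_CRICK[b] for b in sequence]
    if p_radius is None:
        p_radius = np.full(n, P_RADIUS)

    def place(bp, rho, psi_rad, dz, sgn):
        a = theta[bp] + sgn * psi_rad
        return (
            origins[bp]
            + rho * (np.cos(a) * ex[bp] + np.sin(a) * ey[bp])
            + sgn * dz * ez[bp]
        )

    atoms: list[AtomRecord] = []
    aid = start_atom_id

    def emit(chain, res_index, base, bp, sgn):
        nonlocal aid
        resname = _RESNAME[base]
        is_5prime = res_index == 1
        entries = []
        if not is_5prime:
            for name, (rho, psi, dz) in _BACKBONE.items():
                drho = p_radius[bp] - P_RADIUS
                psi_r = gamma[bp] + np.radians(psi - P_GAMMA) if name != "P" else gamma[bp]
                entries.append((name, rho + drho, psi_r, dz))
        for name, (rho, psi, dz) in _BASE_ATOMS[base].items():
            entries.append((name, rho, np.radians(psi), dz))
        for name, rho, psi_r, dz in entries:
            atoms.append(
                AtomRecord(aid, name, resname, res_index, chain,
                           place(bp, rho, psi_r, dz, sgn))
            )
            aid += 1

    for res in range(1, n + 1):  # strand I, 5'->3', bp = res
        emit(chain_ids[0], res, sequence[res - 1], res - 1, +1)
    for res in range(1, n + 1):  # strand II, 5'->3', pairs bp n+1-res
        bp = n - res
        emit(chain_ids[1], res, seq_ii_by_bp[bp], bp, -1)
    return atoms, aid


def _straight_frames(n_bp: int, rise: float, twist: float,
                     origin=(0.0, 0.0, 0.0), phase_deg: float = 0.0):
    origin = np.asarray(origin, float)
    origins = origin + np.outer(np.arange(n_bp) * rise, np.array([0.0, 0.0, 1.0]))
    ex = np.tile([1.0, 0.0, 0.0], (n_bp, 1))
    ey = np.tile([0.0, 1.0, 0.0], (n_bp, 1))
    ez = np.tile([0.0, 0.0, 1.0], (n_bp, 1))
    theta = np.radians(phase_deg + np.arange(n_bp) * twist)
    return origins, ex, ey, ez, theta


def build_bdna(
    sequence: str,
    rise: float = RISE,
    twist: float = TWIST,
    origin=(0.0, 0.0, 0.0),
    phase_deg: float = 0.0,
    chain_ids: tuple[str, str] = ("A", "B"),
) -> MolecularSystem:
    """Fiber-model B-DNA duplex: straight axis (along z), constant rise and
    twist.  Returns a single-duplex :class:`MolecularSystem`."""
    _validate_sequence(sequence)
    frames = _straight_frames(len(sequence), rise, twist, origin, phase_deg)
    gamma = np.full(len(sequence), np.radians(P_GAMMA))
    atoms, _ = _duplex_atoms(sequence, *frames, gamma, chain_ids)
    return system_from_atoms(atoms)


def _minor_width_vs_gamma(gamma_rad: np.ndarray) -> np.ndarray:
    """Cross-strand P-P distance at the minor-groove register (k=+3) of a
    straight fiber-model helix, as a function of the backbone half-offset."""
    k = 3
    dtheta = np.radians(k * TWIST) - 2.0 * gamma_rad
    dz = k * RISE - 2.0 * P_ZOFF
    return np.sqrt((2 * P_RADIUS * np.sin(dtheta / 2.0)) ** 2 + dz**2)


def build_superhelix(spec: SuperhelixSpec) -> MolecularSystem:
    """Duplex bent on a superhelical path, with the backbone half-offset
    calibrated per bp so the measured minor-groove width follows the
    requested sinusoidal profile.

    Bending a helix intrinsically modulates cross-strand P-P distances with
    the helical repeat; the builder measures that bias and compensates, so
    ``modulation_amplitude=0`` really yields a flat width profile.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence or "".join(rng.choice(list("ACGT"), size=spec.n_bp))
    n = spec.n_bp
    R, pitch = spec.superhelix_radius, spec.pitch
    c = pitch / (2 * np.pi)
    dt = RISE / np.hypot(R, c)  # superhelical angle per bp (arc length = rise)
    t = np.arange(n) * dt
    origins = np.column_stack([R * np.cos(t), R * np.sin(t), c * t])
    # local frame: ez = curve tangent, ex = outward radial (perp. to ez)
    tang = np.column_stack([-R * np.sin(t), R * np.cos(t), np.full(n, c)])
    ez = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    rad = np.column_stack([np.cos(t), np.sin(t), np.zeros(n)])
    ex = rad - (rad * ez).sum(axis=1, keepdims=True) * ez
    ex /= np.linalg.norm(ex, axis=1, keepdims=True)
    ey = np.cross(ez, ex)
    theta = np.radians(np.arange(n) * TWIST)

    w0 = float(_minor_width_vs_gamma(np.array([np.radians(P_GAMMA)]))[0])
    amp = spec.modulation_amplitude
    if amp >= w0:
        raise ValueError(
            f"modulation amplitude {amp} A is not smaller than the mean "
            f"minor-groove width {w0:.2f} A"
        )
    targets = w0 + amp * np.cos(2 * np.pi * np.arange(n) / spec.modulation_period)
    gamma, p_radius = _calibrate_backbone(origins, ex, ey, ez, theta, targets)
    atoms, _ = _duplex_atoms(seq, origins, ex, ey, ez, theta, gamma, ("A", "B"),
                             p_radius=p_radius)
    return system_from_atoms(atoms)


def _calibrate_backbone(origins, ex, ey, ez, theta, targets,
                        max_iter=120, tol=0.04):
    """Per-bp backbone half-offset and P radius realizing a target
    minor-groove width profile on a curved axis.

    Bending a helix modulates cross-strand P-P distances with the helical
    repeat, and the analyzer width is a minimum over a register window, so
    the inverse problem is solved as a hinge Gauss-Newton least squares:
    every window pair below its bp's target is pushed out, the windows'
    minima are pulled onto the targets.
    """
    from .groove import MINOR_REGISTER

    n = len(targets)
    klo, khi = MINOR_REGISTER
    gamma = np.full(n, np.radians(P_GAMMA))
    rho = np.full(n, P_RADIUS)
    for _ in range(max_iter):
        a_i, a_ii = theta + gamma, theta - gamma
        c_i = np.cos(a_i)[:, None] * ex + np.sin(a_i)[:, None] * ey
        c_ii = np.cos(a_ii)[:, None] * ex + np.sin(a_ii)[:, None] * ey
        p_i = origins + rho[:, None] * c_i + P_ZOFF * ez
        p_ii = origins + rho[:, None] * c_ii - P_ZOFF * ez
        dg_i = rho[:, None] * (-np.sin(a_i)[:, None] * ex + np.cos(a_i)[:, None] * ey)
        dg_ii = -rho[:, None] * (-np.sin(a_ii)[:, None] * ex + np.cos(a_ii)[:, None] * ey)
        rows, vals = [], []
        width = np.full(n, np.nan)
        for i in range(1, n):
            js = [i + k for k in range(klo, khi + 1) if 0 <= i + k <= n - 2]
            if not js:
                continue
            dd = np.linalg.norm(p_ii[js] - p_i[i], axis=1)
            m = int(np.argmin(dd))
            width[i] = dd[m]
            for jj, d in zip(js, dd):
                if d < targets[i] or jj == js[m]:
                    u = (p_i[i] - p_ii[jj]) / d
                    row = np.zeros(2 * n)
                    row[i] = u @ dg_i[i]
                    row[jj] = -u @ dg_ii[jj]
                    row[n + i] = u @ c_i[i]
                    row[n + jj] = -u @ c_ii[jj]
                    rows.append(row)
                    vals.append(d - targets[i])
        ok = np.isfinite(width)
        if np.abs(width - targets)[ok].max() < tol:
            break
        jac = np.array(rows)
        r = np.array(vals)
        lhs = jac.T @ jac + 3e-2 * np.eye(2 * n)
        step = np.clip(np.linalg.solve(lhs, jac.T @ r), -0.1, 0.1)
        gamma -= step[:n]
        rho -= step[n:]
    return gamma, rho


# -- spermidine --------------------------------------------------------------

_SPD_NAMES = ["N1", "C2", "C3", "C4", "N5", "C6", "C7", "C8", "C9", "N10"]
_SPD_BONDS = [1.47, 1.53, 1.53, 1.47, 1.47, 1.53, 1.53, 1.53, 1.47]
_SPD_ANGLE = 112.0  # degrees, heavy-atom valence angle
_FOLD_TURN = 120.0  # degrees, in-plane turn of the second arm at N5


def spermidine_template(folded: bool = False) -> np.ndarray:
    """Heavy-atom coordinates of spermidine, (10, 3), centered on N5.

    ``folded=False``: planar all-trans zigzag (elongated, EE ~ 11.2 A);
    ``folded=True``: the arm beyond N5 turned by 120 deg in-plane
    (C-shape, EE ~ 5 A)."""
    half = np.radians((180.0 - _SPD_ANGLE) / 2.0)
    pos = np.zeros((10, 3))
    heading = 0.0
    for k, b in enumerate(_SPD_BONDS):
        if folded and k == 4:  # first bond leaving N5
            heading += np.radians(_FOLD_TURN)
        a = heading + (half if k % 2 == 0 else -half)
        pos[k + 1] = pos[k] + b * np.array([np.cos(a), np.sin(a), 0.0])
    return pos - pos[4]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# -- placement ---------------------------------------------------------------

def _threshold_for_separation(separation: float) -> float:
    table = {20.0: 15.0, 25.0: 19.0, 30.0: 23.0}
    if separation in table:
        return table[separation]
    # interpolate/extrapolate the studied mapping
    return float(np.interp(separation, [20.0, 25.0, 30.0], [15.0, 19.0, 23.0]))


def _min_dist_to(points: np.ndarray, targets: np.ndarray) -> float:
    d = np.linalg.norm(points[:, None, :] - targets[None, :, :], axis=-1)
    return float(d.min())


def _sample_caged_site(rng, centers1, centers2, threshold, margin, max_tries=200):
    for _ in range(max_tries):
        c1 = centers1[rng.integers(len(centers1))]
        c2 = centers2[np.argmin(np.linalg.norm(centers2 - c1, axis=1))]
        site = 0.5 * (c1 + c2) + rng.uniform(-2.5, 2.5, size=3)
        if (
            np.min(np.linalg.norm(centers1 - site, axis=1)) < threshold - margin
            and np.min(np.linalg.norm(centers2 - site, axis=1)) < threshold - margin
        ):
            return site
    raise RuntimeError("could not sample a caged site; threshold/margin too tight")


def _sample_uncaged_site(rng, centers1, centers2, threshold, margin, max_tries=200):
    for _ in range(max_tries):
        c1 = centers1[rng.integers(len(centers1))]
        c2 = centers2[np.argmin(np.linalg.norm(centers2 - c1, axis=1))]
        away = c1 - c2
        away /= np.linalg.norm(away)
        site = c1 + away * (threshold + margin + rng.uniform(1.0, 5.0))
        site += rng.uniform(-2.0, 2.0, size=3)
        if np.min(np.linalg.norm(centers1 - site, axis=1)) >= threshold + margin:
            return site
    raise RuntimeError("could not sample an uncaged site")


def _place_polyamines(
    rng,
    dna_atoms: list[AtomRecord],
    centers1: np.ndarray,
    centers2: np.ndarray,
    n_polyamine: int,
    n_caged: int,
    threshold: float,
    margin: float,
    folded_fraction: float,
    start_atom_id: int,
):
    atoms = list(dna_atoms)
    occupied = np.array([a.xyz for a in dna_atoms])
    states = np.zeros(n_polyamine, dtype=bool)
    aid = start_atom_id
    for m in range(n_polyamine):
        caged = m < n_caged
        states[m] = caged
        folded = rng.random() < folded_fraction
        template = spermidine_template(folded=folded) @ _random_rotation(rng).T
        for _ in range(50):
            if caged:
                site = _sample_caged_site(rng, centers1, centers2, threshold, margin)
            else:
                site = _sample_uncaged_site(rng, centers1, centers2, threshold, margin)
            coords = template + site
            if _min_dist_to(coords, occupied) >= CLASH_DISTANCE:
                break
        occupied = np.vstack([occupied, coords])
        for name, xyz in zip(_SPD_NAMES, coords):
            atoms.append(AtomRecord(aid, name, "SPD", m + 1, "S", xyz))
            aid += 1
    return atoms, states, aid, occupied


def _place_ions(rng, atoms, occupied, n_K, n_Cl, lo, hi, start_atom_id):
    aid = start_atom_id
    res = 1
    for name, count in (("K", n_K), ("CL", n_Cl)):
        for _ in range(count):
            for _ in range(100):
                xyz = rng.uniform(lo, hi)
                if _min_dist_to(xyz[None, :], occupied) >= CLASH_DISTANCE:
                    break
            occupied = np.vstack([occupied, xyz[None, :]])
            atoms.append(AtomRecord(aid, name, name, res, "I", xyz))
            aid += 1
            res += 1
    return atoms, occupied, aid


def _best_phase(sequence, separation):
    """Azimuthal phase of duplex 2 maximizing inter-duplex clearance."""
    sys1 = build_bdna(sequence)
    c1 = sys1.coordinates
    best_phase, best_d = 0.0, -1.0
    for phase in range(0, 360, 5):
        sys2 = build_bdna(sequence, origin=(separation, 0.0, 0.0),
                          phase_deg=phase)
        d = _min_dist_to(sys1.coordinates, sys2.coordinates)
        if d > best_d:
            best_phase, best_d = float(phase), d
    return best_phase, best_d, c1


def assemble_two_duplex_system(
    spec: SystemSpec,
    fraction_caged: float = 0.4,
    seed: int = 0,
    folded_fraction: float = 0.0,
    criterion: CageCriterion | None = None,
    margin: float = 2.0,
) -> tuple[MolecularSystem, np.ndarray]:
    """Two parallel duplexes at ``spec.separation`` plus polyamines and ions.

    ``round(fraction_caged * n_polyamine)`` molecules are placed so that
    their central N satisfies the caging criterion with a ``margin`` (A) to
    spare on both duplexes; the rest are placed beyond threshold + margin.
    Returns ``(system, initial_states)`` where the boolean vector is the
    placement ground truth (guaranteed to agree with the classifier).
    """
    if not 0.0 <= fraction_caged <= 1.0:
        raise ValueError("fraction_caged must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if criterion is None:
        criterion = CageCriterion(_threshold_for_separation(spec.separation))
    phase, clearance, _ = _best_phase(spec.sequence, spec.separation)
    if clearance < CLASH_DISTANCE:
        raise ValueError(
            f"axis separation {spec.separation} A leaves inter-duplex "
            f"clearance {clearance:.2f} A < {CLASH_DISTANCE} A"
        )
    sys1 = build_bdna(spec.sequence, chain_ids=("A", "B"))
    atoms1 = sys1.atoms
    n1 = len(atoms1)
    sys2 = build_bdna(spec.sequence, origin=(spec.separation, 0.0, 0.0),
                      phase_deg=phase, chain_ids=("C", "D"))
    atoms = atoms1 + [
        AtomRecord(a.atom_id + n1, a.atom_name, a.residue_name,
                   a.residue_index, a.chain_id, a.xyz)
        for a in sys2.atoms
    ]
    tmp = system_from_atoms([*atoms])
    d1 = next(d for d in tmp.duplexes if d.chain_i in ("A", "B"))
    d2 = next(d for d in tmp.duplexes if d.chain_i in ("C", "D"))
    coords = tmp.coordinates
    centers1 = coords[np.asarray(d1.bp_center_atoms)]
    centers2 = coords[np.asarray(d2.bp_center_atoms)]

    n_caged = int(round(fraction_caged * spec.n_polyamine))
    atoms, states, aid, occupied = _place_polyamines(
        rng, atoms, centers1, centers2, spec.n_polyamine, n_caged,
        criterion.threshold, margin, folded_fraction, start_atom_id=2 * n1 + 1,
    )
    lo = occupied.min(axis=0) - 4.0
    hi = occupied.max(axis=0) + 4.0
    atoms, occupied, aid = _place_ions(
        rng, atoms, occupied, spec.n_K, spec.n_Cl, lo, hi, aid
    )
    box = spec.box
    if box is None:
        span = occupied.max(axis=0) - occupied.min(axis=0)
        # generous padding keeps periodic images from intruding on the
        # caging geometry (minimum-image distances stay > threshold+margin)
        box = span + np.array([2 * criterion.threshold, 30.0, 20.0])
    system = system_from_atoms(list(atoms), box=np.asarray(box, float),
                               n_water=spec.n_water)
    _verify_placement(system, states, criterion)
    return system, states


def _verify_placement(system, states, criterion):
    pair = (system.duplexes[0], system.duplexes[1]) if len(system.duplexes) == 2 \
        else segment_duplexes(system.duplexes[0])
    coords = system.coordinates
    got = np.array([
        classify_caged(coords, p, pair, criterion, system.box)
        for p in system.polyamines
    ])
    if not np.array_equal(got, states):
        raise RuntimeError(
            "internal placement error: classifier disagrees with intended states"
        )


def assemble_nucleosome_system(
    spec: SuperhelixSpec | None = None,
    n_polyamine: int = 100,
    n_K: int = 156,
    n_Cl: int = 166,
    n_water: int = 50583,
    fraction_caged: float = 0.4,
    seed: int = 0,
    folded_fraction: float = 0.0,
    criterion: CageCriterion | None = None,
    margin: float = 2.0,
    segment_ranges: tuple[tuple[int, int], tuple[int, int]] = ((1, 67), (80, 146)),
) -> tuple[MolecularSystem, np.ndarray]:
    """Superhelical 146-bp duplex with polyamines caged between its two
    parallel gyres (bps 1-67 vs 80-146), built to the nucleosome
    stoichiometry (100 Spd3+, 156 K+, 166 Cl-)."""
    spec = spec or SuperhelixSpec()
    if criterion is None:
        criterion = CageCriterion.for_system("nucleosome")
    rng = np.random.default_rng(seed)
    base = build_superhelix(spec)
    atoms = base.atoms
    seg1, seg2 = segment_duplexes(base.duplexes[0], segment_ranges)
    coords = base.coordinates
    centers1 = coords[np.asarray(seg1.bp_center_atoms)]
    centers2 = coords[np.asarray(seg2.bp_center_atoms)]
    n_caged = int(round(fraction_caged * n_polyamine))
    atoms, states, aid, occupied = _place_polyamines(
        rng, atoms, centers1, centers2, n_polyamine, n_caged,
        criterion.threshold, margin, folded_fraction,
        start_atom_id=len(atoms) + 1,
    )
    lo = occupied.min(axis=0) - 4.0
    hi = occupied.max(axis=0) + 4.0
    atoms, occupied, aid = _place_ions(rng, atoms, occupied, n_K, n_Cl, lo, hi, aid)
    span = occupied.max(axis=0) - occupied.min(axis=0)
    box = span + np.array([2 * criterion.threshold] * 3)
    system = system_from_atoms(list(atoms), box=box, n_water=n_water)
    _verify_placement(system, states, criterion)
    return system, states


# -- pseudo-dynamics ---------------------------------------------------------

def generate_trajectory(
    system: MolecularSystem,
    dyn: DynamicsSpec,
    initial_states: np.ndarray | None = None,
    criterion: CageCriterion | None = None,
    margin: float = 2.0,
) -> tuple[Trajectory, StateSeries]:
    """Evolve each polyamine by the two-state Markov chain of ``dyn``.

    On entering the caged (uncaged) state a molecule is translated to a
    freshly sampled inter-duplex (outer) site; Gaussian positional noise of
    sd ``noise_sigma`` is added to *every* atom of *every* frame.  Returns
    the trajectory and the generator's ground-truth state matrix.
    """
    rng = np.random.default_rng(dyn.seed)
    if len(system.duplexes) == 2:
        pair = (system.duplexes[0], system.duplexes[1])
    elif len(system.duplexes) == 1:
        pair = segment_duplexes(system.duplexes[0])
    else:
        raise ValueError("system must contain two duplexes (or one segmented)")
    if criterion is None:
        threshold = _infer_threshold(system, pair)
        criterion = CageCriterion(threshold)
    base = system.coordinates.copy()
    centers1 = base[np.asarray(pair[0].bp_center_atoms)]
    centers2 = base[np.asarray(pair[1].bp_center_atoms)]
    polys = system.polyamines
    n_mol = len(polys)
    if initial_states is None:
        initial_states = np.array([
            classify_caged(base, p, pair, criterion, system.box) for p in polys
        ])
    states = np.zeros((n_mol, dyn.n_frames), dtype=bool)
    states[:, 0] = initial_states
    mol_coords = {p.molecule_id: base[np.asarray(p.atom_ids)].copy() for p in polys}
    frames = np.empty((dyn.n_frames, system.n_atoms, 3))
    frames[0] = base + rng.normal(scale=dyn.noise_sigma, size=base.shape) \
        if dyn.noise_sigma > 0 else base
    current = base.copy()
    for f in range(1, dyn.n_frames):
        for i, p in enumerate(polys):
            prev = states[i, f - 1]
            flip = rng.random() < (dyn.p_exit if prev else dyn.p_enter)
            now = (not prev) if flip else prev
            states[i, f] = now
            if now != prev:
                if now:
                    site = _sample_caged_site(
                        rng, centers1, centers2, criterion.threshold, margin
                    )
                else:
                    site = _sample_uncaged_site(
                        rng, centers1, centers2, criterion.threshold, margin
                    )
                ids = np.asarray(p.atom_ids)
                central_pos = current[p.central_N]
                shift = site - central_pos
                current[ids] = current[ids] + shift
        noise = (
            rng.normal(scale=dyn.noise_sigma, size=current.shape)
            if dyn.noise_sigma > 0
            else 0.0
        )
        frames[f] = current + noise
    times = np.arange(dyn.n_frames) * dyn.frame_dt
    traj = Trajectory(frames, times, system)
    truth = StateSeries(
        states,
        sample_interval=dyn.frame_dt,
        molecule_ids=[p.molecule_id for p in polys],
        times=times,
    )
    return traj, truth


def _infer_threshold(system: MolecularSystem, pair) -> float:
    if len(system.duplexes) == 1:
        return CageCriterion.DEFAULTS["nucleosome"]
    c = system.coordinates
    a1 = c[np.asarray(pair[0].bp_center_atoms)].mean(axis=0)
    a2 = c[np.asarray(pair[1].bp_center_atoms)].mean(axis=0)
    return _threshold_for_separation(float(np.linalg.norm(a1 - a2)))
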
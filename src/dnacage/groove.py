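"""Minor/major groove widths per base pair and groove-width periodicity.

Widths follow the El Hassan-Calladine construction: the width at a base
pair is the shortest cross-strand phosphate-phosphate distance over a
sliding register window appropriate to each groove.  Raw P-P distances are
reported by default; ``subtract_vdw=True`` applies the conventional -5.8 A
phosphate-radius correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .model import Duplex, Trajectory

__all__ = [
    "GrooveProfile",
    "PeriodicityResult",
    "groove_widths",
    "minima_periodicity",
    "MINOR_REGISTER",
    "MAJOR_REGISTER",
    "VDW_CORRECTION",
]

#: cross-strand register windows, in bp offsets k = j - i between the
#: strand-I phosphate of bp i and the strand-II phosphate of bp j; chosen
#: for the fiber-model geometry (minor minimum near k=+3, major near k=-4)
#: and disjoint by construction.
MINOR_REGISTER = (0, 6)
MAJOR_REGISTER = (-7, -1)
VDW_CORRECTION = 5.8  # Angstrom, two phosphate-group radii


@dataclass
class GrooveProfile:
    """Per-bp groove widths (mean +- sd over frames); NaN where undefined."""

    minor_width: np.ndarray
    major_width: np.ndarray
    minor_sd: np.ndarray
    major_sd: np.ndarray
    n_frames: int
    labels: list[str] = field(default_factory=list)
    #: True where the full register window was available (interior bps);
    #: edge bps are minimized over a partial window and biased upward.
    minor_complete: np.ndarray | None = None
    major_complete: np.ndarray | None = None

    def __post_init__(self):
        for name in ("minor_width", "major_width", "minor_sd", "major_sd"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        for w in (self.minor_width, self.major_width):
            if np.any(w[np.isfinite(w)] <= 0):
                raise ValueError("groove widths must be positive where defined")

    @property
    def n_bp(self) -> int:
        return self.minor_width.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bp": np.arange(1, self.n_bp + 1),
                "pair": self.labels or [""] * self.n_bp,
                "minor": self.minor_width,
                "minor_sd": self.minor_sd,
                "major": self.major_width,
                "major_sd": self.major_sd,
            }
        )


def _phosphate_maps(duplex: Duplex):
    """bp index (1-based) -> atom index of the strand-I / strand-II
    phosphate at that bp; strand-II residue s pairs bp n+1-s."""
    n = duplex.n_bp
    p_i = duplex.phosphate_P.get(duplex.chain_i, [])
    p_ii = duplex.phosphate_P.get(duplex.chain_ii, [])
    map_i = {r: p_i[r - 2] for r in range(2, 2 + len(p_i))}
    map_ii = {n + 1 - s: p_ii[s - 2] for s in range(2, 2 + len(p_ii))}
    return map_i, map_ii


def groove_widths(
    traj: Trajectory,
    duplex: Duplex,
    subtract_vdw: bool = False,
) -> GrooveProfile:
    """El Hassan-Calladine groove widths for every base pair.

    For bp i the minor (major) width is the minimum distance between the
    strand-I phosphate of bp i and a strand-II phosphate of bp i+k with k
    in the minor (major) register window, evaluated per frame and averaged.
    Base pairs with no admissible pair are NaN.
    """
    n = duplex.n_bp
    if n < 6:
        raise ValueError("groove registers are undefined below 6 bp")
    map_i, map_ii = _phosphate_maps(duplex)
    if not map_i or not map_ii:
        raise ValueError("duplex must carry phosphates on both strands")
    offset = -VDW_CORRECTION if subtract_vdw else 0.0
    out = {}
    for tag, (klo, khi) in (("minor", MINOR_REGISTER), ("major", MAJOR_REGISTER)):
        mean = np.full(n, np.nan)
        sd = np.full(n, np.nan)
        complete = np.zeros(n, dtype=bool)
        for i in range(1, n + 1):
            if i not in map_i:
                continue
            partners = [map_ii[i + k] for k in range(klo, khi + 1) if i + k in map_ii]
            if not partners:
                continue
            complete[i - 1] = len(partners) == khi - klo + 1
            a = traj.frames[:, map_i[i], :]
            b = traj.frames[:, partners, :]
            d = np.linalg.norm(b - a[:, None, :], axis=-1).min(axis=1)
            mean[i - 1] = d.mean() + offset
            sd[i - 1] = d.std(ddof=0)
        out[tag] = (mean, sd, complete)
    labels = [
        f"{b}-{ {'A':'T','T':'A','G':'C','C':'G'}[b] }".replace(" ", "")
        for b in duplex.sequence
    ]
    return GrooveProfile(
        minor_width=out["minor"][0],
        major_width=out["major"][0],
        minor_sd=out["minor"][1],
        major_sd=out["major"][1],
        n_frames=traj.n_frames,
        labels=labels,
        minor_complete=out["minor"][2],
        major_complete=out["major"][2],
    )


@dataclass
class PeriodicityResult:
    """Local minima of a groove-width series and their mean spacing."""

    minima_positions: np.ndarray  # 1-based bp indices
    mean_spacing: float | None  # bp; None with < 2 minima
    smoothed: np.ndarray

    @property
    def n_minima(self) -> int:
        return self.minima_positions.size


def minima_periodicity(
    profile: GrooveProfile | np.ndarray,
    smoothing_window: int = 3,
    prominence: float = 0.2,
) -> PeriodicityResult:
    """Positions and mean spacing of minor-groove width minima.

    The series is smoothed with a centered moving average, then strict
    local minima with at least ``prominence`` (A) are located.  A flat
    profile (range below the prominence floor) yields no minima rather
    than a zero spacing.
    """
    series = (
        profile.minor_width if isinstance(profile, GrooveProfile) else
        np.asarray(profile, float)
    )
    finite = np.flatnonzero(np.isfinite(series))
    if finite.size < 3:
        return PeriodicityResult(np.array([], int), None, np.array([]))
    lo, hi = finite[0], finite[-1]
    y = series[lo : hi + 1]
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window)
        counts = np.convolve(np.ones_like(y), kernel, mode="same")
        y = np.convolve(y, kernel, mode="same") / counts
    if np.ptp(y) < prominence:
        return PeriodicityResult(np.array([], int), None, y)
    idx, _ = find_peaks(-y, prominence=prominence)
    positions = idx + lo + 1  # back to 1-based bp indices
    spacing = float(np.mean(np.diff(positions))) if positions.size >= 2 else None
    return PeriodicityResult(positions, spacing, y)
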
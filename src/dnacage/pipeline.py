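"""End-to-end runs: generate a synthetic system, analyze it, report.

The pipeline mirrors the study workflow: build the structure and
pseudo-trajectory for one of the presets (dd20 / dd25 / dd30 /
nucleosome), then compute region RDFs and coordination numbers, the
inter-duplex phosphate RDF, groove-width profiles, the caged/uncaged state
matrix with its summary statistics, end-to-end conformer fractions, and
bridge contacts.  Every run writes a manifest with a config hash so reruns
are reproducible.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .caging import (
    CageCriterion,
    caged_count_series,
    residence_stats,
    segment_duplexes,
    state_series,
    state_summary,
)
from .conformers import ConformerThresholds, detect_bridges, ee_distribution
from .groove import groove_widths, minima_periodicity
from .model import MolecularSystem, select_region
from .rdf import compute_rdf, coordination_number, per_residue_cn, rdf_dd
from .synthetic import (
    DynamicsSpec,
    SuperhelixSpec,
    SystemSpec,
    assemble_nucleosome_system,
    assemble_two_duplex_system,
    generate_trajectory,
)

__all__ = ["RunConfig", "PRESETS", "run_generate", "run_analyze"]

log = logging.getLogger("dnacage")

#: per-preset study conditions: caging threshold (A), Markov kinetics per
#: 25 ns step, count normalization for cross-system comparison.
PRESETS: dict[str, dict] = {
    "dd20": {"separation": 20.0, "threshold": 15.0,
             "p_enter": 0.05, "p_exit": 0.02, "normalization": 1.0},
    "dd25": {"separation": 25.0, "threshold": 19.0,
             "p_enter": 0.10, "p_exit": 0.10, "normalization": 1.0},
    "dd30": {"separation": 30.0, "threshold": 23.0,
             "p_enter": 0.35, "p_exit": 0.35, "normalization": 1.0},
    "nucleosome": {"threshold": 22.0,
                   "p_enter": 0.08, "p_exit": 0.08, "normalization": 3.0},
}


@dataclass
class RunConfig:
    """Everything one generate/analyze run needs."""

    system_tag: str = "dd20"
    outdir: str = "runs/dd20"
    seed: int = 0
    # generation
    n_frames: int = 21
    frame_dt: float = 25.0  # ns
    noise_sigma: float = 0.8
    fraction_caged: float = 0.4
    folded_fraction: float = 0.15
    p_enter: float | None = None  # preset default when None
    p_exit: float | None = None
    traj_format: str = "pdb"  # or "dcd"
    # analysis
    structure: str | None = None  # default: <outdir>/structure.pdb
    trajectory: str | None = None
    threshold: float | None = None
    sample_interval: float = 25.0
    t_start: float = 0.0
    normalization: float | None = None
    dr: float = 0.1
    r_max: float | None = None
    rdf_regions: tuple[str, ...] = ("minor", "major", "phosphate")
    cn_cut: float = 4.55
    dd_cut_total: float = 6.4
    dd_cut_per_p: float = 6.5
    hbond_cutoff: float = 3.5
    pp_angles: tuple[float, float] = (30.0, 60.0)  # parallel/perpendicular gates
    folded_max: float = 7.0
    elongated_min: float = 9.0
    polyamine_resname: str = "SPD"
    smooth: int = 3
    prominence: float = 0.2
    subtract_vdw: bool = False

    def __post_init__(self):
        if self.system_tag not in PRESETS:
            raise ValueError(
                f"unknown system tag '{self.system_tag}'; presets: {sorted(PRESETS)}"
            )
        preset = PRESETS[self.system_tag]
        if self.p_enter is None:
            self.p_enter = preset["p_enter"]
        if self.p_exit is None:
            self.p_exit = preset["p_exit"]
        if self.threshold is None:
            self.threshold = preset["threshold"]
        if self.normalization is None:
            self.normalization = preset["normalization"]
        for name in ("threshold", "sample_interval", "frame_dt", "dr",
                     "cn_cut", "dd_cut_total", "dd_cut_per_p", "hbond_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _structure_path(cfg: RunConfig) -> Path:
    return Path(cfg.structure or Path(cfg.outdir) / "structure.pdb")


def _trajectory_path(cfg: RunConfig) -> Path:
    if cfg.trajectory:
        return Path(cfg.trajectory)
    ext = "dcd" if cfg.traj_format == "dcd" else "pdb"
    return Path(cfg.outdir) / f"trajectory.{ext}"


def run_generate(cfg: RunConfig, force: bool = False) -> dict:
    """Build the preset system, evolve it, and write structure +
    trajectory + ground-truth sidecar + manifest into ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} already exists; pass force=True (--force) to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    crit = CageCriterion(cfg.threshold, cfg.system_tag)
    if cfg.system_tag == "nucleosome":
        system, states0 = assemble_nucleosome_system(
            SuperhelixSpec(seed=cfg.seed),
            fraction_caged=cfg.fraction_caged,
            seed=cfg.seed,
            folded_fraction=cfg.folded_fraction,
            criterion=crit,
        )
    else:
        spec = SystemSpec.dd(PRESETS[cfg.system_tag]["separation"])
        system, states0 = assemble_two_duplex_system(
            spec,
            fraction_caged=cfg.fraction_caged,
            seed=cfg.seed,
            folded_fraction=cfg.folded_fraction,
            criterion=crit,
        )
    dyn = DynamicsSpec(
        p_enter=cfg.p_enter,
        p_exit=cfg.p_exit,
        noise_sigma=cfg.noise_sigma,
        n_frames=cfg.n_frames,
        frame_dt=cfg.frame_dt,
        seed=cfg.seed,
    )
    traj, truth = generate_trajectory(
        system, dyn, initial_states=states0, criterion=crit
    )
    spath = _structure_path(cfg)
    tpath = _trajectory_path(cfg)
    dio.write_structure(system, spath)
    dio.write_trajectory(traj, tpath)
    truth_payload = {
        "system_tag": cfg.system_tag,
        "seed": cfg.seed,
        "threshold": cfg.threshold,
        "frame_dt": cfg.frame_dt,
        "p_enter": cfg.p_enter,
        "p_exit": cfg.p_exit,
        "noise_sigma": cfg.noise_sigma,
        "molecule_ids": truth.molecule_ids,
        "states": truth.states.astype(int).tolist(),
        "times": truth.times.tolist(),
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth_payload, indent=1)
    )
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "files": {
            "structure": str(spath),
            "trajectory": str(tpath),
            "ground_truth": str(outdir / "ground_truth.json"),
        },
        "n_atoms": system.n_atoms,
        "n_frames": traj.n_frames,
        "net_charge": system.net_charge(),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    log.info("generated %s: %d atoms, %d frames", cfg.system_tag,
             system.n_atoms, traj.n_frames)
    return manifest


def _cage_pair(system: MolecularSystem):
    if len(system.duplexes) == 2:
        return system.duplexes[0], system.duplexes[1]
    if len(system.duplexes) == 1:
        return segment_duplexes(system.duplexes[0])
    raise ValueError(f"expected 1 or 2 duplexes, found {len(system.duplexes)}")


def run_analyze(cfg: RunConfig) -> dict:
    """Run the full analysis bundle over a structure + trajectory.

    Writes TSV/JSON result files into ``cfg.outdir`` and returns the
    aggregated summary dict (also written as summary.json).  Individual
    stage failures are logged and recorded; completed outputs are kept.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spath, tpath = _structure_path(cfg), _trajectory_path(cfg)
    if not spath.exists():
        raise FileNotFoundError(f"structure file not found: {spath}")
    if not tpath.exists():
        raise FileNotFoundError(f"trajectory file not found: {tpath}")
    system = dio.read_structure(spath, polyamine_resname=cfg.polyamine_resname)
    traj = dio.read_trajectory(system, tpath, frame_dt=cfg.frame_dt)
    d1, d2 = _cage_pair(system)
    crit = CageCriterion(cfg.threshold, cfg.system_tag)
    thr = ConformerThresholds(cfg.folded_max, cfg.elongated_min)
    summary: dict = {"system_tag": cfg.system_tag, "config_hash": cfg.config_hash(),
                     "n_frames": traj.n_frames, "errors": {}}

    def stage(name, fn):
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            log.error("stage '%s' failed: %s", name, exc)
            summary["errors"][name] = str(exc)

    def _rdfs():
        spd = select_region(system, None, "polyamine_heavy")
        for tag in cfg.rdf_regions:
            per_duplex = []
            for d in (d1, d2):
                sel = select_region(system, d, tag)
                per_duplex.append(
                    compute_rdf(traj, spd, sel, dr=cfg.dr, r_max=cfg.r_max)
                )
            df = per_duplex[0].to_frame()
            df["g"] = np.mean([r.g for r in per_duplex], axis=0)
            df["p"] = np.mean([r.p_counts for r in per_duplex], axis=0)
            df.to_csv(outdir / f"rdf_{tag}.tsv", sep="\t", index=False)
            cn = [per_residue_cn(traj, spd, [d1, d2], tag, r_cut=cfg.cn_cut)]
            cn[0].to_frame().to_csv(outdir / f"cn_{tag}.tsv", sep="\t", index=False)
        summary["rdf_regions"] = list(cfg.rdf_regions)

    def _dd():
        res = rdf_dd(traj, d1, d2, dr=cfg.dr, r_max=cfg.r_max,
                     r_cut_total=cfg.dd_cut_total, r_cut_per_P=cfg.dd_cut_per_p)
        res.rdf.to_frame().to_csv(outdir / "rdf_dd.tsv", sep="\t", index=False)
        res.per_nucleotide.to_csv(outdir / "cn_dd.tsv", sep="\t", index=False)
        summary["dd_cn_total"] = res.cn_total

    def _groove():
        profiles = []
        targets = [("dna1", d1)]
        if len(system.duplexes) == 2:
            targets.append(("dna2", d2))
        else:  # nucleosome: one full-length duplex
            targets = [("dna", system.duplexes[0])]
        for name, d in targets:
            prof = groove_widths(traj, d, subtract_vdw=cfg.subtract_vdw)
            prof.to_frame().to_csv(outdir / f"groove_{name}.tsv", sep="\t",
                                   index=False)
            profiles.append(prof)
        per = minima_periodicity(profiles[0], smoothing_window=cfg.smooth,
                                 prominence=cfg.prominence)
        summary["groove_minima_positions"] = per.minima_positions.tolist()
        summary["groove_minima_spacing"] = per.mean_spacing

    series_holder = {}

    def _states():
        series = state_series(traj, crit, cfg.sample_interval, duplexes=(d1, d2))
        series_holder["series"] = series
        with open(outdir / "states.tsv", "w") as fh:
            fh.write("molecule\t" + "\t".join(f"{t:g}" for t in series.times) + "\n")
            for mid, row in zip(series.molecule_ids, series.states):
                fh.write(f"{mid}\t" + "\t".join(str(int(v)) for v in row) + "\n")
        summ = state_summary(series, normalization=cfg.normalization,
                             t_start=cfg.t_start)
        counts = caged_count_series(series, normalization=cfg.normalization)
        res = residence_stats(series) if series.n_samples >= 2 else None
        payload = {
            "n_always_caged": summ.n_always_caged,
            "n_always_uncaged": summ.n_always_uncaged,
            "n_mixed": summ.n_mixed,
            "ratio_single_to_mixed": summ.ratio_single_to_mixed,
            "ratio_defined": summ.ratio_defined,
            "normalization": cfg.normalization,
            "t_start": cfg.t_start,
            "caged_count_series": counts.tolist(),
            "sample_times": series.times.tolist(),
        }
        if res is not None:
            payload["transition_probability"] = res.transition_probability
            payload["total_transitions"] = res.total_transitions
        (outdir / "state_summary.json").write_text(json.dumps(payload, indent=1))
        summary["caged_counts"] = counts.tolist()
        summary["ratio_single_to_mixed"] = summ.ratio_single_to_mixed
        truth_path = outdir / "ground_truth.json"
        if truth_path.exists():
            truth = json.loads(truth_path.read_text())
            ref = np.asarray(truth["states"], dtype=bool)
            full = state_series(traj, crit, cfg.frame_dt, duplexes=(d1, d2))
            if ref.shape == full.states.shape:
                summary["ground_truth_agreement"] = float(
                    (ref == full.states).mean()
                )

    def _ee():
        series = series_holder.get("series")
        if series is None:
            raise RuntimeError("state series unavailable")
        dist = ee_distribution(traj, series, thr)
        (outdir / "ee_distribution.json").write_text(
            json.dumps({"fractions": dist.fractions, "counts": dist.counts},
                       indent=1)
        )
        summary["ee_fractions"] = dist.fractions

    def _bridges():
        from .conformers import classify_mode

        rows = []
        mode_counts = {"pp": 0, "c_shape": 0, "other": 0}
        by_id = {p.molecule_id: p for p in system.polyamines}
        for f in range(traj.n_frames):
            frame = traj.frames[f]
            for b in detect_bridges(frame, system, (d1, d2),
                                    cutoff=cfg.hbond_cutoff, frame_index=f):
                rows.append(
                    f"{f}\t{b.molecule_id}\t{b.kind}\t"
                    + ",".join(str(n) for n in b.amino_N)
                    + "\t" + ";".join(f"{o}:{d:.2f}" for o, d in b.contacts_d1)
                    + "\t" + ";".join(f"{o}:{d:.2f}" for o, d in b.contacts_d2)
                )
                label = classify_mode(
                    by_id[b.molecule_id], frame, system, (d1, d2), thr,
                    cutoff=cfg.hbond_cutoff,
                    angle_parallel=cfg.pp_angles[0],
                    angle_perpendicular=cfg.pp_angles[1],
                )
                mode_counts[label.label] += 1
        with open(outdir / "bridges.tsv", "w") as fh:
            fh.write("frame\tmolecule\tkind\tamino_N\tcontacts_d1\tcontacts_d2\n")
            for r in rows:
                fh.write(r + "\n")
        (outdir / "modes.json").write_text(json.dumps(
            {"counts": mode_counts, "pp_angles": list(cfg.pp_angles)}, indent=1
        ))
        summary["n_bridge_records"] = len(rows)
        summary["mode_counts"] = mode_counts

    stage("states", _states)
    stage("rdf", _rdfs)
    stage("rdf_dd", _dd)
    stage("groove", _groove)
    stage("ee", _ee)
    stage("bridges", _bridges)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
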
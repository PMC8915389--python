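"""Spermidine conformers (end-to-end distance) and DNA-DNA bridges.

Classifies each molecule-sample as folded (EE < 7 A), intermediate, or
elongated (EE > 9 A), split by caged state, then scans every frame for
amino-N...phosphate-O bridges spanning the two duplexes and labels the
bridging molecules' interaction modes.
"""
from collections import Counter

import dnacage as dc

system, initial = dc.assemble_two_duplex_system(
    dc.SystemSpec.dd(20.0), fraction_caged=0.4, seed=3, folded_fraction=0.2
)
traj, truth = dc.generate_trajectory(
    system, dc.DynamicsSpec(p_enter=0.05, p_exit=0.02, n_frames=21, seed=3),
    initial_states=initial,
)

dist = dc.ee_distribution(traj, truth)
for state, fracs in dist.fractions.items():
    desc = ", ".join(f"{k} {v:.0%}" for k, v in fracs.items())
    print(f"{state:8s}: {desc}")

kinds = Counter()
modes = Counter()
for f in range(traj.n_frames):
    frame = traj.frames[f]
    for b in dc.detect_bridges(frame, system, cutoff=3.5, frame_index=f):
        kinds[b.kind] += 1
        poly = next(p for p in system.polyamines if p.molecule_id == b.molecule_id)
        modes[dc.classify_mode(poly, frame, system).label] += 1
print(f"bridge records over {traj.n_frames} frames: {dict(kinds)}")
print(f"interaction modes of bridging molecules: {dict(modes)}")
# single_N = one amino group hydrogen-bonding phosphates of both helices
# (the O-HNH-O motif); c_shape = a folded molecule spanning the gap.
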
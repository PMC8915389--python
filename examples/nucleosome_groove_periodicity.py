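"""Minor-groove periodicity of real nucleosomal DNA (optional, needs a
locally downloaded structure).

Reads a nucleosome core particle PDB file (e.g. accession 2cv5 fetched
beforehand; protein chains are skipped with a warning), computes the
El Hassan-Calladine minor-groove width profile of the 146-bp duplex and
the spacing of its minima -- expected around 10 bp.

Usage:  python examples/nucleosome_groove_periodicity.py path/to/2cv5.pdb
"""
import sys

import dnacage as dc

if len(sys.argv) != 2:
    sys.exit(__doc__)

system = dc.read_structure(sys.argv[1])
dna = max(system.duplexes, key=lambda d: d.n_bp)
print(f"duplex {dna.chain_i}/{dna.chain_ii}: {dna.n_bp} bp")
traj = dc.Trajectory.single_frame(system)
prof = dc.groove_widths(traj, dna)
per = dc.minima_periodicity(prof, smoothing_window=3)
print(f"{per.n_minima} minor-groove minima, mean spacing: {per.mean_spacing} bp")
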
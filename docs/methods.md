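# Methods

This note documents the models and conventions behind `dnacage`: what each
analysis computes, what the synthetic generator does and does not emulate,
the numerical choices, and the limitations a user should know before
applying the package to real trajectories.

## The caged/uncaged classifier

A spermidine molecule is **caged** at a frame when the distance from its
central nitrogen (N5) to the nearest base-pair center of *each* of the two
parallel duplexes is strictly below a threshold `T`; a tie at exactly `T`
counts as uncaged. Base-pair centers are the purine N1 atoms, which sit
near the pair centroid for both A·T and G·C pairs (the geometric midpoint
of the two glycosidic nitrogens is available as an alternative via the
atom table). Default thresholds follow the system geometry: 15 Å at 20 Å
axis separation, 19 Å at 25 Å, 23 Å at 30 Å, and 22 Å for the nucleosome.
The threshold-to-separation mapping is stored as per-system defaults
rather than a formula; for non-standard separations the assembler
interpolates linearly between the studied values.

For nucleosomal DNA the two "duplexes" are the parallel gyres of one
molecule: base pairs 1–67 and 80–146, with the linker bps 68–79 excluded
from every bp-center list (`segment_duplexes`).

States are sampled on a uniform grid (default every 25 ns, t = 0
inclusive, so a 500 ns run yields 21 samples; `include_t0=False` drops the
first). Molecules are classified over the window `t ≥ t_start` as
always-caged, always-uncaged, or mixed (at least one sample of each
state); the single-to-mixed ratio is `(n_always_caged +
n_always_uncaged)/n_mixed`, defined as 0 when every molecule is mixed and
flagged undefined (None) when none is. Burn-in is a parameter
(`t_start`, default 0), not a hard-coded constant. Residence statistics
are computed on the sampled chain: dwell lengths are maximal caged runs in
units of the sample interval, and the pooled transition probability is
the per-step flip frequency.

## RDFs and coordination numbers

`g(r) = p(r)/(4πr²Δr)/(N_p/V)` with Δr = 0.1 Å by default. Stored shell
counts are normalized per selection-A atom so their cumulative sum up to a
cutoff *is* the coordination number (mean neighbour count of an A atom);
`N_p = |A|·|B|` minus self-pairs when selections overlap. The shell volume
uses the `4πr²Δr` form rather than the exact spherical shell — the two
differ at O((Δr/r)²) and the test suite pins the raw counts against
MDAnalysis' `InterRDF` exactly while allowing that convention difference
in `g`.

Conventions worth knowing:

- `V` is the periodic box volume; non-periodic fixtures fall back to the
  trajectory bounding box with a warning (a periodic simulation never hits
  this branch).
- Minimum-image distances are used whenever a box is present
  (orthorhombic only); stored coordinates are never wrapped.
- In direct pair-count integrations (per-bp CN, per-nucleotide contact
  CN) a pair exactly at the cutoff counts inside (closed upper edge). The
  histogram-based CN is necessarily quantized to bin edges; tests allow
  one boundary-bin pair of slack against brute-force counting.
- "Polyamine heavy atoms" are all C and N atoms.
- Per-base-pair CN (default cutoff 4.55 Å) is the frame-averaged count of
  (region atom of that bp) × (polyamine heavy atom) pairs within the
  cutoff — the direct integral of the per-bp RDF before any per-atom
  normalization. Averaging over the two duplexes is a position-wise mean
  of the two per-duplex profiles, not a pooled selection.
- The inter-duplex RDF (`rdf_dd`) averages the two directions
  (P of DNA1 vs P of DNA2 and vice versa); total CN integrates to 6.4 Å
  and the per-nucleotide contact CN to 6.5 Å — both cutoffs are kept as
  separate defaults on purpose.

## Groove widths

The El Hassan–Calladine width at base pair *i* is the minimum cross-strand
P–P distance over a sliding register: the strand-I phosphate of bp *i*
against strand-II phosphates of bps *i+k*, with k ∈ [0, 6] for the minor
groove and k ∈ [−7, −1] for the major groove (disjoint windows;
minimization over the window). On the package's fiber-model geometry the
minima fall at k = +3 (minor, ≈11.0 Å raw) and k = −4 (major, ≈18.3 Å
raw). Raw P–P distances are reported by default; `subtract_vdw=True`
applies the conventional −5.8 Å phosphate-radius correction. Base pairs
whose register window is entirely unavailable are NaN; bps with a partial
window are computed but flagged (`minor_complete`/`major_complete`
masks), since a partial minimum is biased upward. The exact register
conventions of external groove-width tools differ in detail; equivalence
is claimed at the level of flat-profile and range sanity checks, not
digit-for-digit.

Periodicity: the minor-width series is smoothed with a centered moving
average (default window 3 bp), strict local minima with ≥0.2 Å prominence
are located (`scipy.signal.find_peaks`), and the mean inter-minimum
spacing is reported. A profile whose range is below the prominence floor
yields "no minima", never a zero spacing.

## Conformers and bridges

End-to-end distance (EE) is between the terminal nitrogens N1 and N10 —
the chain termini are nitrogens, so terminal-N and terminal-heavy-atom
definitions coincide here. Folded: EE < 7 Å; elongated: EE > 9 Å;
in-between: intermediate. EE fractions are tabulated per caged-state
partition over the same 25 ns samples as the state series; an empty
partition is reported as absent rather than 0/0.

Bridges are detected on heavy atoms: an amino N within 3.5 Å (a standard
N⋯O hydrogen-bond heavy-atom distance) of ≥1 phosphate oxygen of each
duplex is a single-N bridge (the O-HNH-O motif); two amino nitrogens of
one molecule each contacting a different duplex form a molecule-level
bridge. No hydrogen positions are used or generated — synthetic fixtures
and many trajectory formats lack reliable hydrogens, and the heavy-atom
criterion is the standard proxy.

Mode labels for bridging molecules: `pp` when the conformer is elongated
and the molecule's principal axis (leading eigenvector of the heavy-atom
covariance) lies within 30° of one duplex's local backbone tangent and
beyond 60° of the other's; `c_shape` when the conformer is folded;
`other` otherwise. The backbone tangent at a contact is the unit vector
between the P atoms two residues up- and downstream of the phosphate
nearest the molecule. The 30°/60° gates are this package's
operationalization of a qualitative geometric description; they are
configurable and echoed with every label.

## The synthetic generator

The generator's purpose is closure: produce systems with exactly the
statistical structure the analyses assume, with known ground truth, at the
studied compositions (two 22-bp duplexes of sequence
d(CGCGAATTCGCGCGAATTCGCG) at 20/25/30 Å separation with 30 Spd³⁺, 84 K⁺,
90 Cl⁻ and 31,308 bookkept waters; a 146-bp nucleosome-like duplex with
100 Spd³⁺, 156 K⁺, 166 Cl⁻, 50,583 waters — all charge neutral given one
phosphate per non-5′-terminal residue).

- **Fiber model.** Base pairs stacked at rise 3.38 Å, twist 36°/bp.
  Each residue carries only the analysis-relevant atoms (P, O1P, O2P,
  glycosidic N, purine N1, groove-edge atoms) on a cylindrical template:
  P at radius 9.4 Å, backbone azimuthal half-offset 77°, axial offset
  ±1.0 Å — constants chosen once to land the raw minor/major widths
  (≈11.0/18.3 Å) inside the ranges reported for B-DNA in solution.
  No hydrogens, sugars, or full base rings.
- **Two-duplex assembly.** Duplex 2's helical phase is chosen by a
  deterministic scan maximizing inter-duplex clearance (≥3.1 Å at 20 Å
  separation); assembly fails below 1.5 Å clearance. A requested fraction
  of polyamines is placed with the central N at least 2 Å inside the
  caging threshold for both duplexes, the rest at least 2 Å outside it
  for one duplex, so ground-truth labels are unambiguous under noise; the
  assembler re-classifies its own output and refuses to return a system
  whose labels disagree. Ions are placed uniformly (clash-checked);
  waters are counted, never instantiated. The box pads the content span
  generously so periodic images cannot intrude on the caging geometry.
- **Pseudo-dynamics.** Each molecule evolves by a two-state Markov chain
  (`p_enter`, `p_exit` per frame); on a state change it is translated to
  a freshly sampled caged/uncaged site; i.i.d. Gaussian noise (default
  σ = 0.8 Å) is added to every atom of every frame. Preset kinetics
  mirror the qualitative exchange ordering of the studied systems —
  near-frozen at 20 Å (0.05/0.02), moderate at 25 Å (0.10/0.10), fast at
  30 Å (0.35/0.35), nucleosome-like at 0.08/0.08 per 25 ns step. Default
  trajectory length is 21 frames × 25 ns (the 0–500 ns sampling grid).
- **Superhelix.** The 146-bp duplex follows a superhelical path (radius
  41.9 Å, pitch 25 Å ⇒ ≈78 bp per turn, gyres 25 Å apart, matching the
  1–67 / 80–146 segment split). Bending a helix intrinsically modulates
  cross-strand P–P distances with the helical repeat, so the requested
  minor-width profile (default: 10-bp period, 2 Å amplitude) is *imposed*
  by calibration: a hinge Gauss–Newton solve adjusts the per-bp backbone
  half-offset and P radius until the analyzer's own width (a minimum over
  the register window, hence the hinge formulation) matches the target to
  <0.05 Å. With amplitude 0 the profile is genuinely flat — no minima at
  the 0.2 Å prominence floor.
- **Spermidine.** Ten heavy atoms (N1…N10), bonds 1.47/1.53 Å, valence
  angle 112°; the elongated template is the planar all-trans zigzag
  (EE ≈ 11.2 Å), the folded one turns the N5–N10 arm by 120° in-plane
  (EE ≈ 5 Å). Molecules keep their conformer for the whole run
  (`folded_fraction` sets the mix); conformational kinetics are not
  modelled.

What passing the closure tests does **not** show: the generator has no
forces, no water structure, no sequence-dependent groove narrowing, no
correlated DNA breathing, and its caged/uncaged exchange is memoryless.
Agreement between generator truth and classifier output validates the
analysis machinery, not any physical prediction; real trajectories bring
tautomeric atom-name dialects, non-orthorhombic boxes (unsupported) and
genuinely ambiguous borderline molecules that the margin-based placement
deliberately avoids.

## Numerical and I/O choices

- I/O is MDAnalysis-backed: PDB structures, multi-model PDB and DCD
  trajectories. OP1/OP2 are normalized to O1P/O2P on read. DNA strands
  are renumbered 1..n per chain, 5′→3′, in file order; duplexes are
  detected by chain-length + reverse-complement pairing, and an unpaired
  DNA chain is an error naming the chain. Spermidine residues are found
  by a configurable residue name (default `SPD`), and their terminal vs
  central nitrogens by bond-graph degree (distance < 1.85 Å), falling
  back to N1/N5/N10 atom names — file naming dialects vary.
- The water count is bookkeeping: the generator embeds it as a header
  remark (`NWATER n`) that the reader recovers; instantiated waters are
  counted by residue if present.
- Identical spec + seed reproduces output files byte-for-byte; every
  pipeline run writes a manifest with a SHA-256 config hash.
- Default problem sizes (21-frame trajectories, ≤4,000-atom systems,
  ≤2,000-atom RDF selections) keep any single analysis under a few
  seconds; they are the sizes at which the closure properties are
  asserted, and all scale linearly in frames.

## Known limitations

Orthorhombic boxes only; no helicoidal parameters beyond groove widths
(no roll/twist/slide); no water or metal-ion RDFs; the caged/uncaged
model ignores intermediate "surface-bound" states; bridge detection has
no energetic scoring; the pp/c-shape gates are geometric conventions, not
fitted quantities. The per-nucleotide contact CN assigns phosphates to
residues by strand position (residues 2..n), so 5′-terminal residues
never appear in contact tables.
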
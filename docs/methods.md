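# Methods

## Model overview

The package builds a purely descriptive, multi-scale geometric model
of chromatin. No mechanics, energetics or experimental-constraint
fitting is involved: every scale is generated from a small set of
parameters plus a seed, and the scales are kept mutually consistent by
construction. The model's value is as a *coordinate system* — a way to
place genomic annotations in 3D — not as a prediction of any
particular nucleus.

All internal lengths are nanometres; genomic coordinates are 0-based
half-open throughout the library. The command line accepts UCSC-style
1-based inclusive `chrom:start-end` strings and converts them at the
boundary. PDB and XYZ output converts nm → Å (×10).

## Nuclear scale: giant-loop random walk

Each chromosome is a chain of closed giant loops (default 3 Mbp)
attached to a backbone, one walk step (150 nm) per 30 kbp, confined to
a nuclear sphere of radius 5,000 nm. These defaults are
literature-plausible round numbers for a human-sized nucleus and are
all configurable; the manifest records the values used.

Two invariants are exact by construction: every step has exactly the
nominal length, and every loop closes exactly on its anchor. A
Brownian bridge satisfies neither exactly, so loops are sampled as
*closed equilateral random polygons*: shuffled antipodal pairs of
uniform unit vectors (plus one planar triple at 120° when the step
count is odd). The antipodal pairing reduces the variance of loop
shapes relative to a true uniform closed polygon ensemble; for a
display-oriented model this bias is acceptable and is documented here
rather than hidden.

Confinement uses whole-loop rejection (a loop that exits the sphere is
resampled, up to 500 attempts, then rigidly reflected through its
anchor) and per-step resampling-then-reflection for backbone steps.
This preserves both exact invariants. With the default geometry
(loop extent ≈ 1.5 µm rms versus a 5 µm nucleus) rejection almost
never triggers.

The unconfined, non-looping variant (`close_loops=False`,
`nucleus_radius_nm=inf`) is a plain ideal chain and recovers
⟨R²⟩ = N·b²; this is verified by Monte-Carlo in the test suite
(200 replicates of 1,000 steps, 3-standard-error band).

## Fiber scale

The fiber path subdivides the nuclear polyline by genomic coordinate
(one point per 1,200 bp ≈ 6 nucleosome repeats) using piecewise-linear
interpolation, plus seeded isotropic Gaussian jitter (default 3 nm) to
avoid perfectly straight segments. Zero jitter reproduces the
interpolated polyline exactly, which the tests use as a degenerate-case
oracle. Jitter that would leave the nucleus is resampled and, as a
last resort, dropped for that point.

## Nucleosome scale

Nucleosomes tile the chromosome with a fixed repeat (default 200 bp =
147 bp wrap + 53 bp linker) starting at bp 0; the final linker absorbs
the remainder so the bp-conservation identity
Σ(wrap + linker) = chromosome length holds exactly. Explicit position
lists (e.g. experimentally mapped nucleosomes) are validated for
sorting, overlap and chromosome bounds; bp before the first record are
tracked as a leading linker so conservation still holds.

Particles are arranged as a solenoid: the superhelix axis follows the
local fiber tangent, and successive particles rotate 360°/6 about it
at a radial offset of 8 nm — inside the 15 nm fiber radius, so
nucleosome origins stay within one fiber radius of their fiber point.

**Frame anchoring.** A record's frame origin is the *centroid of its
147 wrapped bp positions*, not the superhelix cylinder centre. Over
1.65 turns the bp centroid sits ≈0.7 nm off the cylinder axis, so
anchoring at the geometric centre would make "centroid within 0.5 nm
of the record origin" — the cross-scale consistency contract —
unsatisfiable. The cylinder-axis anchor is recovered from the frame
via a fixed in-frame offset computed once from the superhelix
parameters.

## DNA scale (on demand)

Wrapped bp lie on a left-handed helix of radius 4.18 nm, pitch
2.39 nm, 1.65 turns over 147 bp — canonical core-particle crystal
values, all configurable. bp are uniformly spaced in arc length
(≈0.296 nm/bp along the path); this is geometrically incompatible with
the straight-DNA rise of 0.34 nm/bp, and uniform arc spacing was
chosen for smoothness of the wrapped path. Each bp frame's e3 is the
path tangent, e1 starts radially inward, and the frame twists about
the tangent by 360°/10.5 per bp.

Linker bp between consecutive wraps interpolate position linearly and
orientation by spherical interpolation (scipy Slerp) between the exit
frame of one wrap and the entry frame of the next; leading/trailing
linkers are straight B-DNA propagated from the nearest wrap frame. No
bending-energy model is applied. Every bp's frame is a closed-form
function of the records alone, so chunked queries concatenate to
bit-identical coordinates — the basis of the drill-down workflow.

Pseudo-atoms: 20 per bp (10 per strand — phosphate, sugar-ring and
base pseudo-atoms at B-DNA-like radii, backbones separated by a 154°
minor-groove angle). This is display geometry, not chemistry; the
template is plain data and fully user-replaceable. Sequence is
optional and affects labelling only, never coordinates.

## Storage format

Three scales per chromosome are serialised as XML, chunked into blocks
of ≤10,000 elements, each block an independently decompressible gzip
member (level 6, mtime 0 — no timestamps, so equal models give
byte-identical files). The uncompressed manifest records all build
parameters plus every block's byte offset and bp span, enabling range
loads that decode only intersecting blocks. Coordinates are written
with 3 decimals in nm (±0.5 pm quantisation, far below any geometric
tolerance); round-trip equality is asserted at 5×10⁻⁴ nm. The DNA
scale is never serialised — PDB/XYZ export is the only atomic
persistence.

Compression accounting extrapolates the store's bytes/bp to a
reference genome size (default 3×10⁹ bp) and compares with the naive
atomic figure genome_bp × atoms/bp × 3 coords × 4 bytes. On a 10 Mbp
default-parameter fixture the measured ratio is ≈1,270× (≈0.57 GB
extrapolated); the nucleosome scale dominates the payload at 12
fixed-precision frame numbers per 200 bp.

## Annotation projection

BED is parsed as 0-based half-open, WIG declarations as 1-based
(fixedStep/variableStep; bedGraph auto-detected by 4-column data
lines). Projection clips each value interval against element bp spans.
`coverage` counts annotated bp per element *with multiplicity*, so
Σ coverage = Σ clipped interval lengths exactly; `sum` adds
value × bp; `mean` = sum/coverage; `max` is the largest single value
touching the element. A brute-force per-bp assignment oracle checks
the clipping arithmetic on small fixtures.

SNP phasing reports, per single-bp SNP, its record, offset from the
wrap start, helical phase angle (offset × 360/10.5 mod 360) and axial
position along the superhelix axis. Proximity classification measures
|site midpoint − TSS start| and calls *near* strictly below the
threshold (default 10 kbp), so a site at exactly the threshold is far.
The midpoint convention is a design choice (nearest-edge would be the
alternative) and is configurable in spirit via the interval inputs.

## Export

PDB uses fixed-column v3.3 ATOM records (residue name `DN`, chain A,
resSeq = bp index + 1 wrapped at 9999, element from the template).
Serials stop hard at 99,999 — no hybrid-36 extension — and coordinate
fields refuse to overflow their 8 columns: selections far from the
nuclear origin must be recentred (the CLI recentres on the selection
centroid automatically). gemmi serves as an independent parse-back
oracle in the tests. PovRay output emits one object per scene
primitive (polylines as a single `sphere_sweep`); a degenerate
cylinder becomes a sphere with a logged warning. Scene generation
renders nuclear/fiber scales as polyline + spheres, nucleosomes as
11 nm × 5.5 nm cylinders (canonical display dimensions, configurable)
with polyline linkers, DNA as one sphere per atom (range capped,
default 100 kbp), plus optional TSS expression spheres
(signed green/red, zero = neutral grey, saturation monotone in
|value|) and binding-site boxes (orange near / yellow far).

## Synthetic fixtures

The fixture generators emulate only the *shape* of real inputs:
uniform SNP/TSS placement, truncated-normal nucleosome repeats
(symmetric truncation keeps the mean unbiased, a 157 bp floor keeps
wraps non-overlapping), a planted near/far mixture of binding sites,
and zero-mean Gaussian expression log-ratios. They deliberately do not
reproduce the sequence biases, clustering or correlation structure of
real datasets, so passing tests demonstrate correctness of the
machinery, not biological realism. Every generator is a pure function
of (spec, seed).

## Problem sizes and numerical choices

The test suite and the reproduction script use 100 kbp–10 Mbp
single-chromosome models, chosen as the smallest sizes at which every
quantity of interest (loop closure, storage extrapolation, cross-scale
consistency at thousands of nucleosomes) is well exercised.
Orthonormality and handedness of frames are asserted at 1e-9; the
superhelix polyline length matches the analytic helix arc length to
0.1% for wraps ≥147 bp sampled over ≤2.5 turns (the chord-sum error
grows quadratically with the per-bp angular step, so very coarse wraps
would need a finer comparison path).

## Known limitations

- No inter-chromosome exclusion or territory modelling beyond seeded
  start points; no Hi-C/fractal-globule constraint fitting.
- Straight-linker DNA and slerp blending ignore DNA bending mechanics;
  linker path curvature is not physically meaningful.
- The closed-loop sampler's antipodal pairing is not the uniform
  measure on closed equilateral polygons.
- Histone proteins are not modelled at atomic detail; nucleosomes are
  cylinders at display scale.
- bigBed/bigWig, GFF and mmCIF are out of scope.
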
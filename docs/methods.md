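# Methods

## Model

The quantity of interest is the local deformation of a DNA duplex across a
short junction: how much the helical axis changes direction (bend magnitude
β_h), toward which azimuth (bending direction γ_h), and how much helical
twist accumulates across the junction (ζ_h), from which the underwinding
N × 36° − ζ_h follows for an N-bp junction. The model treats the two flanking
segments H1 and H2 as locally ideal B-form helices and assigns all deformation
to the junction J between them. This is appropriate for protein-induced
kinks localized to a few base pairs (such as the PAM-adjacent hinge imposed
by Cas effectors) and is not a curvature model for smoothly bent DNA.

### Frames from superposition

Each 3-bp flanking segment gets a frame by building an ideal B-form helix
with the segment's own sequence and superposing it (Kabsch, proper rotations
only) onto the observed coordinates. The atom set is the base-ring heavy
atoms plus C1′ of both strands of all three pairs — backbone atoms beyond C1′
are excluded because sugar-phosphate conformers are the noisiest part of
cryo-EM models, while ring atoms are rigid and well resolved. The frame
carried to the structure is the ideal helix's **central-pair** frame
(symmetric in the segment, least end effect). The fit RMSD is reported so
users can judge how B-form-like each flank actually is.

### Euler convention and registration

The relative rotation R between the H1 and H2 frames is decomposed as active
ZYZ, R = Rz(α)·Ry(β_h)·Rz(γ). This convention makes β_h exactly the angle
between the two helical axes (matching its defined range 0–180°) and reduces
ζ_h = α + γ to cumulative helical twist when the helix is undistorted. β_h is
computed as atan2(√(R₃₁²+R₃₂²), R₃₃) rather than arccos(R₃₃): the arccos form
loses half the floating-point digits near β_h = 0, and the straight-helix
null result should be clean to ~1e-13°, not ~1e-6°.

Raw angles between central-pair frames include the flanks' internal twist
(for the default layout, 3 extra ideal steps = 108°). The report therefore
re-references: γ_h is expressed in the frame of H1's junction-proximal end
pair, and ζ_h is reduced by (S − N) × 36°, where S is the step count between
the two central pairs. Because these corrections are rotations of each helix
about its own axis, β_h is untouched, and ζ_h becomes the twist accumulated
over exactly the N junction steps: an undistorted duplex yields
ζ_h = N × 36° and underwinding 0 for *every* contiguous H1/J/H2 split, and an
injected junction twist deficit Δ is recovered as underwinding = Δ
independent of where inside the junction the hinge sits. The convention
string is embedded in every report.

Gimbal handling: at β_h = 0 only α + γ is determined, so γ_h is reported as 0
and the report flagged `direction_undefined` (threshold 1e-3°); at β_h = 180°
the twist is also undefined. A `large_underwinding` flag fires when
|underwinding| > 90°, since ζ_h wrapping makes underwinding meaningful only
for junctions unwinding well under half a turn (the structures this analysis
is designed for are ≤ ~30°).

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `FiberParams.twist_per_step` | 36.0° | ideal B-form twist per bp step; also the reference twist in the underwinding formula |
| `FiberParams.rise_per_step` | 3.38 Å | ideal rise per step |
| `JunctionDefinition.h1/j/h2` | (−3,−2,−1)/(+1,+2)/(+3,+4,+5) | 3-bp PAM-proximal helix, 2-bp junction, 3-bp spacer helix |
| `C1_C1_RANGE` | [8.5, 12.5] Å | accepted glycosidic C1′–C1′ span per pair (canonical ≈ 10.4–10.8 Å) |
| `DIRECTION_TOL` | 1e-3° | bend below which the direction is reported undefined |

The fiber values are the canonical B-DNA parameters; they are configurable
for sensitivity analysis and are recorded in every report because the
underwinding scale is defined relative to them. H1 defaults to the three
junction-proximal PAM pairs (−3..−1) rather than the full 4-bp TTTV PAM, so
that both flanks are 3 bp; −4..−2 can be selected instead via the junction
definition.

Base-pair templates use the standard nucleic-acid base reference frame
coordinates (Olson 2001 convention), ring atoms + C1′ only. The C1′–C1′ span
is constant for all pairs of a given type but differs by ~0.1 Å between A:T
and G:C templates.

## Duplex selection

Pairing is supplied explicitly (chain ids plus residue/PAM-index triples),
never inferred from hydrogen bonds: crosslinked interrogation-complex
structures contain chemically modified bases and dual-conformation (stacked/
flipped) bases that defeat naive Watson-Crick detection. Validation instead
checks the C1′–C1′ window and WC complementarity (with an explicit `modified`
exemption list). The distance window alone does not catch every one-residue
misregistration — a shifted partner can sit 9–12 Å away — so the
complementarity check is the primary guard for non-degenerate sequences.
Alternate locations resolve to the highest-occupancy conformer, ties broken
by altloc id, with an `altloc=` override to force a named conformer (e.g. to
analyze a flipped rather than stacked base). Since junction atoms never enter
frame fitting, bend results are insensitive to conformers inside J.

## Synthetic data

`generate_bent_duplex` emulates the deformation the analysis is meant to
measure: an ideal fiber duplex whose frame propagation is premultiplied at a
single hinge by Rz(direction)·Ry(bend)·Rz(−direction), whose N junction steps
each twist by (36 − Δ/N)°, and whose atoms optionally receive iid isotropic
Gaussian noise (one seeded generator per call; the seed is recorded in the
ground-truth record). The hinge acts before the twist of the step entering
the first junction pair, which makes the recovered γ_h equal the injected
direction exactly.

What the generator does **not** emulate: sequence-dependent step parameters,
propeller/roll/slide, backbone atoms beyond C1′, base flipping or other
extra-helical conformers, and spatially correlated (B-factor-like) coordinate
error. Passing recovery tests therefore demonstrates correctness of the
geometry pipeline under the stated deformation model, not robustness to every
pathology of experimental maps; the fit RMSDs are the practical diagnostic on
real structures.

Default study conditions for the recovery experiments: the bend/underwinding
levels of the three observed structures (42°/18°, 45°/19°, 53°/28°), a
zero-noise grid over bends 10–80° × deficits 0–40°, and a noisy condition of
σ = 0.5 Å with 100 replicates per cell — sizes chosen so the whole suite and
the acceptance run complete in seconds on one CPU while giving ≤ ~0.1°
standard error on the reported MAEs. At σ = 0.5 Å the mean absolute bend
error is ≈ 1°, comfortably inside the 5° acceptance bound the package sets
for itself.

## 2-AP normalization

Replicates (≥ 2; triplicates in the emulated design) are summarized by mean
and *sample* (n−1) standard deviation — the estimator choice is stated here
because "standard deviation" alone is ambiguous. Each condition is normalized
to the dsDNA-only control **at the same probe position** (each probe has its
own control sequence); the ratio uncertainty uses first-order propagation
(x̄/ȳ)·√((σx/x̄)² + (σy/ȳ)²), which treats numerator and reference as
independent and is accurate for CVs ≪ 1. dsDNA rows normalize to exactly 1
with σ = √2·σy/ȳ. Time-point selection from kinetic reads (75 s in the
emulated design) happens in the CSV reader; statistics always operate on
already-selected readings. No kinetic modeling is attempted.

## Numerical choices and edge cases

- Kabsch uses SVD with the determinant sign correction, so reflections are
  never returned even for planar point sets; < 3 points or collinear sets
  raise a degenerate-geometry error rather than returning an arbitrary frame.
- Angles wrap to (−180°, 180°]; underwinding itself is never re-wrapped so
  its sign always distinguishes under- from overwinding.
- All randomness flows through `numpy.random.default_rng` with caller-visible
  seeds; repeated calls with the same seed are bit-identical.
- Duplexes reject duplicate or non-consecutive PAM indices at construction;
  index bookkeeping maps the zero-skipping PAM scale onto consecutive
  ordinals internally.

## Known limitations

- Single-junction model only: no scanning for "the" bend along a long duplex,
  no multi-junction curvature integration, no roll/tilt/slide decomposition.
- B-form reference only (no A-form/Z-form, no RNA:DNA hybrids).
- γ_h is convention-dependent (reference frame of H1's junction-proximal end
  pair); it is validated against the generator's ground truth, not against
  any published per-structure value.
- PDB round trips are exact only to the format's 1e-3 Å coordinate precision.
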
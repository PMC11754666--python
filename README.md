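# bendscan

Quantify local DNA bending and unwinding in protein–DNA complexes from atomic
coordinates, using inter-helical Euler angles — the geometry that CRISPR–Cas
effectors such as Cas12a and Cas9 impose on PAM-adjacent DNA while
interrogating a target. The package is aimed at structural biologists who have
a duplex (with or without bound protein) in PDB/mmCIF form and want a
reproducible bend/underwinding number per junction, plus the solution-side
companion: normalization of 2-aminopurine (2-AP) base-flipping fluorescence
assays with propagated uncertainties.

## Method

A PAM-indexed duplex (positions ..., −2, −1 in the PAM; +1, +2, ... in the
protospacer; there is no 0) is split into an upstream 3-bp helix **H1**
(default −3..−1), an **N**-bp junction **J** (default +1, +2) and a downstream
3-bp helix **H2** (default +3..+5). For each of H1 and H2 an idealized B-form
3-bp helix with the matching sequence (fiber model: twist 36°/bp, rise
3.38 Å/bp, standard base reference frames) is superposed onto the observed
base-ring + C1′ atoms by Kabsch least squares, carrying the ideal helix's
central-pair frame onto the structure. The relative rotation R between the two
fitted frames is decomposed in the active ZYZ convention,

    R = Rz(α) · Ry(β_h) · Rz(γ),

giving the bend magnitude β_h ∈ [0°, 180°] (exactly the angle between the two
helical axes), the bending direction γ_h = α, and the inter-helical twist
ζ_h = α + γ, both wrapped to (−180°, 180°]. After removing the helices' own
internal twist so that ζ_h counts only the N junction steps, the underwinding
is

    underwinding = N × 36° − ζ_h

with positive values meaning the junction is underwound relative to B-form.
For an undistorted B-DNA duplex every junction split returns β_h = 0 and
underwinding = 0 to numerical precision.

For the 2-AP assay, replicate intensities are averaged (sample SD, n−1) and
each condition is normalized to the dsDNA-only signal at the same probe
position; the ratio uncertainty follows

    σ_r = (x̄/ȳ) · sqrt((σ_x/x̄)² + (σ_y/ȳ)²).

## Worked example

Generate a duplex carrying a known 53° hinge bend and 28° junction twist
deficit — the largest distortion condition studied — and analyze it:

```python
import bendscan as bs

spec = bs.DistortionSpec(bend=53, direction=30, extra_untwist=28)
duplex, truth = bs.generate_bent_duplex("GCTTTGACTGACGT", spec)
report = bs.analyze_junction(duplex)
print(f"beta_h = {report.beta_h:.2f} deg, "
      f"underwinding = {report.underwinding:.2f} deg, "
      f"gamma_h = {report.gamma_h:.2f} deg")
```

```
beta_h = 53.00 deg, underwinding = 28.00 deg, gamma_h = 30.00 deg
```

The analysis recovers the injected bend magnitude, twist deficit and bend
direction exactly at zero noise; with 0.5 Å Gaussian coordinate noise the mean
absolute bend error over 100 replicates is about 1°.

The same pipeline runs from the shell on deposited coordinates:

```sh
bendscan simulate --sequence GCTTTGACTGACGT --bend 53 --untwist 28 \
    --out toy.pdb --truth truth.json
bendscan analyze --structure toy.pdb --config pairing.json --out report.json
bendscan 2ap --input plate.csv --timepoint 75 --reference dsDNA
```

where `pairing.json` supplies the chain ids and the explicit
(target-strand residue, non-target-strand residue, PAM index) map:

```json
{"ts_chain": "A", "nts_chain": "B",
 "pairs": [[1, 14, -3], [2, 13, -2], [3, 12, -1], [4, 11, 1], "..."]}
```

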
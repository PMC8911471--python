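# Methods

This note documents the models behind `adaptqa`: what is computed, what
the synthetic phantom does and does not emulate, the defaults and why,
and the numerical conventions that affect results.

## Spatial model

All structures live on one axis-aligned anisotropic voxel grid in patient
millimetre coordinates, with voxel-centre semantics (the grid origin is
the centre of voxel (0, 0, 0)) and z increasing cranially. The default
grid is 96 × 96 × 64 voxels at 1.5 × 1.5 × 3.0 mm — a typical MR-LINAC
planning resolution over a pelvic field of view. Grids are *compatible*
only when origin, spacing and shape match exactly; every cross-structure
operation requires compatibility and nothing is ever resampled silently.
General direction cosines are rejected at the DICOM boundary.

Rasterization sets a voxel when its centre falls inside an odd number of
that slice's polygons (even-odd rule), which resolves holes the way RT
structure sets express them. Expansion uses the exact Euclidean distance
transform with the physical spacing; a voxel exactly at the margin is
included (≤), the conservative reading for target margins. Depth-limited
trimming measures an organ voxel's depth as its distance to the nearest
non-organ voxel, so a boundary voxel has positive depth; the EDT-based
depth map is cross-validated against a brute-force all-pairs oracle on
small grids in the test suite and then used at phantom scale.

## Target rules and constraint tiers

The planning target is derived mechanically from the CTV and the day's
organs: trim the CTV so it extends at most 3 mm into the bladder, subtract
the bowel, then expand by 3 mm to form the PTV. The rule order is fixed
(trim, subtract, expand) and recorded on every derived structure. The PTV
is deliberately **not** re-trimmed against the organs after expansion —
the rules as practised stop at the expansion — so the PTV may re-enter
bladder or bowel by up to the margin, which is exactly why those organs
can receive near-prescription dose. For evaluation, the bowel is cropped
15 mm above the CTV's most cranial occupied slice ("superior extent" =
centre z of that slice).

Constraints carry an ideal and an acceptable-variation upper bound;
boundary equality belongs to the better tier, a plan's tier is its worst
constraint tier, and "pass" means met or acceptable variation. Only the
bladder-Dmean and bowel-D(0.03 cc) pairs enter tier classification; PTV
coverage and conformity are reported alongside but do not gate the tiers.

## DVH conventions

Scalar metrics come from raw voxel doses, never from the binned DVH.
Volume-indexed metrics (Dx%, D(v cc)) place each sorted voxel's volume at
its cumulative midpoint and interpolate linearly between voxels; requests
hotter than half a voxel clamp to Dmax. There is no sub-voxel
partial-volume model. The RTOG conformity index counts every voxel in the
dose grid at or above 95% of prescription — not only voxels inside a body
or structure — divided by the PTV volume, so spilled dose inflates CI by
construction. The default cumulative-DVH bin width is 0.1 Gy.

## The phantom

The phantom stands in for the study cohort; it emulates the *statistical
conditions* of the evaluation problem, not images or beams.

**Anatomy.** Bladder: ellipsoid (semi-axes ≈ 33 × 25 × 28 mm, ≈ 97 cc)
scaled by a filling factor. Bowel: a spline tube (radius ≈ 10 mm) looping
through the upper pelvis and descending to graze the CTV's cranial
aspect, kept ≥ 2 mm clear of the bladder. CTV: an ellipsoid that is
trimmed so its maximum depth of penetration into the bladder equals the
requested value (default 10 mm, the low-pelvis contouring convention) —
the same mechanism guarantees the requested depth is recovered from the
generated masks to within a voxel diagonal. Per-patient variation jitters
centres and semi-axes by a few percent under a seeded generator.

**Daily variation.** Bladder and bowel are advected through a smooth
band-limited random displacement field (correlation ≈ 30 mm) whose RMS
magnitude is the deformation amplitude (default 4 mm, a typical daily
pelvic organ shift); the field is damped until each organ's volume change
stays within ±30%. Targets are copied rigidly, as they are in the
workflow.

**Observer noise.** An observer's re-contour thresholds the structure's
signed distance function at `bias + amplitude × G`, where `G` is a
unit-variance Gaussian random field with 10 mm correlation length. This
produces smooth, spatially coherent over- and under-contouring rather
than voxel noise. Zero amplitude and bias reproduce the reference
exactly; expected Dice decreases monotonically with amplitude, and a
Monte-Carlo routine inverts that curve to hit a requested expected Dice.
Note a discretization floor: boundary shifts smaller than the voxel pitch
flip no voxels, so amplitudes below ≈ 1 mm on the default grid leave
contours unchanged. The default panel (physicians 1.0/1.2 mm, therapists
1.4–1.8 mm, student 2.2 mm with slight under-contouring bias) was chosen
once so pairwise Dice lands in the 0.94–0.99 range reported for
physician–therapist panels, with the physician pair best.

**Dose surrogate.** There is no optimizer or beam physics. Dose is a
plateau at prescription inside the PTV, crosses 95% of prescription at a
controllable distance outside it (the *conformity bulge*, default 4 mm,
placing cohort mean CI near 1.15, the reported participant regime), then
falls off exponentially (scale 8 mm). A bounded multiplicative random
field (default ±5%) adds hot and cold spots. Sparing is modelled by
capping dose at 93% of prescription inside the **adapter's own** evaluated
organs plus a 2 mm penumbra. Because the cap follows the adapter's
contours, an under-contoured bowel leaves true bowel tissue uncapped at
near-prescription dose — the exact mechanism by which contouring error
becomes a silent gold-standard failure. The `ideal()` parameter set
(no noise, no cap, 0.5 mm bulge) gives full PTV coverage and CI within
voxelization of 1.

**Cohort defaults.** Ten patients (six conventional courses at 1.8–2
Gy/fraction totalling 45–58 Gy, four short courses at 5 Gy/fraction
totalling 15–25 Gy), two adapted fractions each, six observers. With
these conditions the phantom reproduces the qualitative findings: the
adapters' own evaluations essentially always pass (the surrogate spares
what was contoured), silent failures concentrate in the highest-dose
patients and the noisier observers, and the safety rate (delivered
acceptably or halted) exceeds the gold pass rate.

**What passing tests do not show.** The phantom has smooth convex-ish
organs, a single anatomy template, no air/bone heterogeneity, no
optimizer trade-offs, and clinical failures of the adapter's own plan are
essentially absent (a real optimizer sometimes cannot meet constraints;
the surrogate always can, by capping). Rates measured on the phantom
characterize the pipeline's logic under controlled conditions, not
clinical performance.

## Statistics

Dice of two empty masks is an error, never a value — a silent 1.0 would
mask a missing contour pair. Table standard deviations are sample (n−1).
The one-way fixed-effects ANOVA is delegated to `scipy.stats.f_oneway`
behind a validating wrapper (≥ 2 groups of ≥ 2 finite values; the
all-constant case is rejected as 0/0); its type-I error is verified by
simulation in the acceptance tests. The pipeline's default grouping for
the ANOVA is by comparison pair, pooling structures. Because the phantom's
observers genuinely differ in noise level, the cohort ANOVA typically
rejects — with real observers of similar skill it need not. Percentages
are computed exactly (integer arithmetic through `decimal`) and rounded
half-even to one decimal, with raw numerator/denominator always reported
alongside.

## Workflow dispositions

Per fraction: clinical FAIL → halted for on-table review; clinical pass
with gold FAIL → delivered suboptimal (silent failure, caught offline);
otherwise delivered OK. The dispositions are total and mutually
exclusive, and safety rate ≥ gold pass rate holds identically (a silent
failure is always also a gold failure). No replanning after offline
review is simulated.

## Problem sizes

Unit tests use small grids (≤ 64 × 64 × 48, coarsened 2.25 × 2.25 × 4 mm
for phantom-scale checks) so brute-force oracles stay tractable;
acceptance checks run the full default cohort at 96 × 96 × 64. These
sizes were chosen as the smallest that keep voxelization effects well
below the tolerances being asserted.
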
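# Methods

## Scope and model

`hipnav` implements the cup-placement precision-assessment workflow of a
CT-based THA navigation system as a reusable, seeded pipeline:

1. **Patient alignment** — register ~26 probed bone-surface points (in an
   arbitrary tracker/"rater" frame) to the pre-op pelvis surface by rigid
   point-to-surface registration.
2. **Guide readout** — express the tracked cup pose in the pre-op pelvic
   frame through the alignment transform and read off operative
   anteversion/inclination and depth.
3. **Post-op examination** — register the post-op bone surface back to
   pre-op coordinates, transform the post-op cup pose along, and read the
   same quantities.
4. **Navigation error** — `guide − post-op` per metric; study-level
   mean ± SD, range, absolute-value summaries, and 5°/10° exceedance.

The pelvis is treated as perfectly rigid throughout; all deformation,
segmentation and imaging physics are outside the model.

## Coordinate frames and angles

The anterior pelvic plane (APP) frame is built from the two ASIS and two
pubic landmarks: lateral axis along right→left ASIS; anterior axis the
plane normal through both ASIS and the pubic midpoint, with the sign fixed
anteriorly by the pubic left/right ordering (a label-symmetric construction,
so mislabeled ASIS flip only the lateral axis); superior axis by
Gram–Schmidt on the pubis→ASIS-midpoint direction. The frame is
right-handed with the lateral axis toward the patient's *left*; right hips
are handled by mirroring the lateral component of the cup axis at
angle-computation time, so one angle formula serves both sides. The
functional pelvic plane (FPP) rotates the APP about the lateral axis by the
pelvic tilt; positive tilt is anterior tilt (superior axis leaning
forward). The tilt sign and the pubic-landmark choice are package
conventions — the clinical systems this emulates do not publish theirs.

Cup angles follow the Murray conventions (see README for the formulas).
The operative pair is the primary readout (it is what a navigation display
shows); radiographic and anatomic are provided as conversions and are
validated against the closed-form identities. Conversions are refused at
inclination 90°, where the other conventions degenerate.

The signed depth difference projects the centre displacement onto the
**guide** cup axis (the displayed navigation value is self-referential);
positive = lateral/shallower. Projecting instead on the post-op axis
changes the value only at second order in the angle error.

## Registration

*Closest-point queries.* Exact closest point on any triangle (interior,
edge or vertex; Ericson's Voronoi-region case analysis) under an AABB tree
with branch-and-bound traversal, numba-compiled. The tree prunes only boxes
that provably cannot contain a closer point, so results equal an exhaustive
scan to machine precision — the tests compare against an independent
plane-projection implementation.

*ICP.* Alternating exact correspondence / Kabsch update, with the RMS
point-to-surface residual asserted non-increasing at every iteration
(violations raise rather than warn — they indicate a broken correspondence
step). Stopping: RMS change < `tol` (default 1e-6 mm) or 200 iterations.
Because point-to-point ICP converges only linearly along surface-sliding
directions, a short point-to-plane Gauss–Newton polish runs after the main
loop; polish steps are accepted only while the RMS does not increase, which
preserves the monotonicity contract and removes the ~1e-4-degree
convergence floor that pure ICP leaves on noiseless data.

*Multi-start.* The proprietary global search of the clinical system is
replaced by a seeded multi-start around a coarse alignment (Kabsch on
region centroids of the labeled points vs. the model's region centroids;
16 starts, perturbations up to ±15°/±20 mm by default). Starts are first
run on a short budget (30 iterations, 1e-4 mm tolerance) to separate
basins; the unperturbed start plus the best finalists are refined to full
tolerance. ICP is memoryless, so truncation+continuation reproduces the
uninterrupted trajectory and the unperturbed start can never end worse
than a plain single-start run (up to polish, which is a local refinement).

*Dense post-op registration.* The intensity-based volume registration of
clinical practice is replaced by dense surface ICP on the segmented
meshes: the pelvis is rigid and the study's own quality metric is surface
distance. A subsample (default 1000) of post-op vertices is registered to
the pre-op surface. All four proper principal-axes coarse alignments are
refined — the iliac blade's two largest inertia eigenvalues differ by only
~2%, so PCA sign ranking alone is unreliable — and the principal axes are
computed from the full vertex clouds for the same reason. The
alignment-accuracy readout is the mean surface distance of all transformed
post-op vertices to the pre-op surface (asymmetric by construction; both
directions can be reported).

*Control screw.* `control_screw_check` re-probes one fixed point through a
candidate alignment; default tolerance 1.0 mm (configurable — no published
threshold exists).

## Synthetic scenes

The generator produces everything one surgery contributes, with every
ground-truth transform recorded and all randomness drawn from one
`SeedSequence`:

* **Pelvis** — a radially parameterized surface over icosphere directions:
  an ellipsoidal iliac blade (semi-axes 28/52/70 mm) with a seeded smooth
  low-frequency deformation (±5%), carved by an exact ray-sphere
  intersection to form a spherical acetabular cavity (default radius
  24 mm). Cavity vertices lie *exactly* on the construction sphere, so the
  acetabular-centre oracle is exact. Landmarks sit at fixed parametric
  sites; probing regions (iliac crest, anterior wall, posterior wall,
  acetabular rim) are defined by geometric predicates. Right-side scenes
  are exact mirrors of left-side ones.
* **Cup** — centre at the acetabular centre plus a depth offset along the
  target axis; axis from the operative target (default 15° anteversion /
  40° inclination, the classical target orientation; depth 0).
* **Rater samples** — per rater, `n_points` (default 26, split 8/6/6/6
  over the regions) drawn area-weighted on the region faces with isotropic
  Gaussian noise (default σ = 0.5 mm), expressed in a random rigid rater
  frame (rotation ≤ 45°, translation ≤ 100 mm). The tracked cup pose in
  that rater frame is an observable (the camera measures it); the
  rater-frame transform itself is ground truth and hidden from the
  pipeline.
* **Post-op scene** — the pre-op mesh under a bounded random rigid
  displacement (≤ 10°, ≤ 20 mm) plus per-vertex Gaussian noise (default
  σ = 0.3 mm), and the cup carried by the same displacement plus optional
  manual-overlay noise (default 0; a rotation-vector σ propagates to
  anteversion spread as σ/cos I).

Noise defaults are assumptions, chosen once: 0.5 mm probing noise is a
plausible magnitude for a tracked pointer on bone (tip calibration +
residual cartilage), and 0.3 mm surface noise yields an expected pre/post-op
surface agreement of `0.3·√(2/π) ≈ 0.24 mm`, inside the sub-half-millimetre
band clinical systems report for CT-to-CT pelvis registration. Defaults of
3 raters, 26 points, and batch sizes 15/18 mirror the study design this
package emulates.

What the generator does *not* emulate: real pelvic anatomy (no statistical
shape model, no dysplasia morphology), CT imaging and segmentation error,
tracking-camera noise, instrument calibration error, or soft-tissue
interference with probing. Passing tests therefore demonstrate the
correctness and noise response of the *analysis pipeline*, not the clinical
accuracy of any navigation device.

## Statistics

Sample SD uses the n−1 denominator; absolute-value summaries are
mean/SD of |error|. Exceedance uses strict inequality ("errors over 5°").
Boxplot exports use Tukey conventions (quartiles, 1.5·IQR whiskers
clamped to data). The study runner isolates per-case failures, records
them, and continues; outputs (per-case CSV, summary JSON/CSV, boxplot and
scatter data) are byte-reproducible given the study seed. No inferential
statistics are computed.

## Numerical choices and problem sizes

Rotations are stored as proper orthonormal matrices (validated to 1e-8);
lengths are mm and angles degrees at every API boundary. Kabsch rejects
reflections by sign-flipping the smallest singular vector and refuses
rank-deficient (collinear) correspondence sets. Degenerate (zero-area)
faces are rejected at mesh construction.

The default mesh resolution is icosphere subdivision 3 (642 vertices,
1280 faces), at which the cavity's chordal flattening stays below 2% of
the acetabular radius and a full simulate+assess cycle takes well under a
second, so the Monte-Carlo suites (300 cases per noise level for parameter
recovery, 100 seeds for the multi-start comparison) run in minutes on one
CPU. Resolution, point counts, noise levels and start counts are all
config fields, not constants.

## Known limitations

* The parametric pelvis is deliberately stylized; region definitions are
  tied to its canonical geometry and do not transfer to arbitrary meshes.
* Multi-start ICP is a heuristic global search: on pathologically
  clustered point sets it can still converge to a wrong basin (the
  adversarial test quantifies this rather than excluding it).
* The near-degenerate inertia spectrum of the hemipelvis makes principal-
  axes initialization fragile; the four-candidate refinement handles the
  synthetic scenes, but real, partially segmented bones may need a
  landmark-based initial guess instead.
* Manual template-overlay error in the post-op examination is modelled as
  a configurable Gaussian pose perturbation with default 0, because no
  published magnitude exists for it.
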
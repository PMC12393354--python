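# Methods

## The question and the design

The package compares local deterministic and local probabilistic
streamline tractography by the shape similarity of the bundles they
reconstruct. Real diffusion MRI is replaced by a synthetic substrate in
which the ground truth is known exactly: a single arcuate-like bundle,
modelled as a circular arc thickened into a tube, rasterized into a voxel
grid that stores one fiber axis and one FA-like scalar per voxel. Because
the generative model is explicit, every downstream quantity — coverage,
bundle adjacency (BA), paired statistics — can be validated against
analytic geometry or brute-force recomputation.

Each synthetic *cohort* draws subjects by jittering the base geometry
(arc radius, arc center, tube thickness) with seeded Gaussian
perturbations and by giving every subject an independent realization of
voxelwise angular noise. A noise-free *model bundle* laid deterministically
along the base arc serves the role of a standard-space atlas bundle: it is
the reference for bundle segmentation, the target of registration, and the
comparator for atlas BA.

## Phantom model

- **Geometry.** The arc lies in the x-y grid plane (analytic tangents make
  tracking testable); the tube is the set of voxels within `tube_radius`
  of the finite arc, with spherical caps at its ends. In-tube voxels get
  `fa_inside` (0.8) and the unit tangent of the nearest arc point; all
  other voxels get `fa_outside` (0.05) and a fixed constant axis that
  tracking can never follow because the FA there is below the stopping
  threshold.
- **Angular noise.** Each in-tube axis is rotated by an angle drawn from
  `N(0, angular_noise_sd)` about a random perpendicular axis, seeded per
  subject. Axes are stored sign-canonically (nonnegative x, ties broken by
  y then z) since a fiber axis has no intrinsic orientation.
- **Units.** All lengths are world millimetres; the voxel-to-world affine
  is `diag(voxel_size)` with RAS convention, voxel centers at integer
  indices.

## Tracking

Both modes run fixed-step (0.5 mm) Euler integration through the
trilinearly interpolated axis field, bidirectionally from every seed,
seeded 8 times per voxel with FA > 0.15 and stopped when the interpolated
FA falls below 0.15 — the standard local-tracking protocol. Axis
interpolation sign-aligns the 8 neighbouring axes against the previous
step direction before blending (antipodally symmetric fields cancel under
naive averaging). Deterministic propagation follows the blended axis and
terminates when the turning angle exceeds `max_angle` (30°, the common
default; the protocol itself does not pin it down). Probabilistic
propagation draws from a von Mises–Fisher distribution with concentration
`kappa` about the same axis and redraws (up to 20 times) when the turning
angle exceeds `max_angle`; `kappa` is the knob that controls the
deterministic/probabilistic contrast, with the deterministic tracker as
its `kappa to infinity` limit (verified to < 0.1 mm on ≤ 20 mm paths; over
longer paths the ~kappa^-1/2 per-step angular noise accumulates as a
random walk and the bound is no longer meaningful). Streamlines shorter
than 10 mm are discarded; 250 mm caps runaway trajectories. Seed placement
is uniform within each voxel, drawn from a seed-sequence stream that is
independent of the tracking mode, so the deterministic and probabilistic
runs of a subject consume exactly the same seed set.

The whole-volume tracker propagates all seeds in lockstep with vectorized
interpolation; the per-seed `propagate` runs the identical code path on a
single seed.

## Why voxel size equals step size in the reference conditions

The study conditions prescribe strong voxelwise angular noise (25° SD).
Trilinear interpolation averages 8 neighbouring axes, so on a grid much
coarser than the step the tracker only ever experiences a smoothed
fraction of that noise (≈ 13°/step at 1 mm voxels) and deterministic
tracking is never challenged. The reference phantom therefore uses 0.5 mm
voxels — equal to the step — so the noise field decorrelates at the step
scale and its nominal magnitude is what the propagator actually sees.
This is the regime in which the two algorithms genuinely diverge:
deterministic tracking terminates at sharp noise-induced turns, while
probabilistic redrawing tracks through them.

## Bundle extraction, registration, and the similarity analysis

- **Extraction** keeps every tractogram streamline whose minimum MDF to
  any model streamline is ≤ `theta_extract` (12 mm in the reference
  conditions). The threshold is deliberately permissive: truncated
  streamlines are part of the phenomenon under study, and a strict
  full-length match criterion would silently remove exactly the
  deterministic truncations being measured. The same threshold is applied
  to both methods' tractograms.
- **Registration** places each extracted bundle in model space with a
  simplified streamline-based linear registration: Powell minimization of
  the symmetric mean-min-MDF cost over a rigid/similarity/affine
  parameterization, centroid-initialized. This mirrors the atlas-space
  workflow of bundle analytics pipelines and removes the mode-independent
  geometric jitter (center jitter is a translation, radius jitter close to
  a scaling), so that the shape comparison isolates what the tracking
  algorithm did. The full progressive, cluster-based registration of the
  literature is intentionally not reimplemented — registration is
  instrumental here, and the returned transform is guaranteed no worse
  than identity.
- **BA analysis** runs on seeded 30-streamline subsamples per bundle in
  the reference conditions. Whether published shape-similarity networks
  use full bundles or cluster representatives is not specified in the
  source protocols, so the representation is a parameter; a sparse
  representation keeps the strict 5 mm adjacency criterion in its
  sensitive regime, whereas dense many-thousand-streamline bundles
  saturate coverage (every streamline finds *some* neighbour) and the
  metric stops discriminating. Exact, non-subsampled computation is the
  library default and is what the oracle-equivalence tests check.

## Statistics

Per-subject score = mean of the subject's similarity-matrix row excluding
the diagonal (the only definition compatible with subject-level pairing
and n−1 degrees of freedom). Cohort summaries use the sample SD. The
paired comparison reports the paired t-test, the Wilcoxon signed-rank test
(zeros dropped, midranks for ties; exact two-sided p by the
dynamic-programming equivalent of full 2^n sign enumeration for n ≤ 25,
tie-corrected normal approximation above), and the paired Cohen's d
standardized by the SD of the differences — the standardization under
which |t| = |d|·√n holds identically, which is also how the published
effect sizes relate to their printed t values.

## Reproducibility and numerical conventions

- Identical (spec, seed) inputs give bit-identical phantoms, cohorts and
  tractograms; a full pipeline run writes byte-identical CSV/JSON when
  repeated with the same master seed (no timestamps or host data are ever
  written).
- Child seeds are `master_seed * 10^6 + subject_index`; seed-point and
  direction-sampling streams are split from one seed sequence.
- Empty bundles (a possible outcome of extraction on a heavily truncated
  tractogram) score BA 0 with a warning rather than aborting a cohort run;
  degenerate paired tests (zero-variance differences, e.g. a jitter-free
  cohort) are reported as degenerate rather than raising mid-pipeline.
- The similarity-matrix diagonal is set to 1 by definition; each unordered
  pair is computed once and mirrored.
- TRK stores voxmm with the grid affine in its header, TCK world RAS mm;
  both round-trip through float32 at ≲ 1e-5 mm on phantom-scale
  coordinates.

## Problem sizes

The reference experiment uses a 64×42×16 grid of 0.5 mm voxels (arc radius
9 mm, tube radius 1 mm, ≈ 550 seed voxels, ≈ 4,400 seeds per subject and
mode), 10 subjects, and 30-streamline BA subsamples; one experiment takes
≈ 30 s on one CPU and the 10-replicate directional battery ≈ 6 minutes.
These sizes were chosen so the full analysis, its replication, and the
test suite all run comfortably on a laptop-class machine.

## Known limitations

- One bundle per volume; no crossing fibers, no multi-peak orientation
  models, and no diffusion-signal simulation (the axis field is generated
  directly, standing in for a fitted fiber-orientation model).
- The probabilistic sampler spreads about a single axis; it cannot emulate
  the multi-modal uncertainty of orientation distributions in crossing
  regions, which is one mechanism behind method differences on real data.
- Inter-subject variability is a 4-parameter geometric jitter; real
  anatomical variability is far richer, so absolute BA levels here do not
  transfer to clinical cohorts — only the direction and mechanism of the
  deterministic/probabilistic contrast do.
- The FA tube bounds both algorithms equally, so differences in spatial
  *extent* between methods (probabilistic spread into low-coherence
  tissue) are structurally limited in this phantom.
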
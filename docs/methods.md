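# Methods

`mgscaffold` analyses synchrotron micro-CT volumes of degrading
bioresorbable magnesium coronary scaffolds. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not establish.

## The material model: four corrosion phases

A rare-earth magnesium alloy scaffold degrades in vivo from the strut
surface inward: metal converts to a calcium/phosphate/oxide layer, and
localized regions degrade severely, swelling past the original strut
envelope and cracking apart. Volumes are therefore labelled with four
phases: 0 background / soft tissue, 1 metallic Mg, 2 (mildly) degraded
Mg, 3 severely degraded Mg. All morphometry is defined on this label
scheme; the degraded fraction is (V2 + V3) / (V1 + V2 + V3), degraded
material over the scaffold's total solid volume.

## Synthetic phantoms

Because explanted-scaffold scan data are not redistributable, every
stage is validated on parametric phantoms that emulate the device and
its degradation morphology:

- **Geometry.** A crown-and-link lattice on a cylindrical shell:
  sinusoidal rings z(θ) = z_i + A·sin(n_crowns·θ) with amplitude A equal
  to half the ring pitch (the simplest shape that produces highly bent
  crown regions), connected by straight axial links at evenly spaced
  azimuths. Defaults follow the implanted devices: 15 mm length, 95 or
  130 μm wall, 110 or 130 μm strut width, 8 crowns, 12 links,
  (3.07 μm)³ voxels. Axis 0 is the scaffold axis; voxels are isotropic;
  specs whose wall or strut spans fewer than 2 voxels are rejected as
  undersampled.
- **Slight degradation (label 2)** grows surface-inward. A voxel at
  Euclidean depth d below the strut surface converts when
  d ≤ τ·(1 + b·|sin(n_crowns·θ)|)·η(z, θ), where b is `curvature_bias`
  (the ring centreline's axial curvature is ∝ |sin(n_crowns·θ)|, so
  conversion concentrates at crown bends), η is a smooth log-normal
  field on the shell surface (patchy rather than uniform corrosion),
  and τ is solved by bisection so the converted fraction of the
  original metal matches `slight_degradation_fraction` (default 0.35,
  inside the 30–50 vol.-% range typical after four weeks in vivo).
  Because the threshold varies only along the shell, not radially, the
  converted set is a surface layer by construction: flood-filling from
  the background through non-metal voxels reaches every label-2 voxel
  (tested exactly), and radial rays meet label 2 before label 1 up to
  grid discretization (tested statistically, <5% of crossings).
- **Severe degradation (label 3)**: seeded spherical regions at random
  strut locations (default 2 blobs of 60 μm radius), dilated beyond the
  original strut envelope to mimic swollen degradation products, with
  thin seeded crack planes (removed voxels) inside, default on.
- **Rendering.** Labels map to mean grey values (16-bit; defaults
  12000 / 52000 / 40000 / 28000 for phases 0/1/2/3, metallic
  brightest), blurred by an isotropic Gaussian PSF (default σ = 3 μm)
  plus Gaussian noise (default sd 1200, i.e. ~10% of the inter-phase
  separation). The phase grey levels are free parameters: measured
  values for this alloy/beamline are not published, so the defaults are
  placeholders exposed in the config, chosen to preserve the observed
  contrast ordering.
- Everything is bit-reproducible from (spec, seed).

**Scale.** A full scaffold at acquisition resolution is ≈4900 × 620²
voxels — far beyond what a routine test run should allocate. Tests and
the acceptance script use geometrically similar scaled-down phantoms
(`PhantomSpec.scaled_down`): 8 μm voxels, 0.6–0.8 mm long, ~0.6 mm
diameter segments (~100³ voxels) that keep the true wall thickness and
strut width. All voxel-counting arithmetic is scale-free; the published
scan geometry (800³ patch counts, 2048-pixel field of view) is checked
at its true size on index arithmetic and zero-filled arrays.

## Scan splitting and stitching

Tall samples are imaged as 3–4 vertically overlapping scans (~750 μm
overlap). `split_scans` cuts a volume into blocks sharing
round(overlap/voxel) slices; `stitch_scans` merges them back, blending
the overlap with a linear ramp (seam-free under slight intensity
drift). Blending computes a + w·(b − a), so identical overlap data pass
through bit-exactly and split→stitch is an exact inverse. Optional
refinement maximizes normalized cross-correlation over ±10 slices
around the nominal overlap on a central lateral crop; a best
correlation below 0.5 falls back to the nominal overlap with a warning.
`to_uint16` rescales the [P0.1, P99.9] percentile window (robust to hot
pixels) linearly onto [0, 65535]; it is the identity on full-range data
with clips (0, 100), and order-preserving inside the window.

## Segmentation

A 2D U-Net with three encoding stages of two 3×3 same-padded
convolutions (ReLU), 16 feature maps doubled per stage, 2×2 max-pooling,
a mirrored decoder with 2×2 up-convolutions and skip concatenations,
and a 1×1 output head. The engine is a self-contained NumPy
implementation (im2col convolutions over BLAS, Adam optimizer): small,
dependency-free, and exactly reproducible — two runs from the same seed
produce bit-identical parameters, which GPU frameworks do not
guarantee. Gradients are verified against finite differences per layer
and end-to-end.

- **Orthogonal-plane training.** 2D patches are tiled from every slice
  of the x-y, y-z and x-z plane families (partial tiles flush to the
  edge). A cubic volume of side s at patch size s and zero overlap
  yields exactly 3s pairs — 2400 for 800³, 14,400 for six volumes.
- **Head mode.** The published figure's head reduces to one feature
  map, which cannot express four classes directly. The default
  `multiclass_4` uses a 4-channel softmax with class-weighted
  cross-entropy (inverse frequency, since background dominates);
  `binary_per_class` reproduces the single-channel design as three
  binary networks (one per material phase) fused by highest
  probability, background elsewhere. The analytic parameter count of
  the default architecture is 116,804 (sum of k²·c_in·c_out + c_out
  over all layers); the contract enforced by tests is that the built
  model always matches `count_parameters` exactly, for any spec.
- **Training defaults.** Adam at 1e-3 (optimizer and rate are not
  dictated by the architecture; both exposed), batch 8, per-training-set
  z-score normalization stored in the model, train/validation split by
  whole volume (never by patch, to avoid slice leakage), rare-class
  patch oversampling (`subsample_patches`).
- **Inference.** Every slice of the three plane families is predicted;
  the three class-probability fields are averaged per voxel and the
  argmax taken. Fusion is permutation-invariant. Slices are edge-padded
  to the pooling multiple and cropped back.

With phases rendered at distinct grey levels the task is dominated by
intensity, so segmentation quality on phantoms is an upper bound on
real-data performance: held-out Dice reaches ≥0.99 per class on
noiseless renderings and ≥0.85 (typically ≥0.98) at default noise, and
the degraded volume is recovered within ±10% end-to-end. Real scans add
reconstruction artefacts, intensity drift and tissue texture that the
phantom does not model; passing these tests validates the pipeline's
plumbing and learning machinery, not clinical-grade accuracy.

## Morphometry

- **Volumes** are exact voxel counts × (voxel size)³, reported in mm³.
- **Surface area**: marching cubes at iso-level 0.5 on the binary mask
  of the selected phases (volume padded by one background voxel so the
  outer boundary closes), summing triangle areas. No smoothing — the
  measure is a pure function of the mask. On a voxelized cylinder
  (r = 50 voxels) this overestimates the analytic area by ≈4%, inside
  the 5% band the tests enforce. Meshes export to binary STL or PLY in
  mm units.
- **Scaffold axis**: principal direction of the non-background voxel
  cloud. PCA needs the axial extent to dominate the lateral one; for
  short stubby volumes the stacking-axis hint carried by generated
  volumes is used instead (`full_report` prefers it when present).
- **Strut-region partition.** For each label-2 voxel the escape
  direction is the vector to its nearest background voxel (via exact
  Euclidean distance transform); with r̂ the outward radial direction
  from the axis, a voxel is abluminal if angle(escape, r̂) <
  cone_half_angle, luminal if angle(escape, −r̂) < cone_half_angle,
  lateral otherwise. Default cone half-angle 45° gives the two radial
  classes and the lateral band equal angular budgets (lateral counts
  both side faces). Severely degraded voxels are excluded entirely;
  regional volumes sum exactly to the label-2 volume. The rule is a
  declared operationalization — the original study's exact partition
  procedure is not published — and is validated on constructed shells
  (outer-face degradation ⇒ ≥90% abluminal, inner-face ⇒ ≥90% luminal,
  symmetric thin shell ⇒ ratio within 10% of unity, rotation-invariant
  within 2%).

## Clinical statistics

Late lumen loss LLL = MLD(implantation) − MLD(follow-up) in mm
(negative values are flagged as lumen gain); recoil
R = (mean LD(implantation) − mean LD(follow-up)) / mean LD(implantation)
× 100%. Group comparison: one-way ANOVA followed by Tukey-Kramer post
hoc tests (statsmodels' studentized-range implementation, valid for
unequal n; all-constant input returns the F = 0, p = 1 convention),
significant at p < 0.05. The degradation–inflammation association uses
Spearman rank correlation with midranks for ties, because the
Kornowski inflammation score is ordinal 0–3; Pearson is available via a
flag. Tests pin these against independent implementations
(`scipy.stats.tukey_hsd`, a hand-rolled midrank Pearson) to 1e-6.

## Pipeline and reproducibility

`run_pipeline` chains phantom cohort → split/stitch → 16-bit conversion
→ training → prediction → morphometry → statistics. Per-sample seeds
derive from the global seed and cohort position; re-running a config
reproduces all phantom volumes and predictions bit-exactly. Outputs
(per-sample CSV, statistics JSON, config echo, log with seeds and
library versions) all carry the config hash. The default cohort mirrors
the four-arm study design — thick-strut bare, thin-strut POBA, and two
drug-coated-balloon arms — with per-arm degradation severity and
synthetic angiographic endpoints chosen so the non-drug arms degrade
more and lose more lumen, and an inflammation score that increases with
the sample's rank in severely degraded volume. These synthetic
endpoints demonstrate the statistical layer; they are generated, not
measured.

## Known limitations

- No corrosion kinetics or electrochemistry: degradation is
  morphological/statistical only.
- No projection/reconstruction simulation (phase fringes, ring
  artefacts); tomographic reconstruction and phase retrieval are
  upstream of this package, and the Paganin length travels as metadata
  only.
- The strut-width parameter is applied as an axial half-width on rings,
  slightly widening struts on steep sinusoid segments.
- Marching cubes on binary masks biases surface area high by a few
  percent; comparisons between samples at the same voxel size are
  unaffected.
- Soft-tissue morphometry (neointima, stenosis) is out of scope.
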
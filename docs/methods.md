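# Methods

This note documents the models, conventions and numerical choices behind
`cervimetry`, and what its phantom-based validation does and does not show.

## Anatomy, labels and coordinates

The package operates on 3D multi-label segmentations of the pregnant cervix
as seen on motion-corrected (slice-to-volume reconstructed) T2-weighted MRI
at roughly 0.8 mm isotropic resolution. Five tissue labels are used:

| code | structure | typical T2w appearance |
|------|-----------|------------------------|
| 1 | endocervical canal (ECC) | mixed regional high/low signal (mucus) |
| 2 | inner stroma / subglandular zone (SGZ) | darkest layer |
| 3 | outer stroma (OS) | intermediate signal |
| 4 | fluid-filled cysts | focal hyperintensities, inside the canal |
| 5 | bladder | bright (urine) |

All geometry is carried by the NIfTI voxel-to-world affine in RAS+
millimetres. Landmarks and measurements are computed in world coordinates,
never voxel indices, so they are invariant to grid orientation. Labels are
resampled nearest-neighbour only.

## The cervix phantom

The synthetic-data generator models the cervix as a two-segment tube:

- the canal centreline is exactly two straight segments,
  inlet -> midpoint -> outlet, so the clinical two-line cervical length is
  the true arc length of the canal by construction;
- the canal is the union of two cylinders of radius `canal_radius`
  **mitre-joined** at the hinge (each cylinder clipped by the bisector
  plane through the midpoint). A perpendicular cut at the hinge would leave
  a background notch on the outer bend that creates spurious
  canal-background interfaces; the mitre joint removes it, and makes the
  per-label volumes exactly closed-form (`pi r^2 (L1+L2)` for the canal and
  the matching annuli for the stromal shells, by a point-reflection
  argument) at every bend angle;
- the far ends are flat perpendicular caps open to the background,
  modelling the internal and external os where the canal meets the uterine
  cavity and vagina;
- inner and outer stroma are concentric open-ended shells
  (defaults 2.5 mm and 3.5 mm thick, in the range seen on mid-gestation
  MRI); cysts are spheres radially inside the canal that may reach the open
  ends; an optional bladder sphere sits in the background.

Rasterisation classifies `supersampling^3` (default 27) sub-voxel points
against the continuum geometry and takes the majority label, ties broken by
priority cyst > canal > inner > outer > bladder. Volumes measured by voxel
counting converge to the closed forms as spacing shrinks **for generic
orientations**; for an exactly grid-aligned cylinder the digitised
cross-section error (a Gauss-circle-type quantisation of roughly +/-2% at
0.4-0.8 mm for a 3 mm radius) repeats identically in every slice and does
not average out. The convergence test therefore uses a tilted tube, and
axis-aligned phantoms should be expected to carry an alignment-dependent
volume offset of a few percent that supersampling cannot remove.

The intensity renderer assigns per-label means ordered as on T2w MRI
(inner stroma 0.20 < outer stroma 0.45 < canal 0.60 < cysts 0.95, bladder
0.90, background 0.10 on a [0,1] scale), adds a smooth regional high/low
mixture inside the canal (amplitude 0.15, correlation length 8 mm,
emulating heterogeneous mucus), multiplies by a smooth bias field
(amplitude 0.2, scale 30 mm) and adds i.i.d. Gaussian noise (SD 0.03).
All randomness is seeded.

What the phantom does **not** model: funneling or post-surgical anatomy,
curved (spline) canals, partial-volume intensity mixing at boundaries,
through-plane motion artefacts, and the tissue-contrast differences between
0.55T and 3T acquisitions. Passing phantom tests therefore demonstrates the
correctness of the geometric algorithms and the trainability of the
network under controlled conditions, not clinical performance.

## Biometry

Landmark extraction follows the clinical protocol:

1. **End interfaces.** Canal-or-cyst voxels with at least one face-adjacent
   (6-connectivity) background voxel are grouped into 26-connected
   components; the two largest are the open ends. Face adjacency keeps the
   interface strict, 26-connectivity keeps the grouping permissive for
   staircase surfaces. Grid borders count as background so a canal touching
   the volume edge still terminates.
2. **Inlet vs outlet.** The protocol itself does not distinguish the ends;
   by default the more superior end (larger S coordinate, toward the
   uterine cavity in supine imaging) is the inlet. The rule is overridable
   (`--inlet superior|inferior|nearest-to X,Y,Z`).
3. **Centre-points.** Inlet/outlet centres are arithmetic means of their
   interface-voxel centres; the canal midpoint is the mean world coordinate
   of the canal label (label 1 only — cysts participate in end-interface
   detection but not in the midpoint, reading the protocol literally).
4. **Cervical length** is the two-line polyline length
   |inlet - midpoint| + |midpoint - outlet|.
5. **Diameters.** At each end, the measurement direction is
   d = normalize(n x a), where a is the canal-axis estimate at that end
   (from the end centre toward the midpoint at the inlet, from the midpoint
   outward at the outlet) and n the normal of the best-fit plane through
   the three landmarks (for collinear landmarks the plane is undefined and
   the world left-right axis is used, matching the mid-sagittal
   convention). Rays march along +/-d in 0.1 mm steps with
   nearest-neighbour label sampling and stop at the first *sustained*
   boundary sample — inner stroma (the boundary the protocol defines) or
   background (a genuine exit through an open end) persisting for one voxel
   diagonal along the ray; isolated boundary samples are staircase
   rasterisation noise, not the wall. Two discretisation effects make a
   single chord at the exact centre-point unreliable: the centre-point lies
   on the rasterised open-cap surface, where nearest-neighbour labels
   alternate between canal and beyond-cap background, and the voxelised
   lateral wall deviates from the continuum wall by up to half a voxel
   diagonal with a phase set by the grid orientation. Both are averaged out
   by marching a bundle of five parallel rays, inset 0.5-1.5 voxels into
   the canal along the axis (one staircase period, all within ~1 voxel of
   the centre-point level), and averaging the stop distances per side. No
   label interpolation is involved — only averaging of nearest-neighbour
   chords. This keeps diameters invariant to rigid rotation within one
   voxel, which no single-chord first-crossing rule achieves.

Known systematic behaviour, visible in the validation suite: because the
midpoint is the canal *centroid*, it is pulled toward the inside of the
bend for curved cervices, shortening the two-line length by about
`L(1 - sqrt(0.625 - 0.375 cos(theta)))` for bend angle theta (about 3% of
the length at theta = 135 degrees); and the end centre sits roughly half a
voxel inside the open cap, shortening each line by ~0.4 mm at 0.8 mm
resolution. Both biases are inherent to the measurement definition, not to
its implementation. Integrated over the suite's geometry range (bends down
to 120 degrees) they place the mean absolute length error at about 1.6 mm
— the same order as, and slightly above, the published ~1.56 mm
manual-vs-automated agreement level, which the acceptance suite treats as
its budget; the diameter errors stay far inside their budgets.

## Volumetry

Volumes are voxel counts times `|det A|` of the affine's 3x3 block. The
reported total canal volume merges the cyst label into the canal (cysts are
mucus-filled cavities of the canal); cysts are additionally counted as
26-connected components.

## Agreement metrics

Dice is 2|A∩B|/(|A|+|B|) with the both-empty case defined as 1. Volume
differences are reported absolute (mm^3) and relative (% of the first,
reference, argument). The intraclass correlation coefficient is ICC(2,1) —
two-way random effects, absolute agreement, single measurement — the
standard choice for manual-vs-automated comparisons; it is computed from
the classical mean-squares decomposition and cross-checked against an
independent implementation in the test suite. All-equal data has no
variance to apportion and is reported as 1.0 with a warning.

## Segmentation network

The architecture is the classical 3D UNet: per level two 3x3x3
convolutions, each followed by batch normalisation and ReLU; 2x max-pooling
between encoder levels; nearest-neighbour upsampling plus a 3x3x3
convolution and skip concatenation in the decoder; dropout (ratio 0.5) at
the bottleneck; a 1x1x1 output convolution over 6 classes. Training uses
the equally weighted sum of soft Dice and cross-entropy, AdamW (weight
decay 1e-5, default betas), batch size 1, and a learning rate decaying
linearly to zero at the final iteration. The Dice term averages over the
classes present in the target volume (configurable): with batch size 1 an
absent class has a near-zero soft Dice whose gradient is pure noise, and
including it measurably destabilises the short desk-scale schedule. Augmentation applies, each with
probability 0.5 per iteration: rotation about a random grid axis within
+/-45 degrees, a smooth multiplicative bias field, and gamma contrast in
[0.7, 1.4]; optional piecewise-linear quantile histogram matching to a
reference image is available. Preprocessing resamples to an isotropic
grid^3 box preserving aspect ratio and rescales intensities to [0, 1];
predictions are argmaxed and back-projected nearest-neighbour onto the
input grid. Preprocessing normalises intensities between the 0.5th and
99.5th percentiles (clipped) rather than min-max, so that focal
hyperintensities such as cysts do not rescale every other tissue's
normalised intensity. After the last iteration the batch-norm running
statistics are recomputed over the un-augmented training volumes
(training-time statistics reflect augmented, dropout-active activations
that never occur at inference). Finally, a degenerate run — a class
present in every training label but predicted on none of the training
volumes, a known batch-size-1 failure mode — triggers a single restart
from a shifted initialisation seed.

The network, including the 3D convolution and batch-normalisation forward
and backward passes, is implemented in numpy with numba-compiled kernels;
gradient correctness is verified against finite differences and float64
closed forms in the test suite.

Two configurations matter:

- the **reference recipe**: five encoder-decoder blocks with output
  channels (32, 64, 128, 256, 512), 128^3 grid, initial LR 1e-3, 100,000
  iterations. `UNetConfig` expresses it and its parameter count is what
  the architecture formula predicts, but training it is far outside a
  single-CPU budget;
- the **desk-scale configuration** used by the validation experiments:
  three blocks (4, 8, 16), 64^3 grid, 1000 iterations, initial LR 1e-2,
  dropout 0, 20 training / 5 held-out rendered phantoms. The larger
  initial LR and disabled dropout are the scaled-down counterparts of the
  reference settings: with the linear-decay schedule compressed 100-fold,
  1e-3 never leaves the warm-up regime (verified by ablation — predictions
  remain all-background), and stochastic regularisation designed to
  prevent overfitting over 100k iterations instead degrades the context
  features that separate dark canal mucus from outer stroma. The
  desk-scale run reaches held-out canal Dice > 0.9 in minutes on one CPU.

Training phantoms are generated directly on the 64-voxel grid at 1.0 mm
spacing (so the full cervix plus stromal shells fits the field of view)
with lengths 20-40 mm, radii 2.5-5 mm, bends 120-180 degrees, and cysts in
every third phantom.

## Atlas construction

The groupwise template procedure: resample the first input to the target
spacing (0.8 mm default) as the initial reference; in each of 5 iterations,
register every subject to the current template (rigid, then affine;
optionally a non-rigid B-spline stage, off by default), resample, average
voxelwise, and apply Laplacian sharpening `out = img - alpha * L(img)`
with the 6-neighbour Laplacian, clamped to the input range (alpha = 0.5
default; the amount is exposed because no canonical value exists).
Registration is delegated to SimpleITK's multi-resolution framework with a
normalised cross-correlation metric (shrink factors 4/2/1, regular
sampling at 25% with a fixed seed for determinism). The non-rigid stage is
pluggable because free-form deformation engines are interchangeable here;
the averaging/sharpening logic is the substance of the procedure.

## Normative charts

Trends of each measurement against gestational age (16-40 weeks) are
least-squares polynomials (degree 1 by default, degree 2 optional);
centile bands add the empirical 5th/50th/95th residual quantiles to the
fitted curve, avoiding distributional assumptions at the cost of assuming
residual exchangeability across GA. The synthetic cohort generator draws
GA uniformly, applies a linear trend (default 40 mm intercept, -0.3 mm/week
slope, 1 mm residual SD — the magnitude of gradual cervical shortening
over gestation) and randomly assigns 0.55T/3T field strength.

## Validation experiments and problem sizes

The standard studies (in `cervimetry.experiments`, rerun by
`scripts/acceptance.py` and the test suite):

- **Biometry suite**: 50 random phantoms, lengths 20-45 mm, radii 2-5 mm,
  bends 120-180 degrees, isotropically random orientation, 0.8 mm spacing
  on a 96^3 grid; reports mean absolute errors of length and both
  diameters against the analytic truth.
- **Segmentation experiment**: the desk-scale configuration above;
  reports the mean relative volume difference over the canal and inner
  stroma labels on the 5 held-out phantoms.

Both finish in minutes on one CPU. The equal-halves split of the
centreline, the uniform parameter distributions and the cyst-free biometry
suite are fixed conventions of the studies, chosen once for symmetry and
simplicity.

## Known limitations

- The phantom's sharp label boundaries and strong layer contrast make the
  segmentation task easier than clinical data; the desk-scale result
  bounds implementation correctness, not clinical accuracy.
- The centroid-midpoint length bias grows with bend; strongly re-curved
  (theta < 120 degrees) or S-shaped cervices are outside the validated
  range.
- Inlet/outlet disambiguation by superior coordinate assumes supine
  orientation conventions; use the override for unusual geometries.
- The ICC variant and the trendline model class are fixed conventions
  (ICC(2,1); polynomial + empirical centiles); other choices are defensible
  and would give slightly different numbers.
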
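# Methods

## The index

`desimri` computes the Disproportionately Elevated Sulcal Index (DESI), a
dimensionless biomarker of the DESH morphology in normal pressure
hydrocephalus (enlarged Sylvian fissures together with effaced, "tight"
high-convexity sulci):

    DESI = V_sylvian / V_superior

where `V_sylvian` is the CSF volume labeled left or right Sylvian fissure
and `V_superior` is the suprasylvian sulcal CSF volume restricted to a
three-dimensional dihedral wedge whose apex edge is the AC-PC line and
which opens superiorly with a 30° total aperture (±15° about the vertical;
the aperture is configurable).  Both volumes are voxel counts times the
native voxel volume, computed on coronal planes perpendicular to the AC-PC
axis between the two commissures.  The decision rule is `DESI >= threshold
⇒ positive`, with shipped operating points 6.10 (DESH vs non-DESH
hydrocephalus), 4.83 (DESH vs other diagnostic groups) and 1.92
(hydrocephalus vs all others).

## Coordinate geometry

All physical coordinates are mm in RAS.  Landmarks (AC, PC) are inputs in
the physical space of the NIfTI affine; automatic detection is out of
scope and pluggable upstream.  `acpc_transform` maps AC to the origin and
the AC→PC direction onto −y using the minimal rotation; the roll degree of
freedom, which two landmarks cannot fix, is resolved by that minimal
rotation, which keeps the scanner's left-right axis as close to itself as
possible.  `resample_to_acpc` applies the transform with linear (intensity)
or nearest-neighbour (label) interpolation at preserved spacing.
Voxel membership everywhere is by voxel centre — no partial-volume
weighting — matching the voxel-count × voxel-volume volumetry.

Two conventions the index definition leaves open were fixed as follows:

- the 30° wedge angle is read as the FULL opening (half-angle 15°); a
  reading as half-angle would double the captured sector, and "opening
  angle" most naturally denotes total aperture.  It is a parameter.
- volumetry is restricted to the AC-PC slab (the closed interval of
  coronal planes between the landmarks, endpoints snapped to the nearest
  grid plane and included), since segmentation itself is defined on
  exactly those slices.  A flag widens it to all planes.

## Segmentation model

A 2D multi-label encoder-decoder segments each coronal slice into four
independent sigmoid channels: left Sylvian, right Sylvian, suprasylvian,
plus an auxiliary background channel that is trained like the others and
ignored downstream (the fourth logit exists so the channel count matches
the four-logit output contract; only three labels are anatomical).
Slices are resized to 224×224 (linear for intensities, nearest for masks)
and standardized to zero mean, unit variance.  Thresholding is `p ≥ 0.5`
(ties foreground).  Predicted masks are mapped back to the native grid by
nearest neighbour, stacked into 3D, and filtered for 26-connected
components smaller than 50 mm³ (configurable; thin oblique sulci fragment
under stricter connectivity, hence 26).

The network is implemented directly in numpy (im2col convolutions with
hand-written backward passes, all verified against finite differences, and
an AdamW optimizer with decoupled weight decay 0.02 and β₂ = 0.99 so the
second-moment scale adapts within a desk-scale run): three resolution
levels of (3×3 conv → instance norm → ReLU) blocks, average-pool down,
nearest-neighbour up, skip concatenations and a 1×1 projection head.  Two
presets share this topology: `small-random` (base width 6, ≈17k
parameters, single-conv full-resolution decoder block — the
full-resolution level dominates CPU cost) and `efficientnet-b0-style`
(base width 24, double convs throughout, ≈267k parameters) when compute
allows.  No pretrained weights are required.  Several design points are
essential to make a compact network trainable on this task — each was
added after observing a concrete failure mode:

- instance normalization after every convolution.  Region losses
  constrain only the ordering of probabilities around the threshold, not
  their scale; without normalization the activations grow without bound,
  the logits saturate the sigmoids (observed at magnitude ±500), and any
  channel that is wrong at saturation time freezes with vanishing
  gradients.
- the input carries two normalized coordinate planes besides the
  intensity, and the head additionally sees the raw input planes through
  an identity skip.  Convolutions are translation-equivariant, so a
  shallow network has no absolute-position signal away from the borders
  and cannot decide whether a Sylvian-shaped cleft belongs in the left or
  the right channel; coordinate planes restore that information (a very
  deep encoder would instead get it from its global receptive field).
- random mirror augmentation that flips the left-right axis and swaps the
  paired Sylvian label channels.  The brain is nearly mirror-symmetric across
  the midline; the swap makes both side channels see identical training
  statistics, without which whichever side happens to win the early
  feature race starves the other.
- linear learning-rate warmup over the first epoch.  Adam's earliest
  steps are full-size regardless of gradient scale and can drive every
  channel into the saturated-empty regime before any feature has formed.
- the head bias starts at −1 so every channel begins near-empty.  The
  sulcal labels cover a tiny pixel fraction, and an all-foreground start
  is a slow local trap for the Dice loss.

### Loss

Training minimizes `1.0 · soft-Dice + 0.5 · Hausdorff-surrogate`.  The
weighting is a package default (configurable); equal weighting lets the
boundary term dominate early training, while a pure Dice loss converges to
blurrier borders — 1:0.5 was a stable middle ground.  The soft Dice term is
`1 − mean_c (2Σpt+ε)/(Σp+Σt+ε)` with ε = 1.  The Hausdorff surrogate is the
distance-transform form: the squared probability error weighted by the
squared unsigned boundary-distance transforms of the truth and of the
thresholded prediction, distances normalized by the image diagonal so the
weights are O(1); the distance maps are treated as constants when
differentiating (the standard approximation — the exact symmetric
Hausdorff distance, used only for evaluation, is not differentiable).
When one mask is empty and the other is not, the empty side's distance
map is the full diagonal everywhere — the Hausdorff distance to an empty
set is unbounded — which also gives an entirely-missed structure a strong
restoring gradient.

### Augmentation and split

On-the-fly per-sample augmentation: random rotation ±15°, random zoom-crop
to 80–100% of the field of view, and random left-right mirroring with the
paired Sylvian channels swapped (all shared by image and mask; nearest
neighbour for masks), plus image-only Gaussian blur (σ ≤ 1.2 px), additive
noise (σ ≤ 0.1 on standardized intensities) and coarse dropout (≤4 holes,
≤12% of the side length).  Train/validation splits are at the subject
level, 80/20, and overlap is rejected.  Training runs up to 100 epochs
with early stopping (patience 5 on validation loss) and returns the
best-validation weights.  All randomness flows from explicit seeds;
seeded runs reproduce bit-identical histories on a fixed machine.

## Synthetic phantoms

The phantom generator provides the validation substrate: heads with
*analytically known* compartment volumes, so the whole geometry pipeline
can be checked against closed forms — something no real cohort offers.

Geometry (defaults in parentheses): an ellipsoidal brain (semi-axes
65×80×60 mm) with landmarks at fixed fractional positions giving a 25 mm
AC-PC slab; per hemisphere one Sylvian cleft, a tilted rectangular slab
(8×20 mm cross-section, tilt ±8°, mirrored); high-convexity sulci as
radial planar slits about the AC-PC axis near the vertex (4 slits of
width 3 mm spanning radii 38–62 mm at angles ±4.5°, ±11°), all strictly
inside the 30° wedge; plus two lateral distractor slits at ±24°, strictly
outside the wedge, so the wedge restriction is exercised and the
wedge-restricted superior volume equals the summed inner-slit volume
exactly.  Every compartment is a (tilted) box, so every volume is a closed
form.  Compartment intervals are half-open and the slab endpoints sit off
the voxel centres at the default 1 mm spacing, which removes the
double-counted boundary plane that closed intervals would produce; the
tilts make voxelization errors average along the structure instead of
accumulating.  Voxelized volumes agree with the closed forms to well
within 5% at 1 mm and converge as spacing shrinks.

The severity dial `s ∈ [0, 1]` scales Sylvian cross-section dimensions by
`(1+s)` and slit widths by `(1−s/2)`, so ground truth DESI,

    DESI(s) = k · (1+s)² / (1 − s/2),    k ≈ 1.11 at the defaults,

is strictly increasing — from ≈1.1 (s=0) through ≈3.3 (s=0.5) to ≈8.9
(s=1), a span that brackets all three published operating points.

Intensity is a contrast model, not MRI physics: parenchyma 100, CSF 30,
background 5 (arbitrary units), Gaussian noise (σ=4), optional smooth
multiplicative bias field (coarse random grid, cubic-spline upsampled,
amplitude a fraction of unity).  Ventricles (CSF-intensity ellipsoids,
unlabeled) act as distractors.  What the phantom does *not* emulate —
folded cortical geometry, partial-volume fractions, scanner-specific
contrast and artefacts, anatomical variability — bounds what passing
tests show: they validate the geometry, volumetry, index and
classification machinery, and that the segmenter can learn this task
family, not clinical-grade segmentation accuracy on real scans.

## Evaluation metrics

3D Dice `2|A∩B|/(|A|+|B|)` (two empty masks agree: 1.0, logged choice);
exact symmetric Hausdorff distance between surface-voxel centres in mm
(a percentile variant is available by flag, the default is the exact
maximum); Euclidean landmark error in mm; rank-based ROC AUC (equals the
trapezoidal area and the pairwise probability with half-credit ties);
confusion metrics computed exactly from counts and rounded only at
display.  "Best" thresholds maximize Youden's J over midpoints of adjacent
sorted unique scores, ties toward the smallest — the selection criterion
behind published operating points is not otherwise pinned down, and
Youden's J is the standard, reproducible choice.  An undefined DESI (zero
superior sulcal volume) is flagged rather than returned as infinity and
classifies positive with a warning: vanishing high-convexity CSF is the
extreme of the pathology, not a missing value.

## Numerical and design notes

- Bias-field correction delegates to the N4 algorithm (SimpleITK) behind a
  corrective contract: within uniform tissue the coefficient of variation
  must not increase.  N4 is cited preprocessing, not a contribution worth
  re-deriving.
- RAS reorientation is pure axis permutation/flips and refuses oblique
  volumes (beyond 1e-3 in the direction cosines) rather than silently
  resampling.
- Constant slices z-score to all zeros with a warning, so blank edge
  planes do not abort a run.
- `resize_to_model` records native shape and scale factors; the mask
  round-trip native→224→native is identity for upsampled grids and
  conserves area within a few percent otherwise.
- Desk-scale study sizes (chosen once as the package's validation
  conditions): learnability runs train the small preset on 200 slices from
  100 phantoms (2 per subject, severities uniform in [0,1]), 80/20 subject
  split, up to 20 epochs with early stopping; severity-grid recovery uses
  5 phantoms at 1 mm spacing; cohort separation uses 20 phantoms at
  severities 0.1 vs 0.9 in oracle-mask mode; rotation robustness uses ±10°
  pitch.

## Known limitations

- The numpy network trains on CPU at desk scale only; the wide preset is
  provided for completeness but is slow to train without vectorized
  hardware.
- Oblique acquisitions must be rigidly resampled upstream.
- The phantom's analytic guarantee rests on box-shaped compartments; it
  cannot probe errors specific to curved, branching sulci.
- Landmark coordinates are trusted as given; landmark error metrics are
  provided for evaluating an upstream detector, not for self-diagnosis.
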
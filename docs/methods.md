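# Methods

`cmbkit` implements a fully automated three-step method for detecting
cerebral microbleeds (CMBs) on single-modality susceptibility-based MR
volumes (T2*-GRE, SWI or QSM), together with the synthetic phantoms, training
loops and lesion-level evaluation needed to exercise it end to end on a
desktop CPU. This note records the model, its assumptions, the parameters
that matter, and the design choices made where the published description left
the design open.

## Problem and pipeline

CMBs are small (2–10 mm), roughly spherical haemosiderin deposits —
hypointense on T2*-GRE/SWI, hyperintense on QSM. Automated detection is hard
because of their size, sparsity, and the abundance of *mimics*: vessels and
sulci (elongated), calcifications, and boundary artefacts. The pipeline
attacks this in three stages:

1. **Candidate detection.** After intensity normalisation (division by the
   within-brain maximum) and, for T2*-GRE/SWI, inversion (so CMBs are
   bright), elongated bright structures are removed (see *Vessel removal*)
   and the 3D fast radial symmetry transform (FRST) is computed at radii
   {2, 3, 4, 6} voxels and averaged. A shallow 3D encoder–decoder (a U-Net
   trimmed to two pooling levels) consumes the image and FRST map as two
   channels and produces a voxel-wise CMB probability map `P_Cdet`. It is
   trained on non-overlapping 48³ patches with weighted cross-entropy (CMB
   voxels upweighted 10×) plus soft Dice loss, and applied fully
   convolutionally to whole volumes at test time. `P_Cdet` is thresholded at
   `Th_Cdet` (default 0.3) and 26-connected components become candidates.
   This stage aims at maximum sensitivity; its false positives are handled
   downstream.

2. **Candidate discrimination by knowledge distillation.** A multi-tasking
   *teacher* shares a convolutional feature extractor `T_f` between a
   voxel-wise segmentor arm `T_s` (architecturally identical to the detector
   and initialised from its weights) and a patch-level classifier arm `T_c`
   (1×1×1 projection, two 3×3×3 convolutions + pooling, then FC layers of
   1024/128/32 units with 20% dropout before the middle FC and a 2-class
   softmax). It is trained on adjacent 24³ tiles, labelled CMB iff they
   contain a ground-truth CMB voxel. A lightweight *student* (feature
   extractor + classifier only, half the channel counts) is then trained on
   24³ patches centred at detected candidates with

   `L = α·CE(y_S, σ(z_S, τ=1)) + β·KL(σ(z_S, τ) ‖ σ(z_Tc, τ))`,

   τ = 4, α = 0.4, β = 0.6 by default. The softened teacher distribution is
   recomputed on exactly the student's inputs (offline, response-based
   distillation); the student's softened distribution is the first KL
   argument, and no τ² rescaling is applied to the distillation term. At
   test time each candidate keeps its full voxel set iff the student's CMB
   probability reaches `Th_Cdisc` (default 0.3).

3. **Morphological clean-up.** Surviving candidates are filtered by three
   anatomical/shape rules: volume ≥ 2.5 mm³ (stray specks), ellipticity
   ≤ 0.2 (tubular fragments), and centroid distance to the brain-mask
   boundary ≥ 5 mm (sulcal mimics). Rejections are attributed to the first
   triggering rule in the order skull → volume → shape and recorded in a
   ledger. Clusters are mapped back to the original grid *before* the
   distance transform so FOV cropping cannot truncate boundary distances.

Evaluation is lesion-level over 26-connected clusters: a ground-truth
cluster counts as detected iff any predicted cluster overlaps it by at least
one voxel; a predicted cluster overlapping no ground truth is a false
positive. Reported metrics are cluster-wise TPR, FPavg (false positives per
subject) and cluster-wise precision, plus FROC curves with a knee-point
operating threshold (maximal perpendicular distance from the chord joining
the curve endpoints, FPavg normalised to [0, 1]; ties resolved toward higher
TPR). Note that only TPR is guaranteed monotone in the threshold — a
shrinking predicted cluster can lose its overlap and become a *new* false
positive, so FPavg may locally increase.

## Vessel removal

Vessels and sulci are the dominant mimic source. Per-voxel features —
Frangi vesselness at scales 0.5/1.0/1.5 mm (bright-ridge polarity, since
vessels are bright after inversion) and structure-tensor shape measures
(linearity `(λ1−λ2)/λ1` and planarity `(λ2−λ3)/λ1` of the smoothed gradient
outer product, gradients taken in mm; σ_grad = 1 voxel, σ_tensor = 1.5
voxels) — are clustered with K-means (k = 2, 10 restarts, fixed seed). The
cluster with the highest mean vesselness is the structure class; only its
*linear* 26-connected components (principal-axis ratio ≥ 3, ≥ 3 voxels) are
retained as vessels, so round candidates near vessels are returned to the
image rather than destroyed. Features are clustered on their raw values
(they share a common [0, 1]-ish scale); standardising them lets the noisy
shape measures dominate and collapses the vessel class to the few brightest
core voxels. Masked voxels are inpainted with the mean of their unmasked
26-neighbours, onion-peeling inward for thick masks until a fixed point;
unmasked voxels are never modified. The Frangi filter itself is isotropic;
its mm scales are converted to voxel sigmas with the mean spacing.

## FRST details

The transform is the 3D generalisation of the gradient-vote radial symmetry
operator. For every voxel whose gradient magnitude exceeds 5% of the image
maximum, the voxel at `p + round(n·ĝ(p))` receives an orientation vote and a
magnitude vote (bright-centre votes only; dark symmetry is irrelevant after
inversion). With `κ_n = max(O_n)`, the radius-n map is
`S_n = G_{0.5n} * [clip(O_n/κ_n, 0, 1)^α · M_n/κ_n]`, α = 2. The mean over
radii is min-max normalised to [0, 1] within the brain mask. Radii are in
voxels and votes are cast on the raw voxel lattice (anisotropy is ignored
here by design — the radii are specified in voxels).

One property worth stating explicitly: the *argmax* of `S_n` localises a
ball's centre for every radius in {2, 3, 4, 6}, but the peak *values* are
not comparable across radii — at the matched radius all votes land in one or
two voxels and the `0.5n` Gaussian dilutes that spike more than it dilutes
the spread-out votes of mismatched radii. Only localisation (and the mean
map) is relied on downstream, and only localisation is asserted in tests.

## Training recipe and its desk-scale adaptation

Paper-scale defaults (the library defaults): Adam with ε = 1e-4, batch 8,
initial learning rate 1e-3 reduced ×0.1 every 2 epochs until 1e-6, at most
100 epochs with early stopping at patience 20 (best-validation weights are
restored), truncated-normal weight init with σ = 0.05, biases 0.1.
Augmentation avoids rotation/scaling (they can destroy tiny lesions):
random combinations of in-plane integer translation (x/y offsets in
[−15, 15] voxels, segmentation labels moved identically, with redraws so a
CMB patch never loses all CMB voxels), Gaussian noise injection
(σ² ∈ [0.01, 0.04]) and mild Gaussian smoothing (σ ∈ [0.1, 0.2] voxels);
dataset expansion ×10 for detection, ×5 for discrimination.

These defaults presuppose epochs of thousands of updates and wide layers.
The desk-scale configuration (`PipelineConfig.phantom_scale()`), used for the
synthetic end-to-end study, re-scales the coupled quantities while keeping
the recipe's shape:

* **Widths:** detector base width 4 → here 2 at desk scale (paper: 64);
  teacher classifier width 8, FC sizes (64, 32, 16); student at half those.
* **Initialisation:** σ = 0.05 is calibrated to wide layers (for FC-1024 the
  layer gain is √1024·0.05 ≈ 1.6). At reduced widths it collapses signal
  propagation and, combined with Adam's ε floor, freezes learning entirely;
  reduced-width networks therefore use He-scaled truncated normal
  (σ = √(2/fan-in)).
* **Learning rate / decay / batch:** Adam's per-step movement is bounded by
  ~lr, so the update budget, not the data, limits convergence at this scale.
  The scaled schedule uses lr 1e-2 with a short warmup (first epochs at
  lr/10, which suppresses a rare dead-ReLU collapse into the all-background
  attractor), batch 4, decay ×0.1 every 12 post-warmup epochs, and at most
  24/3/5 epochs for detector/teacher/student — roughly 150–350 updates per
  model, which is where validation loss plateaus on phantoms.  As a final
  guard, a detector whose validation probability map never reaches
  `Th_Cdet` (the unmistakable signature of the collapsed attractor, not a
  tunable quality bar) is retrained once from a shifted init seed.
* **Augmentation expansion:** ×5 detection, ×2 discrimination.
* **FOV margin:** crop margin 1 voxel, so the default phantom brain fits a
  single 48³ detection tile.

All of these live in the config and none of them changes the model, the
losses, or the thresholds (`Th_Cdet = Th_Cdisc = 0.3`, τ = 4, α = 0.4,
β = 0.6, and the three filter rules keep their published values everywhere).

## Synthetic phantoms

The generator emulates the *statistical* structure the method relies on, not
MR physics: an ellipsoidal brain mask (≈44×40×40 mm in the default 64³,
1 mm-isotropic grid) with smooth low-frequency tissue variation; 3–8
quasi-spherical CMBs per subject, diameters uniform in 2–10 mm, multiplied
in (SWI/T2*-GRE) or added (QSM) with contrast 0.5–0.9 and sigmoid edges;
1–2 random-walk tubular vessels of radius 0.5–1.2 mm with the same polarity
as CMBs; small blob mimics within 4 mm of the mask boundary; and additive
Gaussian noise (σ = 0.05 of the tissue scale). CMB centres are kept at
least one diameter apart (and never touching) and at depth ≥ radius + 6 mm,
matching the anatomical assumption behind the 5 mm skull-distance rule, and
≥3 mm away from vessel tubes. Everything derives from one seed;
`generate_subjects` spawns per-subject seeds from it.

What the phantoms do *not* contain: susceptibility physics (blooming, phase
artefacts), realistic anatomy (no ventricles, no cortex folding),
calcification-like diamagnetic mimics, intensity non-uniformity beyond the
smooth low-frequency field, and scanner/protocol variability. Passing the
end-to-end phantom study therefore demonstrates that the pipeline's
machinery — preprocessing, radial-symmetry candidate detection, distilled
discrimination, anatomical filtering, lesion-level scoring — is implemented
coherently and can be trained to recover known lesions among tubular and
boundary mimics; it says nothing quantitative about clinical performance.

## The CNN engine

PyTorch-class frameworks are deliberately not a dependency: the networks are
small and the patches modest, so the package ships a compact numpy/numba
backprop engine (`cmbkit.nn`) with exactly the layers the architectures
need. The 3×3×3 convolutions run as JIT-compiled direct convolutions in
channels-first order (narrow channel counts make GEMM-based im2col
memory-bound on CPU); all gradients are verified against central-difference
numerics in the test suite. Decoder upsampling is separable trilinear ×2
interpolation (exact adjoint backward) followed by a 3×3×3 convolution;
nearest-neighbour repetition was measurably worse — its 2-voxel staircase
artefacts skew the second-moment shape descriptor of thresholded candidate
clusters. Activations are leaky rectifiers (negative slope 0.01): with hard
rectifiers the sparse-foreground segmentation loss has an all-background
attractor in which the entire network goes silent.

## Numerical and degenerate-input choices

* Probabilities are clipped at 1e-12 before logs; the soft Dice term uses
  smoothing ε = 1.
* A constant image inside the brain mask is a hard error (normalisation is
  undefined), as are empty masks, k-means with k < 2, a removal mask
  covering the whole brain, and FRST radii that do not fit in the image.
* A constant image yields an identically zero FRST map (no gradients → no
  votes), and a mean FRST map with zero dynamic range is returned as zeros.
* Ellipticity is `1 − sqrt(λ_min/λ_max)` of the cluster's second-moment
  matrix in mm, with each voxel contributing its own box variance
  (spacing²/12) so single-slice clusters on anisotropic grids are not
  degenerate; clusters of fewer than 3 voxels score 0. A sphere scores ≈0,
  a 1×1×9 rod ≈0.89.
* Skull distance is evaluated at the rounded cluster centroid (stable for
  small clusters) on the anisotropy-aware Euclidean distance transform of
  the brain mask.
* NaN/Inf voxels are sanitised to 0 at load time and recorded in
  provenance; if they fall inside a provided brain mask, loading fails
  instead.
* Evaluation maps results back to the original grid before scoring, so crop
  offsets cancel out of all reported coordinates.
* Ties in the FROC knee point go to the higher-TPR threshold.

## Desk-scale performance characteristics

On held-out default phantoms the trained pipeline detects the large majority
of lesions with essentially no false positives (the skull-distance rule
removes the boundary mimics, the shape/volume rules and the discrimination
stage the rest; cluster-wise precision is typically 1.0). The residual
misses are structural rather than tunable, and worth knowing about:

* lesions at the small/faint corner of the generator's ranges (2 mm
  diameter, ~7 voxels at 1 mm spacing, contrast near 0.5) sit below the
  smallest FRST radius (their radius is 1 voxel against the radii
  {2, 3, 4, 6}) and are frequently missed by the candidate stage;
* *confluent* lesion pairs — surfaces within ~2 mm, so their soft intensity
  profiles overlap — threshold into a single merged candidate whose
  ellipticity exceeds 0.2, which the published shape rule then rejects,
  costing both lesions: this is the method behaving as specified on such
  data, not an implementation artefact;
* at the reduced widths used here, predicted masks of small lesions can be
  wobbly enough to brush the ellipticity gate (0.2–0.35).

These effects cap the held-out cluster-wise TPR around 0.65–0.75 at desk
scale while FPavg stays at ~0; the acceptance script reports the exact
numbers it computes for its seed.

## Known limitations

* The engine is single-threaded CPU code; paper-scale widths (base 64,
  FC-1024) are supported but slow — they are meant for correctness
  reference, not routine training.
* The Frangi step uses a single isotropic sigma per scale; strongly
  anisotropic grids (e.g. 0.8×0.8×3 mm) blur the scale correspondence.
* K-means vessel masking is unsupervised; on images with no elongated
  structure the "vessel" cluster is still produced, and only the elongation
  gate keeps the mask near-empty.
* The candidate stage can merge adjacent lesions into one component; the
  GT-side counting rule keeps evaluation coherent, but per-lesion volumes of
  merged detections are not separated.
* MARS-style anatomical rating, registration, skull-stripping and
  bias-field correction are out of scope; the pipeline consumes an already
  brain-extracted volume plus mask.
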
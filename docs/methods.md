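# Methods

## Synthetic torso phantoms

A phantom is a pseudo-3D stack of transaxial slices that share their in-plane
anatomy and differ only in noise, so 3D structures (nodules) are well defined
while every algorithm can operate slice-wise. Geometry is built from
primitives: an elliptical body (default semi-axes 88 × 66 mm; 76 × 58 mm in
the 64×64 desk preset) with a subcutaneous fat rim, two lateral arm ellipses
separated from the trunk by a small gap (the targets of truncation), two
elliptical lungs, a spine disk with a marrow core, four rib disks on a ring,
and a liver-like soft-tissue region. Per-subject anatomical variability is a
seeded ±6% jitter of the body/lung/arm axes and a small lung shift.

Tissue contrast (mean ± SD):

| class  | CT (HU)      | MR (a.u.)     | activity |
|--------|--------------|---------------|----------|
| air    | −1000        | 0.02 ± 0.01   | 0        |
| lung   | −700 ± 25    | 0.15 ± 0.02   | 0.3      |
| fat    | −100 ± 15    | 0.90 ± 0.03   | 0.7      |
| soft   | 40 ± 15      | 0.60 ± 0.03   | 1.0      |
| bone   | 700 ± 50     | 0.08 ± 0.02   | 0.8      |
| marrow | 250 ± 30     | 0.75 ± 0.03   | 0.8      |
| lesion | 40 ± 15      | 0.60 ± 0.03   | 4.0      |

The MR emulates in-phase Dixon contrast: fat bright, soft tissue
intermediate, lung/bone/air dark — precisely the ambiguity that makes
MRI-based attenuation correction hard. The lung CT mean is deliberately
denser than the vendor assumption of −770 HU: real lung density is patient
specific, and that gap is what turns a fixed lung coefficient into a bias
source. Activity contrast only matters up to a common scale (relative bias
is scale invariant). Lesion MR contrast is a configuration knob defaulting
to soft-tissue-like, since small malignant nodules are discernible but not
strongly contrasted on in-phase images.

The MR is corrupted by a multiplicative bias field — the exponential of a
seeded random second-order polynomial in the in-plane coordinates, scaled to
a 20% peak deviation — plus additive per-class Gaussian noise. CT noise is
additive per-class Gaussian.

Corruptions (each a pure function of phantom + parameters, touching only its
stated support, recorded in `outliers_applied`):

- **Truncation**: MR set to air level outside a laterally reduced FOV
  (default 15% of the width per side, clipping the arms and the body rim);
  CT/labels/activity untouched — the anatomy is still there, only the MR
  acquisition lost it.
- **Metal**: MR void disk (default radius 28 mm at the shoulder, deliberately
  spanning the body boundary like a shoulder prosthesis) plus a 3000 HU
  implant core (radius 9 mm) in the CT; activity unchanged. CT streak
  artifacts are not simulated.
- **Single lung**: one lung relabeled soft tissue in all channels
  (post-pneumonectomy), the removed region retained as an evaluation mask.
- **Lung nodule**: a soft-tissue sphere placed entirely inside a lung with
  elevated activity (default 4× soft tissue); the default scenario radius of
  7 mm gives a VOI volume of ≈1.4 mL, inside the 0.5–1.9 mL band typical of
  small malignant lesions.

What the generator does *not* emulate: Dixon water/fat channel physics,
respiratory motion, CT beam hardening, MR resolution anisotropy, continuous
tissue heterogeneity, and realistic organ shapes. Passing tests therefore
demonstrate the *mechanisms* (how μ-map errors propagate to SUV bias, and
which sCT family is robust to which corruption), not clinical-scale error
magnitudes.

## Conditioning

N4 bias-field correction (SimpleITK, 2 fitting levels on a 2× shrunk copy,
mask-mean preserved) precedes intensity normalization to [0, 1] with
percentile clipping at (0, 99.5) — the clip guards the scale against implant
or outlier intensities; zero-range images map to all zeros by convention.
Histogram matching to a cohort reference is implemented and contract-tested,
but the experiment pipeline leaves it off by default: the synthetic cohort
shares one simulated intensity calibration, and matching a subject with
outlier anatomy (e.g. a single lung) to a two-lung reference shifts the
piecewise-constant histogram's soft-tissue plateau systematically — an
artifact of the phantom's discrete histogram, not a property of the
harmonization step on continuous clinical data. Percentile normalization
already provides composition-robust scale harmonization. Enable matching
with `ExperimentConfig(match_reference=True)` when feeding data with real
inter-scan intensity variation.

Registration uses SimpleITK with Mattes mutual information (32 bins, 50%
random sampling at a fixed seed): a centered affine stage (multi-resolution
4/2/1, regular-step gradient descent) optionally followed by a B-spline
stage (control-point spacing 32 mm, L-BFGS-B, 2/1 multi-resolution). The
metric trace is recorded on the returned displacement field; a B-spline
stage that fails to improve its metric is retried once with a 0.75× control
point spacing; a registration whose sampled metric becomes unevaluable
(e.g. a slice dominated by signal voids) falls back to the identity field
with a logged warning — the analogue of flagging a failed case for manual
review rather than aborting the cohort. Deformations are pull-back
displacement fields in millimetres on the fixed grid; atlas MR→target
transforms are estimated on mid-slice 2D pairs and applied to every slice
of a stack (the stacks are anatomically slice-invariant by construction),
with MR and CT of a pair sharing one transform.

## Segmentation sCT

Body contour: Otsu threshold, in-plane morphological closing (radius 2
voxels), slice-wise hole filling, largest connected component. Lungs:
voxels below half the median body intensity, interior to the body,
components kept above a size prior (50 mL for a 4 cm stack, scaled by stack
extent) with centroid inside the eroded body; interior holes up to 4 cm²
per slice are filled, so sub-centimetre structures (vessels, small nodules)
are absorbed — the characteristic bulk-classification failure on small
lesions. Class values are fixed: soft 0 HU / 0.096 cm⁻¹, lung −770 HU /
0.022 cm⁻¹, air −1000 HU / 0 cm⁻¹. There is no bone class by construction;
the resulting bone-region underestimation is the documented signature of
this method, not an implementation defect. Provenance records lung volume
and component count and flags atypical configurations (≠ 2 components, or
lung volume above 40% of the body) as likely mis-segmentation or abnormal
anatomy. An image with no detectable body yields an all-air map.

## Multi-atlas sCT

Features per aligned atlas entry: bone mask (CT > 160 HU, the same
threshold the evaluation uses), signed Euclidean distance to the bone
boundary (in-plane, mm; negative inside, zero exactly on boundary voxels),
and a phase congruency map from a log-Gabor bank (4 scales, 6 orientations,
minimum wavelength 3 px, multiplier 2.1, σ/f = 0.55) with Rayleigh noise
thresholding (k = 2) — contrast invariant up to the numerical noise floor.
The target bone map is a voxel-wise majority vote (threshold 0.5) over
aligned atlas bone masks. Weights combine the signed-distance kernel
(σ_d = 5 mm) and the patch-mean absolute phase-congruency difference kernel
(σ_p = 0.2, patch radius 2 voxels), normalized over atlases per voxel; the
kernel product is this package's normative fusion definition. Atlases give
zero weight where their resampled CT lacks coverage; voxels where every
kernel underflows fall back to uniform weights (logged); an empty voted
bone map drops the distance kernel (logged). The fused sCT is the weighted
convex combination of aligned atlas CTs, hence bounded voxel-wise by the
atlas values and invariant to atlas order.

## Deep-learning sCT

A 2D residual dilated CNN implemented in NumPy with explicit
backpropagation: a stem 3×3 convolution, then two-layer pre-activation
residual blocks (BN → ReLU → conv, twice, plus identity), with transition
convolutions between dilation blocks and a linear 3×3 head. The full-scale
preset has 20 convolutional layers — 7 at dilation 1, 7 at dilation 2, 6 at
dilation 4 (receptive field ≈ 91 px) — with 16/32/64 channels and the
batch-32, lr 0.04→0.01 protocol; the desk preset keeps the same 20-layer
topology at 8/16/16 channels, batch 8, lr 3·10⁻³→10⁻³ (linear), which
trains in minutes on one CPU core. Convolutions are channel-last
accumulations of k² shifted GEMMs (low memory traffic); gradients were
verified against central finite differences. Loss is the mean-squared error
on CT normalized as (HU + 1000)/2000 clipped at 1000 HU (implants
saturate); the inverse map is applied at inference. Training is
deterministic given the seed. Kernels are 3×3 in 2D (the slice-wise
configuration makes the third kernel dimension moot). Cross-validation
splits are subject-level, never slice-level. No data augmentation by
default.

## PET simulation

HU→μ uses the standard bilinear model: μ = 0.096·(HU+1000)/1000 below 0 HU
and 0.096 + 7.6·10⁻⁵·HU above (cortical bone at 1000 HU → 0.172 cm⁻¹),
clamped at zero. Projection is 2D parallel beam — 176 angles over 180°
(the nearest multiple of the 8 OSEM subsets), radial bins at the voxel
pitch covering the image diagonal, implemented by bilinear image rotation
with a matched rotate-back adjoint. Attenuation factors exp(−∫μ dl) enter
both the data simulation (with the *true* μ) and the OSEM system model
(with each *candidate* μ), so μ-map errors propagate to reconstructed
uptake exactly as on a scanner. Default 5·10⁵ counts per slice with seeded
Poisson sampling; a noiseless mode exists for deterministic oracles.
OSEM: multiplicative EM updates over angle-interleaved subsets, 4
iterations × 8 subsets, per-subset sensitivity precomputed, non-negativity
preserved, circular-FOV support. No scatter, randoms, time-of-flight or
resolution modelling.

SUV is a phantom surrogate: no injected dose or body weight exists, so all
arms of a subject share the single scale that sets the reference (CT-based)
reconstruction's body mean to 1.0. Relative bias is invariant to this
common scale.

## Evaluation

Voxel bias is computed only where the reference exceeds 0.05 SUV. The
soft-tissue HU window [−400, 160] is closed on both ends and bone is
strictly > 160 HU (the endpoint conventions are documented choices); lungs
come from phantom truth labels, standing in for manual delineation, and
lesion VOIs are the truth nodule masks, flagged when outside the 0.5–1.9 mL
band. Paired t-tests are two-sided with explicit zero-variance
conventions: identical samples → p = 1; an exact non-zero constant shift →
p = 0 (infinite t), both logged. No multiple-testing correction is applied
(per-comparison 0.05). Empty regions produce an explicit empty result,
never a silent zero. Reports are deterministic functions of their inputs.

## Experiment workbench

Seeds derive hierarchically from a master seed into disjoint pools
(training cohort, atlas library, evaluation subjects, Poisson noise), so DL
training subjects never overlap evaluation subjects and the atlas library
excludes the target. The affected region for outlier statistics is the
corruption's truth support: the truncated in-body columns, the void disk ∩
body, the removed-lung region dilated by 2 voxels in-plane (a band catching
spill-over), or the nodule VOI. Default desk problem sizes: 64×64 slices at
3.5 mm, 16 training subjects × 4 slices, 50 training epochs, 4 atlases, 5
evaluation subjects per scenario; the nodule scenario uses 5-slice stacks
(4 mm spacing) so the nodule is a true sphere. A failing subject is
recorded and skipped; the run continues.

## Known limitations

- Magnitudes of the scenario biases depend on phantom contrast and desk
  problem sizes; only their signs and orderings are meaningful.
- The rotation projector's adjoint is matched only to interpolation
  accuracy; OSEM tolerates this but exact gradient-based reconstruction
  methods would not.
- The CNN desk preset is deliberately narrow; its residual HU regression
  error sets the floor of the DL arm's bias.
- 2D slice physics: no inter-slice scatter or axial partial volume.
- The fusion weight kernels (σ_d, σ_p, patch radius) are normative package
  constants, configurable but not tuned per dataset.
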
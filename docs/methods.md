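# Methods

`tmtvnet` automates the computation of total metabolic tumor volume
(TMTV) on baseline FDG-PET/CT of FDG-avid lymphomas (Hodgkin lymphoma,
diffuse large B-cell lymphoma, follicular lymphoma).  This note records
the model, the numerical choices, and what the synthetic validation does
and does not establish.

## The two-step segmentation model

TMTV methodologies disagree mainly at lesion edges: the common clinical
rules are a per-lesion relative threshold (41% of the lesion's SUVmax),
absolute cutoffs (SUV > 2.5, SUV > 4.0) and the Otsu histogram
threshold.  Instead of training a network to reproduce one of these
rules, the pipeline separates *detection* from *thresholding*:

1. **Ground truth (TMTVprob).**  Within each manually delineated region
   of interest, all four threshold operators are applied and their
   binary masks averaged voxel-by-voxel.  The result is a probability
   map with values in {0, 0.25, 0.5, 0.75, 1}: 1 where every
   methodology agrees (lesion cores), intermediate values where they
   disagree (edges).  With several ROIs, per-operator masks are unioned
   across ROIs *before* averaging so overlapping ROIs cannot push a
   probability above 1.
2. **Network.**  A 3D V-NET (4 resolution levels, 8 channels at the
   finest level, channel doubling per level, residual stages, skip
   connections, single sigmoid output channel) maps the 0–1-scaled
   CT+PET channels to a voxel-wise tumor probability.  It is trained
   with the soft dice loss `1 − (2Σpt + ε)/(Σp + Σt + ε)` (ε = 1e−6)
   against the continuous TMTVprob, by stochastic gradient descent with
   learning rate 0.001 and momentum 0.9, with one augmented copy of each
   case (random translation ±16 mm, rotation ±10° about the axial axis,
   isotropic scaling 0.9–1.1, identical transform for both channels and
   the target; the target is interpolated, not re-binarized, since it is
   continuous-valued).
3. **Post-processing.**  The predicted map is binarized at probability
   strictly > 0.5.  Absolute-cutoff TMTVs re-threshold the PET globally
   inside that raw mask.  The 41% methodology is per-lesion: 26-connected
   components are isolated; components larger than 30 mL (likely
   coalescent nodal conglomerates) are split along SUV topography by a
   marker-controlled watershed on the inverted smoothed SUV; each
   sub-component is thresholded at 41% of its own SUVmax.  TMTV is the
   summed volume of surviving voxels; the per-(sub-)component count is
   the "generated ROI number".

## Fixed-grid preprocessing

All volumes are resampled (trilinear) to a 128 × 128 × 256 grid at
4 mm isotropic spacing — a 51.2 × 51.2 × 102.4 cm physical box that
holds a whole-body acquisition without distorting the aspect ratio.
Choices the format does not dictate, made here: the output field is
centered on the input field's physical center; out-of-field voxels are
filled with the modality background (0 SUV, −1000 HU); label volumes use
nearest-neighbor resampling so labels are carried, never invented.
Intensities are scaled affinely to [0, 1] from fixed ranges —
CT [−1000, 1000] HU, PET [0, 25] SUV — *clipping* outside the range
rather than rescaling per case, so the map is identical across patients.
Voxel indices are 0-based and a voxel's value sits at its center
coordinate; axes are (x, y, z-axial).

PET DICOM series can be converted to body-weight SUV
(`SUV = concentration × weight / dose`, dose decay-corrected from
injection to series start with `2^(−Δt/T½)`); geometry quality control
rejects duplicate or irregular axial slice positions (for NIfTI, where
irregular gaps are inexpressible, sheared or rotated affines are
rejected instead).

## Numerical choices

- **Boundary semantics.**  Fixed cutoffs use strict `>` (the rule is
  stated as "SUV > 2.5"); the 41% relative threshold uses `≥` so the
  SUVmax voxel itself is always a member; prediction binarization uses
  strict `> 0.5` so an exactly half-confident voxel is excluded.
- **Otsu.**  256 equal-width bins over the ROI's [min, max], threshold
  at the bin center maximizing between-class variance, computed per ROI
  (not globally).  The maximizing split is located with exact integer
  arithmetic: with equal-width bins the variance at a split is
  `width²(I₀w₁ − I₁w₀)²/(w₀w₁)` for integer class counts `w` and class
  sums of bin indices `I`, so the argmax and its first-maximum tie-break
  are deterministic.  This matters because empty bins in the histogram
  gap between modes produce runs of *exactly tied* splits, where
  floating-point implementations break ties by rounding accident.
- **Watershed markers.**  The dominant free parameter of the 41%
  pipeline.  Markers are regional maxima of the SUV field smoothed with
  a 1-voxel Gaussian, merged when closer than 2 voxels; both knobs are
  exposed.  Components at or below the 30 mL gate (measured on the
  processing grid), and components yielding fewer than two markers, are
  returned unchanged.  Sub-parts partition their component exactly, so
  volume is conserved through splitting; sub-components with no voxel
  above their 41% threshold are dropped and not counted.
- **Degenerate inputs.**  Empty raw prediction → TMTV 0 (a valid
  finding, not an error).  All-zero-SUV ROI → error (relative threshold
  undefined).  Single-valued ROI → error naming the ROI (Otsu
  undefined).  Dice of two empty masks is defined as 1 (perfect
  agreement on absence); confusion-matrix ratios with zero denominators
  are reported as missing (NaN), never as 0.
- **Statistics.**  Spearman uses average ranks on ties; the t-test is
  two-sided and paired; Bland–Altman limits are bias ± 1.96 × sample SD
  (n−1) of the paired differences.  Cohort reports emit median, mean and
  SD separately for every quantity.

## The V-NET implementation

The network, its autograd and the training loop are implemented directly
on NumPy arrays: convolutions are lowered to a single BLAS matrix
multiplication via im2col, down-transitions are 2×2×2 stride-2
convolutions (exact scatter in backward, since windows are disjoint),
up-transitions are nearest-neighbor upsampling followed by a 1×1×1
convolution, and gradients are propagated by topological traversal of
the recorded tape.  Gradient correctness is verified against central
finite differences in the test suite.  Weight initialization is He
(seeded); the output bias starts at −2 so the initial foreground prior
is low — tumor voxels are rare, and this stabilizes the first dice-loss
steps.  Leaky-ReLU (α = 0.1) is the nonlinearity.

Desk-scale defaults: 16 × 16 × 32 phantom volumes, ≤ 30 epochs, batch
size 1 (the optimizer, loss and augmentation policy are as above; batch
size is unspecified in the clinical setup and batch 1 gives the most
SGD updates per epoch, which at desk scale converges within the epoch
budget).  The full 128 × 128 × 256 / 100-epoch configuration remains
expressible through `VnetConfig`.

## What the phantoms emulate — and what they do not

The synthetic generator stands in for restricted clinical cohorts.  It
emulates: FDG-avid lesions as flat or Gaussian-heterogeneous ellipsoids
(peak SUV 6–15 over a 0.7 SUV background, radii 8–16 mm by default,
analytic ellipsoid volumes recorded as exact truth), coalescent
double-peak masses, physiological uptakes (brain- and bladder-like
spheres), an injection-site artifact at an arm edge excluded from the
truth (the classic false positive), additive Gaussian SUV noise
(SD 0.15, clipped at 0), and a schematic CT (soft-tissue body ellipse
near 0 HU, air at −1000, bone rods at +700).  Manual delineation is
emulated by loose bounding boxes with an 8 mm margin — physicians circle
uptakes generously; box-shaped ROIs are an assumption of this package.

It does **not** emulate scanner physics (PSF, reconstruction,
partial-volume effects), respiratory motion, anatomical texture, or the
inter-reader variability of real delineations.  Passing tests therefore
establish that the pipeline's operators, invariants and learning
dynamics are correct — not that clinical-cohort accuracy figures
transfer.  Cohort-dependent results (dice against expert readers,
per-subtype tables) are out of scope without the clinical data.

## Problem sizes used in validation

Property sweeps run 100 seeded random phantoms at 24³ voxels / 4 mm;
the training study uses 33 phantoms at 16 × 16 × 32 / 4 mm split
60/20/20 (20 train / 7 validation / 6 test), 30 epochs.  The analytic
recovery case is a 10 mm sphere on a 2 mm grid (4.19 mL).  These sizes
were chosen so the whole validation runs on a single CPU while every
code path — including the > 30 mL watershed gate — is genuinely
exercised (71 of the 100 random phantoms contain at least one gated
component).

## Known limitations

- The watershed marker policy (Gaussian sigma, merge distance) is a
  heuristic; on flat-topped plateaus the regional-maxima detector may
  return one marker and leave a coalescent mass unsplit.
- Otsu is implemented and used in ground-truth generation but not wired
  as a post-processing methodology by default; only the three clinically
  validated methodologies (41%, 2.5, 4.0) are.
- The DICOM path is minimal (single PET series, body-weight SUV only);
  NIfTI is the primary interchange format.
- CPU training beyond desk scale is impractical; the implementation
  targets correctness and reproducibility, not throughput.
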
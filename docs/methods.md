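# Methods

## The problem

A PET coincidence assigns an event to the line of response (LOR) between the
two scintillator crystals that registered the annihilation photons.  A
511 keV photon frequently Compton-scatters between crystals before it is
absorbed, and oblique photons penetrate past their entry crystal before they
first interact, so the registered crystal is often not the geometrically
correct one.  Both effects — inter-crystal scattering (ICS) and parallax —
displace LOR endpoints and blur the reconstructed image.

`icsfilter` compensates this in image space: a small multilayer perceptron
maps a 3D position (mm, tomograph-centered) to a normalized, non-negative
11×11×11 filter kernel that models the local image-domain blur, and these
position-dependent kernels are applied to the image estimate around each
OS-EM forward projection.  Because the correction lives in the image domain
it composes naturally with ordered-subset reconstruction, where only a
subset of the LOR data is visible per update.

## Monte Carlo detector model

Photon pairs are emitted back-to-back with isotropic direction.  Transport
through the scintillator uses Beer–Lambert free paths with energy-dependent
total attenuation, and interactions are chosen proportionally to the partial
coefficients:

* photoelectric absorption — deposit everything, terminate;
* Compton scattering — angle from the Klein–Nishina distribution (Kahn's
  rejection method), outgoing energy `E' = E / (1 + (E/511)(1 − cos θ))`,
  deposit `E − E'`;
* Rayleigh scattering — Thomson angle law `∝ (1 + cos²θ) sin θ`, elastic.

Photons below 10 keV deposit locally and stop.  A photon is registered to
the crystal with the largest summed energy deposit (ties go to the earlier
interaction); a coincidence requires both photons to register in distinct
crystals.  Energy is conserved along every chain to 1e−9 keV (tested).

The transport solid is the cylindrical annulus of the crystal stack; the
crystal id of an interaction point is its azimuthal sector × ring slab.
This is exact for a gapless ring up to the chord-vs-arc difference of
rectangular crystals, and an order of magnitude faster than per-box ray
marching.  Object attenuation and scatter, positron range, acollinearity,
energy windows and electronic effects are not modeled.

Attenuation coefficients ship as a CSV generated by an analytic LYSO-like
model: Compton from the integrated Klein–Nishina cross-section at an
electron density of 1.8×10²⁴ cm⁻³, photoelectric ∝ E⁻³ anchored to 33% of
the 511 keV total, and a small ∝ E⁻² Rayleigh term (total ≈ 0.87 cm⁻¹ at
511 keV, in the range of LSO-class scintillators).  It is a synthetic
stand-in, not vendor data.

## Projector

Forward and backprojection are one sparse matrix and its transpose: Siddon
grid traversal accumulates exact ray–voxel intersection lengths along the
chord between the front-face centers of the two crystals, optionally
averaged over an n×n grid of jittered sub-rays per crystal face
(`rays_per_lor`).  Adjointness is therefore exact to float accumulation —
this is load-bearing, because training approximates kernel gradients by
backprojection, which is only the true gradient for a matched pair.

The experiment pipeline uses 3×3 sub-rays so the system model includes the
crystal aperture; with a single central ray the learned kernels absorb
aperture blur and over-deconvolve.

## Skew-normal kernels

The univariate skew normal is `SN(x; μ, σ, α) = (2/σ) φ(t) Φ(αt)` with
`t = (x−μ)/σ` and `Φ` the standard normal CDF (via the standard error
function).  The 3D form is the product of independent axis factors
evaluated at grid points rotated in the xy plane by a learned angle θ
(`R = [[c, s, 0], [−s, c, 0], [0, 0, 1]]`); the scanner is cylindrically
symmetric, so only the xy rotation is needed.  Kernels are the density
sampled on the integer lattice [−5, 5]³ and normalized to unit sum, so
filtering preserves total activity.  Densities and their 10-parameter
Jacobian are evaluated in log space (`log_ndtr` for the CDF factor), so no
reachable clamp-box corner underflows; the Jacobian matches central finite
differences to ~1e−7 relative (tested).

Raw network outputs are clamped to μ ∈ [−5, 5], σ ∈ [0.01, 10],
α ∈ [−5, 5], θ ∈ [0°, 360°] (hard clamp; θ does not wrap — matching the
stated rule; gradients are zero outside the box, with a straight-through
option).  Kernel-grid units are voxel offsets.

## Networks

Both heads share a fully connected trunk 3 → 64 → 128 → 256 → 512 with Mish
activations (`x·tanh(softplus(x))`, overflow-safe).  The direct head emits
1331 values, rectified and normalized to unit sum; the skew-normal head
emits the 10 distribution parameters with no output activation.  Trainable
parameters: 855,987 (direct) and 178,314 (skew-normal).

Initialization: the final layer's weights are zeroed and its biases set so
the first prediction is exactly the documented starting kernel — the
isotropic Gaussian with σ = 7/6 (direct) or μ = (1,1,1), σ = (1,1,1),
α = (1,1,1), θ = 180° (skew-normal) — independent of the trunk's random
(fan-in-scaled, seeded) initialization.  Positions are standardized by the
FOV half-extent before the first layer; the public API takes raw mm.

## Training

A training sample is a position drawn uniformly from the image volume
(clipped to the scanner bore) and the Monte Carlo LOR histogram of a point
source at that position.  The predicted kernel is placed at the voxel
containing the position (nearest-voxel; the network input is snapped to
that voxel center so the net cannot learn sub-voxel shifts that would be
wrong at prediction time, where it only ever sees voxel centers), forward
projected geometrically, L1-normalized, and compared to the L1-normalized
measured histogram with the smooth-L1 (Huber) loss, summed over LORs.  The
kernel gradient is the backprojection of the LOR-space loss gradient
(including the exact L1-normalization Jacobian), then chained analytically
into the head — through the rectifier's active set and normalization for
the direct head, through the kernel Jacobian and the clamp for the
skew-normal head.  The whole chain matches finite differences to better
than 1e−3 (tested; mostly ~1e−6).  Optimization is RAdam.

The loss only receives contributions from LORs touched by the kernel patch
or carrying counts, so each sample's computation is restricted to that
active set — a pure speedup with identical results.

Reference protocol: 500 samples at 1e8 pairs each, 5-fold cross-validation
(80/20), 50 epochs, RAdam, lr 1e−5, batch 8.  Desk-scale protocol used by
the shipped experiment: 50 samples at 1e6 pairs, 200 epochs, lr 1e−4.  With
10× fewer optimizer steps per epoch and ~100× noisier histograms the
reference schedule leaves training visibly unconverged (the loss is still
falling linearly at epoch 50); the desk schedule was lengthened and its
step size raised until the training loss plateaus.  Cross-validation
produces per-fold curves for inspection; the network used for
reconstruction is a final fit on all samples.

## Reconstruction

OS-EM with 8 subsets (LORs interleaved by transaxial angle index modulo the
subset count) and 8 full iterations.  Per update, with image-space
filtering enabled, the current image is filtered before the geometric
forward projection of the subset.  The package supports both the
forward-only placement and the adjoint-matched variant (filter transpose in
the backprojection plus filtered sensitivity); the experiment uses the
matched variant, which is the EM algorithm of the composed model `A∘F` and
is provably monotone — at desk scale, 64 multiplicative subset updates with
an unmatched adjoint diverge once the kernels deviate from symmetric blurs.

Kernels are precomputed per voxel center into a `KernelStore`.  The octant
mode stores only the non-negative-coordinate octant and mirrors on read
(optionally averaging the 8 symmetry-mate predictions), an 8× storage
saving justified by the mirror symmetry of the ring's blurring pattern.
Filtering scatters each voxel's activity over its own kernel footprint;
kernels truncated by the volume boundary are renormalized per voxel, so the
total activity is preserved exactly.

## LOR-space reference correction

The comparison standard reconstructs with the forward model `B∘A`, where
`B` is a LOR-domain endpoint blur estimated by a high-sample Monte Carlo
run: coincidence pairs from a volumetric source are traced, and the offsets
of the registered crystals from the geometric entry crystals are
histogrammed jointly for the two endpoints.  Two details proved essential:

1. **Correlation** — parallax displaces both endpoints of an oblique LOR
   coherently; blurring the endpoints independently destroys this and makes
   the "correction" worse than none.
2. **Orientation** — the joint offsets are recorded in canonical per-LOR
   frames (transaxial: endpoint A is the one from which B lies
   counterclockwise within half a turn, which fixes the sign of the impact
   parameter; axial: ring-ordered endpoints), classed by transaxial
   separation and ring difference respectively.  Plain label-symmetrization
   erases the orientation (axial elongation becomes
   elongation-or-shrinkage) and again breaks the correction.

`B` is applied as two count-preserving stages (transaxial joint, axial
joint) with per-LOR renormalization over retained targets, and the exact
adjoint backs the EM update.  With this construction the reference is the
best reconstruction of the Derenzo phantom in the pipeline (ground-truth
correlation 0.96 vs 0.86 uncorrected), which is the premise for using it as
the NRMSE reference.

## Image-quality metric

NRMSE = RMS voxel difference over all voxels, divided by the mean
ground-truth voxel intensity; reported in percent.  Scale-equivariant.

## Study conditions of the shipped Derenzo experiment

* Scanner stand-in: 128 transaxial crystals × 12 rings, ring radius 40 mm,
  crystal pitch 1.95 / 2.5 mm, depth 10 mm.  A coarser 64×8 ring (the
  `ScannerGeometry` class default) keeps every geometric property but its
  3.9 mm aperture spans three voxels and dominates the detector response
  over ICS, which is not representative of the ~1 mm-pitch small-animal
  scanners this method targets.
* Volume: 40×40×16 voxels at 1.25 mm, fully inside the well-sampled FOV
  (voxels outside the scanner's coverage turn EM updates into noise
  amplifiers and corrupt volume-wide metrics).
* Derenzo phantom: 6 sectors, rod diameters 1.2–4.0 mm on triangular
  lattices with spacing twice the diameter, plate radius 18 mm, rod length
  12 mm, two 3 mm plates.
* Acquisition: 1e8 simulated pairs (~7×10⁶ coincidences); endpoint-blur
  estimate from 5×10⁶ pairs.

At these sizes the full pipeline (training data, two networks, kernel
stores, acquisition, four reconstructions) runs in roughly a quarter hour
on one CPU core.

## What the synthetic data does and does not show

The generator reproduces the mechanism the method corrects — Compton-driven
inter-crystal scatter and depth-penetration parallax in a pixelated ring —
under an idealized detector (no gaps, uniform crystals, no optical or
electronic effects, no object attenuation/scatter, no randoms).  Passing
tests therefore demonstrate the machinery: the learned position-dependent
kernels bring the OS-EM reconstruction close to the LOR-space-corrected
reference, and far closer than no correction.  They do not demonstrate
performance on measured data from a real scanner, where crystal
imperfections and the neglected physics alter the response; the intended
path there is fine-tuning on measured calibration data.

Reported NRMSE magnitudes are count-statistics-bound: at 10⁶–10⁸ simulated
pairs the Poisson noise floor between independently reconstructed
replicates is tens of percent, so NRMSE values against the reference sit in
the tens of percent regardless of method quality; the meaningful output at
this scale is the ordering and separation of the methods, which is large
(both corrected heads ≈ 47%, uncorrected ≈ 98% in the shipped
configuration).

## Numerical choices

* EM denominators guarded at 1e−12; iterates stay finite and non-negative.
* Registration ties break to the earlier interaction.
* Blur offset lists per class are trimmed at 1e−3 of the class maximum and
  renormalized.
* All randomness flows from explicit integer seeds (numpy PCG64; the Monte
  Carlo core is a single-threaded numba loop, bit-reproducible per seed).
* Kernel stores hold float32; accumulation is float64.

## Known limitations

* The projector's chord-length weighting differs from the Monte Carlo's
  solid-angle weighting per LOR (the analogue of a real scanner's
  normalization); all four reconstruction methods share the mismatch, and
  the learned kernels absorb part of it.
* The LOR blur factorizes transaxial × axial and conditions only on
  separation / ring difference; residual dependence (e.g. transaxial–axial
  coupling) is neglected.
* Kernels are placed at voxel centers; sub-voxel placement is out of scope.
* No GPU path; the sparse-matrix projector targets desk-scale geometries.
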
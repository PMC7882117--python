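# Methods

`pseudodect` implements a complete, simulated analogue of a pseudo
dual-energy CT (DECT) study: digital electron-density phantoms are scanned
with polychromatic 80/120/Sn-140-kVp beams; a patch-based CNN is trained to
map the 120-kVp image to pseudo 80- and 140-kVp images; and a
projection-domain two-material pipeline (step-wedge-calibrated decomposition,
virtual monochromatic synthesis, iodine quantification) is applied to both
the real and the CNN-generated dual-energy data.  This note records the
models, the conventions, and the choices made where the design was open.

## Attenuation physics

Mass attenuation coefficients for water, air, acrylic (PMMA), aluminum,
elemental iodine and tin are shipped as a CSV fixture on a coarse standard
energy grid, with duplicated points straddling the iodine (33.17 keV) and tin
(29.20 keV) K-edges, and are resampled by log-log interpolation onto a 1-keV
working grid over 10-150 keV.  Tissue surrogates of the CIRS-style
electron-density phantoms (adipose 0.96, breast 0.991, muscle 1.062, liver
1.072, plastic water 1.016, lung 0.195/0.51, trabecular/dense bone
1.161/1.53 g/cm^3) are modeled as water-like mixtures at their nominal
densities: the epoxy compositions are proprietary, and the quantitative
targets of the package concern the iodine/basis materials, not bone spectral
fidelity.  An iodine solution of concentration c mg/ml attenuates as
`mu_water(E) + (c/1000) * (mu/rho)_iodine(E)` per cm (dilute mixture rule,
additive mass).

Tube spectra use an analytic tungsten-anode model: Kramers bremsstrahlung
`N(E) ~ (kVp - E)/E`, tungsten K-lines (58/59.3/67.2/69.1 keV, 8% of
fluence) above their excitation threshold, inherent filtration of 9 mm
Al-equivalent, and an optional 0.4-mm tin prefilter for the 140-kVp beam.
The 9-mm default reproduces clinical beam quality: the effective energy of
the 80-kVp beam over a 20-cm water path is about 49 keV, as for a bow-tie
filtered scanner; with thin filtration the simulated beam would be far
softer than any clinical CT and beam-hardening effects would be
unrealistically exaggerated.

HU <-> mm^-1 conversion uses per-setting effective energies (80 -> 49.4,
120 -> 59.3, Sn140 -> 85.8 keV), derived from the package's own spectra as
the energy whose water attenuation matches a 20-cm water path's effective
attenuation, so uniform water reconstructs near 0 HU.  The choice cancels
exactly in the reproject-then-decompose pipeline because `hu_to_mu` inverts
`mu_to_hu`.

## Acquisition simulation

Phantoms are rasterized with 4x supersampled anti-aliasing into per-material
area-fraction maps.  A Siddon ray tracer computes exact per-pixel
intersection lengths; per ray the transmitted fraction is the
spectrum-weighted Beer-Lambert sum over 1-keV bins, detected counts are
Poisson with a per-ray photon budget, and the sinogram stores -ln(I/I0).
Photon budgets follow the emulated dual-source protocol's effective mAs
ratio 282:175:120 (80:120:Sn140) scaled from 1e5 photons/ray at 120 kVp.
Two scanner-preprocessing behaviors are emulated: counts-adaptive smoothing
of photon-starved rays (below 30 detected counts the log-projection is
replaced by a 5-bin detector-axis mean, as clinical reconstructors do to
suppress starvation bias/streaks), and the restricted 33-cm field of view of
the Sn-140-kVp channel, applied as reconstruction-support masking with the
mask radius recorded in the image metadata.

Geometry is parallel-beam, views uniform over 180 degrees, detector pitch
equal to the pixel pitch, detector covering the grid diagonal.
Reconstruction is standard frequency-domain filtered backprojection
(ram-lak/shepp-logan/hann windows; shepp-logan default as the closest open
analogue of a medium-smooth clinical kernel), pixel-driven linear
interpolation, validated against an independent FBP implementation.  All
analysis is 2-D axial; a "slice" is an independent noise realization.

## Two-material decomposition and parameterization

Each dual-energy ray pair (L, H) maps to equivalent aluminum/acrylic
thicknesses through two rational functions with quadratic numerators and
bilinear denominators (16 coefficients total, absorbing the beam-spectrum
characteristics).  Parameterization uses the orthogonal step-wedge stack:
6 aluminum steps (0-30 mm) crossed with 8 acrylic steps (5-40 mm) exposing
all 48 combinations in one projection; ROI means of the noisy 80/Sn-140
projections give 48 calibration samples.  The absolute-error fit is a
soft-L1 robust loss (quadratic core 0.1 mm) minimized by trust-region least
squares from a linearized least-squares start.  In the monochromatic limit
the denominator terms are unidentifiable (they lie in the span of the
quadratic basis); the minimum-norm start then keeps them near zero and the
fit reduces to the exact linear inversion.  Validation reports per-thickness
mean absolute errors, each aluminum thickness averaged over the acrylic
steps and vice versa.

When decomposing scans, the pipeline follows the image-based acquisition
chain of a clinical scanner: the reconstructed HU images are converted to
mm^-1, Siddon-forward-projected, and decomposed ray-wise.  Before
reprojection the truncated periphery of the Sn-140 image is completed from
the 80-kVp image; the annulus outside the 33-cm FOV is water-equivalent
bolus, whose HU is essentially energy-independent, so direct substitution is
accurate.  Negative thickness estimates are kept (not clipped) and their
fraction reported.

## VMCT and iodine quantification

A virtual monochromatic projection at energy E is
`mu_Al(E) * x_A + mu_acrylic(E) * x_B` per ray; FBP and conversion to HU at
E yields the VMCT.  An image-domain two-material solve (per-pixel inversion
at the two effective energies) is retained as the baseline; on iodine
phantoms it shows the larger beam-hardening cupping that motivates the
projection route, and a test asserts exactly that ordering.

Iodine maps are the FBP of the aluminum-thickness sinogram times a scalar
conversion factor.  The factor is an origin-constrained least-squares slope
of concentration versus background-subtracted syringe ROI signal.  It is a
software calibration constant rather than a per-scan measurement, and each
pipeline carries its own: the real-DECT pipeline calibrates on a noise-free
(high-dose limit) real scan of the 28-cm calibration phantom, and the
pseudo-DECT pipeline calibrates end-to-end on pseudo-DECT of the same
phantom.  Self-calibration makes the factor absorb systematic gain of the
energy mapping exactly as it absorbs spectral conventions in the real
pipeline; what the pseudo-DECT experiment then measures is how well the
calibration transfers from the training disks to the elliptical test
phantom.  Aluminum is an imperfect iodine surrogate (K-edge mismatch), so a
concentration-dependent residual bias is expected and documented rather
than corrected; the observed errors grow with concentration accordingly.

Syringe ROIs are concentric disks at 60% of the physical 10-mm syringe
radius; the background ROI is a disk in the uniform base material.  ROI
readings are averaged over several independently-noisy slices (4 in the
iodine experiment), emulating the multi-slice ROI statistics any observer
would collect from a 10-ml syringe spanning many 2-mm slices.  The
per-concentration error of the size-sweep experiment is the absolute
difference between the size-averaged estimate and the truth, matching the
established reporting convention for this experiment.

## Energy-mapping CNN

The network maps 32x32 input patches of the 120-kVp image to 18x18 patches
of both target energies (two output channels).  Three unpadded convolutional
stages whose kernels satisfy sum(k-1) = 14 (default 7/5/5), dense
connections feeding each stage the center-cropped activations of all earlier
stages plus the input, and deep supervision: 1x1 projection heads on the
hidden stages whose MSEs (on the 18x18 crop) join the final-stage MSE with
weights 0.15/0.15/0.70.  Hidden widths default to 8 channels per stage;
widths, kernel split and DSN weighting are open choices constrained only by
the 32->18 contract.  Weights are Xavier-initialized, biases zero; training
is plain SGD (learning rate 0.01, momentum 0.9, mini-batch 128, sampling
with replacement).

The per-stage objective is the Euclidean loss per output channel
(`sum_spatial(diff^2) / (2 * batch * channels)`).  The spatial-sum
convention matters: step size in SGD is the product of the learning rate and
the loss scaling, and only the former is conventionally reported.  With a
per-pixel-mean loss the printed rate of 0.01 moves these normalized CT
intensities (HU+1024)/4096 by so little that training crawls; with the
spatial-sum convention it takes effective steps while remaining empirically
inside the stable regime.  A divergence guard aborts if the loss exceeds
1000x its initial value.

Patches are extracted on a deterministic stride grid (stride 14 for
training, floor((N-32)/stride)+1 positions per axis), with optional
seed-controlled jitter up to stride/2.  Full-image inference slides 32x32
windows (stride 18, last window snapped to the border), reflect-pads the
7-pixel margin, and averages overlapping 18x18 outputs.  The implementation
is numpy/numba (float32, channels-last im2col GEMMs), single-threaded and
bit-reproducible for a given seed.

At short training budgets two stochastic effects dominate the syringe-level
accuracy: an initialization lottery (some Xavier draws acquire the
iodine-amplification feature early, others take many times longer) and slow
large-amplitude oscillations of constant-rate momentum SGD near its
stability edge.  The training protocol of the pseudo-DECT experiment
therefore uses standard remedies: several restarts are warmed up briefly
and scored on held-out calibration-phantom slices (worst per-syringe CT
number error over both output energies); the best restart continues
training, and the checkpoint minimizing that validation score is the model
retained.  Test readings average syringe ROIs over two independently noisy
evaluation slices.  No test-phantom data enters model selection.

## Synthetic data versus real data

The generator reproduces the geometry and materials of the calibration
phantoms (18-38 cm), the elliptical evaluation phantoms, iodine
concentrations 2.19-35 mg/ml, polychromatic spectra, quantum noise,
beam hardening (larger phantoms depress iodine CT numbers, as a property
test asserts) and FOV truncation.  It does not model scatter, detector
response, bowtie profiles, helical/cone-beam geometry, tube-current
modulation, electronic noise, or tissue heterogeneity; phantom inserts are
piecewise-constant disks.  Passing tests therefore demonstrate the internal
consistency and accuracy of the workflow under idealized but
physically-grounded acquisition, not clinical performance.

## Problem sizes and determinism

The standard study profile uses 192x192 images on a 420-mm field of view,
180 views, and a 1e6 photons/ray baseline at 120 kVp (about 15 HU of image
noise in a 28-cm phantom, typical of a medium-smooth abdominal protocol;
the step-wedge calibration uses its own 1e5 photons/ray).  The CNN trains
for 1500 iterations (four 300-iteration restart warmups plus continuation
of the winner) on patches from two slices of each of the five calibration
phantoms (1440 patches).  These sizes keep the full study reproducible on a
single CPU while leaving every qualitative behavior of the full-resolution
problem intact; every stage accepts larger grids, more views, more slices
and longer training through its configuration.  All randomness flows from
one integer seed via numpy `SeedSequence` spawning; noise-free runs and
same-seed noisy runs are bit-reproducible.

## Known limitations

- Aluminum/acrylic cannot represent the iodine K-edge exactly; iodine
  accuracy degrades toward high concentration and the largest phantoms.
- The wedge calibration spans aluminum-equivalent paths much shorter than a
  38-cm phantom's; the rational function extrapolates there, which the
  clinical-beam-quality default keeps benign but which would degrade with a
  soft beam.
- Tissue surrogates are water-like, so bone/lung spectral contrast is purely
  density-driven in this simulation.
- The CNN learns a conditional mean; it transfers the noise level of its
  training targets only partially, so pseudo images are smoother than real
  ones (visible as a CNR difference in VMCT synthesized from pseudo data).
- Syringe-level CT-number parity between pseudo and real images keeps
  improving with training budget well beyond what a single-CPU session can
  afford; at the packaged budget the worst-syringe difference is typically
  several tens of HU, a few times larger than what a fully converged
  (orders-of-magnitude longer) training of the same recipe achieves.
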
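# Methods

`heartsr` implements single-volume super-resolution for 3D whole-heart
bSSFP-like magnitude MR volumes: a Fourier-domain degradation simulator that
manufactures paired low/high-resolution training data, a 3D residual U-Net
trained to recover the high-resolution features, and a quantitative
evaluation protocol (SSIM, MSE, vessel edge sharpness, eSNR, eCNR, FWHM
calliper, Bland-Altman agreement).  Everything runs on seeded synthetic
phantoms, so the full pipeline is exercisable and testable with no clinical
data.

## Low-resolution simulation

A rapid whole-heart acquisition lowers resolution in the phase- and
slice-encode directions while the frequency-encode (readout) direction is
free.  The simulator reproduces that in the Fourier domain:

1. optional crop/pad of the grid to a standard matrix (the clinical-geometry
   preset uses 256×256×96);
2. centred 3D FFT (DC at index `N//2`);
3. along the phase and slice axes, retain only the central
   `k = round(f·N)` lines (`f` = retained-resolution fraction, default 0.5
   for both axes), then zero the `k − round(pf·k)` highest
   positive-frequency lines of the band (partial Fourier `pf`, default 6/8);
   the retained count is therefore `round(pf·k)` and the DC line is never
   discarded;
4. inverse FFT of the zero-filled k-space and magnitude (no
   homodyne/POCS partial-Fourier reconstruction — zero-fill only);
5. optional in-plane centre crop (192×192 in the clinical preset);
6. independent min-max normalization of both partners of the pair to [0, 1].

Conventions that were genuinely open and are fixed here: the central band
places its extra line (odd `k`) on the negative-frequency side; partial
Fourier removes *positive* frequencies by default (`pf_side="high"`,
switchable), matching an asymmetric acquisition of the upper k-space half;
whether partial-Fourier zeroing counts against the full matrix or the
retained band is ambiguous in general — it is applied to the retained band,
which corresponds to acquiring `f·N` lines at `pf` partial Fourier.  A
degradation that would leave fewer than 4 lines on an axis raises
"resolution too low".

`upsample_to_grid` performs sinc (zero-padded k-space) interpolation for
feeding prospectively coarse grids to a network trained on a finer grid; it
is exact for band-limited inputs and only upsamples.

## Phantoms

Real whole-heart bSSFP contrast is bright blood, intermediate myocardium and
dark noisy lung.  The generator renders that hierarchy from simple solids:
an ellipsoidal blood pool (default intensity 0.9) wrapped in a myocardial
shell (0.5), bright tubular vessels (0.95; straight segments or quadratic
Bezier arcs, default calibres 8 mm and 6 mm), and a dim background (0.1).
Defaults for sizes scale with the field of view; the default grid is 48³ at
1.6 mm (the isotropic high-resolution voxel of the clinical protocol).

Numerical choices that matter for the metrics:

* **Partial volume.** Structure occupancy is computed on a 3× supersampled
  grid per axis, so borders are sub-voxel smooth.  Binary voxel borders
  would alias exactly the gradients that edge sharpness and FWHM probe.
* **Noise before magnitude.** Gaussian noise (default sd 0.02) is added to
  the composed image and the absolute value taken, mimicking magnitude-MR
  statistics; this is a Gaussian approximation, not a Rician draw from
  complex pairs, and is recorded as such.
* **Bias field.** A low-order (linear + quadratic) polynomial multiplies
  the image, peak fractional amplitude 0.05 by default.
* **Masks** (blood / myocardium / lung) mark the noiseless geometric
  supports (occupancy > 0.5; lung = zero occupancy) and are mutually
  disjoint by construction.  One cross-sectional probe per vessel is
  emitted, centred on the centerline with its plane perpendicular to the
  local vessel direction.

`make_dataset` derives one independent seed per item from a master seed and
additionally jitters the geometry mildly (±10% on sizes, small centre
shifts).  Without geometric variation an 8-item training set would be eight
noise realizations of one image, and a training run would measure noise
averaging rather than edge restoration.

What the phantoms deliberately do **not** emulate: anatomy (chambers,
valves, trabeculation), cardiac/respiratory motion, flow and off-resonance
artefacts, coil sensitivities, parallel-imaging (GRAPPA) aliasing, and the
spatial noise correlations of a real reconstruction.  Passing tests on
phantoms therefore demonstrate that the pipeline's mechanisms work —
degradation, residual learning of contrast and vessel edges, metric
arithmetic — not that a phantom-trained network transfers to clinical data.

## Network

A 3D residual U-Net: encoder/decoder over `levels` scales (default 3),
3×3×3 zero-padded convolutions with ReLU, `base_channels` filters at the
finest scale doubling per level (default 16), max pooling ×2 down,
nearest-neighbour ×2 followed by a convolution up, skip connections by
channel concatenation.  The last convolution emits a single-channel residual
with no nonlinearity; the output is `ReLU(input + residual)`, enforcing the
non-negativity of magnitude images.  `residual=False` yields the plain
U-Net comparator (direct prediction).

Initialization is seeded He-uniform except the final layer, which is
zero-initialized by default (`zero_init_final`): the network then starts
exactly at the identity and short training runs spend their whole budget
improving on the low-resolution input rather than first unlearning random
residual noise.  Down/upsampling alternatives are limited to max/mean
pooling and nearest-neighbour; strided and transposed convolutions were
considered and omitted — they roughly double the hand-written backward code
for variants nothing in the protocol requires.

The implementation is pure NumPy with hand-written backpropagation
(`heartsr.nn`): convolutions are realized by stacking the 27 shifted views
of the padded input into a `(C·27, N)` matrix and issuing one GEMM; the
input-gradient pass reuses the same primitive with a flipped, transposed
filter bank.  Gradient correctness is verified in the test suite against
finite-difference directional derivatives.  At import the module raises the
glibc malloc mmap/trim thresholds so the large per-step buffers are
heap-recycled; without this, per-allocation mmap round trips dominate
runtime on virtualized hosts.

## Training

The reference recipe: l1 loss (mean absolute voxel difference) between
output and ground truth, Adam (β₁ 0.9, β₂ 0.999, ε 1e-8 — conventional, as
none are dictated), learning rate 1e-3, constant (no schedule; 1e-2 and
3e-3 stall at the identity plateau under short budgets), batches of two
whole volumes (no patch extraction), 200 epochs at full scale.  l2 is
available as the comparator objective.  No augmentation.  Shuffling is
seeded per epoch; two runs from identical (dataset, configs, seed) produce
identical loss traces.

The **desk-scale** configuration used by the tests and the acceptance
script shrinks the problem, not the recipe: 8 training + 4 held-out
phantoms at 48³, 2 levels, 8 base channels, 30 epochs (≈120 Adam steps,
about 3 minutes on one CPU).  Under these conditions the held-out SSIM gain
is ≈+0.03 with MSE dropping by roughly a third — the direction and
mechanism of the full-scale result at a fraction of its magnitude.

## Evaluation protocol

* **SSIM**: 3D Gaussian window σ = 1.5 truncated at 3.5σ (11³ support),
  K1 = 0.01, K2 = 0.03, data range 1.0, population (not sample) local
  variances, mean over the volume with the window-radius border excluded.
  Computed volumetrically, not slice-wise.  The implementation is
  cross-checked in the tests against scikit-image's Gaussian-weighted SSIM
  to 1e-6.
* **Edge sharpness (mm⁻¹)**: per probe, 60 radial rays in the vessel
  cross-section; each ray's trilinear-sampled profile is min-max normalized
  (making the metric invariant to global affine intensity changes) and the
  maximum absolute forward difference divided by the sample step is taken;
  the per-ray values are averaged.  Flat rays are excluded with a warning.
  On a voxel grid the per-ray values are equal only up to trilinear
  discretization anisotropy (≈6% CV on a half-voxel grid), which bounds the
  precision of the metric itself.
* **eSNR / eCNR**: ratio of mean blood intensity to mean lung intensity,
  and to mean myocardial intensity, exactly as mean-signal ratios (an
  sd-based denominator is deliberately not the default).
* **FWHM calliper (mm)**: along two perpendicular in-plane diameters,
  background-corrected half-maximum crossings with linear sub-sample
  interpolation; the two widths are averaged, mirroring two perpendicular
  manual measurements.  Under zero-fill degradation this calliper
  *overestimates* small-vessel calibre (≈1–1.5 low-resolution voxels, the
  regime where partial volume dominates) and can slightly underestimate
  wide rods, where truncation-ringing overshoot near the edge raises the
  profile peak; the calliper-bias experiment therefore uses coronary-scale
  cylinders at generic sub-voxel positions.
* **Bland-Altman**: bias = mean paired difference, limits of agreement =
  bias ± 1.96 × sd with the n−1 denominator.

## Generalisability sweep

The sweep degrades held-out volumes at a series of retained-resolution
fractions (phase and slice together, partial Fourier held at the template
value), super-resolves each, and aggregates SSIM/MSE per subject then
across subjects.  Fractions that violate the minimum-line rule are skipped
with a warning and recorded in provenance.

At desk scale the trained network shows its specialization in the
*relative* gains — largest at the training fraction (≈+0.036 at f = 0.5),
smaller below it, and slightly negative above it (≈−0.004 at f = 0.7, where
the learned sharpening overshoots) — while the *absolute* SSIM still rises
monotonically with input resolution, because the phantom baseline SSIM
climbs faster between f = 0.5 and f = 0.7 (≈+0.07) than a 120-step network
can gain.  A fully converged network inverts that ordering (perfect
recovery at the training fraction scores SSIM 1); the desk budget does not,
and the sweep's absolute-maximum check is reported as failing under these
conditions.

## Reproducibility

All randomness flows from one master seed through named substreams (data,
init, shuffle, test) via `SeedSequence` spawning; every stage is
independently re-runnable and `end_to_end` writes a manifest from which a
run re-executes bit-identically (the determinism is asserted in the test
suite).  Checkpoints store weights, the full architecture config and
training provenance (including training item ids, which `validate` uses to
refuse train/test overlap).

## Known limitations

* Phantom realism as above; no claim of transfer to clinical data.
* The NumPy network is single-threaded GEMM-bound; it is sized for
  desk-scale experiments, not for 500-volume training runs.
* The channel counts and depth of the full-scale architecture are not
  pinned by the protocol; the defaults here (16→32→64) are configurable
  choices, and results at desk scale should not be read as parity with a
  fully trained clinical model.
* Vessel centerline occupancy uses dense polyline sampling (0.2 mm step);
  calibre errors from that approximation are ≤ ~1 µm, far below voxel
  scale, but exact analytic tubes are not computed.
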
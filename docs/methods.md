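# Methods

## Imaging model

Scanning light-field microscopy (sLFM) samples a 4D phase space: behind
each microlens an Npix x Npix = 13 x 13 pixel patch resolves angle
u = (u1, u2), and an S x S = 3 x 3 sub-pitch galvo scan recovers spatial
sampling, so T = S^2 = 9 raw frames interleave into Npix^2 spatial-angular
views M(x, u) of size S*H x S*W. The forward model of a volume g(x, z) is
a depth integral of per-plane 2D convolutions,

    P(x, u_j) = sum_z g(:, z) * H(:, z, u_j),

rendered at reconstruction sampling and area-averaged down by Npix/S to
the measurement pixel. Two PSF families implement H:

* **Geometric** delta-shift kernels: a point at depth z appears in view u
  displaced by +alpha*z*u pixels. Sub-pixel displacements are split
  bilinearly so every kernel has mass exactly 1. The sign convention —
  positive u shifts map to positive lateral shift at positive z — is fixed
  here and honored by the refocus, preDAO and tomography modules (the
  refocusing shift is therefore -alpha*z*u, the one that re-centers the
  forward displacement).
* **Scalar wave-optics** kernels: a Debye/Fourier pupil model. The pupil
  disk (default NA 1.4, n 1.515, lambda 525 nm) is tiled into Npix x Npix
  square sub-apertures; for every depth the defocus phase
  -k z sqrt(n^2 - NA^2 rho^2) (the sign fixes the z-axis orientation to
  match the geometric convention) and optional Zernike aberration phase
  are applied, each view's sub-aperture is masked, and the intensity PSF
  is obtained by FFT. High-NA vectorial effects are ignored. `alpha` is
  fitted from the wave-optics centroids when both models are used.
  The coherent full-pupil PSF (`full_aperture_psf`) reaches the Airy width
  (~0.51 lambda/NA); the *incoherent* all-angle sum of sub-aperture PSFs is
  several times wider — that gap is exactly why tomographic fusion of the
  views is needed, and why no resolution claim is made for the plain
  angular sum.

Zernike modes use the OSA/ANSI single index, modes 3..20 (18 modes,
piston/tip/tilt excluded), represented internally as exact bivariate
polynomials: basis values and x/y gradients are analytic, and the basis is
orthonormal over the sampled disk up to edge pixelization (Gram error
~1/grid_size; <= 1e-3 at 512 px).

## Noise model and NLL-MPG loss

The camera model is mixed Poisson-Gaussian: M = Poisson(kappa * P) +
N(mu, sigma^2), with kappa the photon scale (counts per unit intensity)
and (mu, sigma) read noise calibrated robustly (median / 1.4826*MAD) from
dark frames or the dark corner views of the microlens patch. The loss is
the negative log of the tau-marginalized mixture. Numerical choices:

* The Gaussian mixing weights are normalized over the integer tau lattice
  (a theta-function normalizer) instead of the continuous 1/(sqrt(2 pi)
  sigma). The two agree to machine precision for sigma >= ~0.7 counts, and
  the lattice form makes the mixture a proper pmf whose sigma -> 0 limit
  is *exactly* the Poisson NLL P - M log P + log M! — the form whose
  stationarity through the forward projector reproduces the multiplicative
  Richardson-Lucy update (verified: at RL convergence the backprojected
  ratio field is 1 +/- 1e-3 on the support).
* The tau window is per pixel: the Gaussian factor confines the posterior
  to M - mu +/- 6 sigma regardless of brightness, so a common half-width
  ceil(6 sigma) + 8 around each pixel's own floor(M - mu) bounds the
  truncation error below float64 resolution while keeping memory
  independent of the brightness range. (A window proportional to
  sqrt(P + 1) would grow the lattice to thousands of entries for bright
  pixels at no accuracy gain.)
* The gradient d(NLL)/dP = 1 - E[tau | M] / P is computed analytically
  from the posterior mixture weights.
* A Stirling variant of the factorial term is available behind a flag; it
  agrees with the exact log-Gamma form to ~1e-2 per pixel for bright
  pixels and is kept only for comparison.
* Non-integer measurements (after interpolation) are well-defined: tau
  runs over integers while M enters only the Gaussian term.

## Reconstruction network

The network maps A = 49 selected views (central 7 x 7 of the 13 x 13
grid) to a D-plane volume in three stages:

1. **Depth decomposition** (fixed): each view is resampled at
   x + alpha*z*u per depth — the shift-only half of digital refocusing,
   keeping the angular dimension. A 49 x 99 x 99 patch becomes
   49 x 101 x 99 x 99.
2. **Deblurring/fusion trunk** (learned): nine 3D convolutions (3^3
   kernels, LeakyReLU) with three lateral linear-interpolation layers
   (2 x 2 x 13/12 = Npix/S) after convs 3, 6 and 8. Default widths
   (38, 34, 32, 32, 28, 24, 16, 8, 1) give 198,771 trainable parameters,
   within 2% of the 195k design point. The output head is a **square**
   (y = x^2) rather than a softplus: both guarantee non-negativity, but
   near zero the softplus gradient decays exponentially, and under the
   uniform dark-background NLL pressure of sparse fluorescence scenes the
   head freezes before bright structures can pull the estimate back up (an
   impulse phantom never localizes; bubtub quality stalls). The square
   head attenuates only linearly and escapes symmetrically; under
   identical conditions it localizes an impulse exactly and raises
   held-out MS-SSIM from 0.39 to 0.64.
3. **Self-supervision** (training only): the estimated volume is forward
   projected along scheduled angle subsets (21 per step, drawn without
   replacement until all 49 are used, then reshuffled; per-angle loss
   weights inversely proportional to visit counts), scaled to measurement
   sampling, and scored with NLL-MPG against the measured views. Inference
   runs stages 1-2 only.

Training numerics: inputs are divided by the photon scale so the trunk
sees O(1) intensities; predictions are floored at 0.25 counts and the
per-pixel NLL gradient is clipped at +/-25 (the unclipped Poisson gradient
is O(1) once P is within a factor of a few of M); push-down gradients are
gated off once a pixel's prediction is below 0.05 counts so the dark
background cannot saturate the head. Optimizer: Adam, lr 3e-4 with cosine
decay to 10%, seeded.

**Tiled inference** blends overlapping patches: `trim` pixels (default
overlap/4) are discarded from interior tile edges — the band polluted by
the conv zero-padding halo (9 px for nine 3^3 convs) plus the largest
refocus shift — and the kept regions are fused with per-axis sigmoid
ramps (steepness 4 px) normalized to sum to one.

**Axial fine-tuning** addresses the missing-cone elongation: a small
two-level lateral encoder-decoder with an additive skip is appended in
residual form, out = (sqrt(base + eps) + f(base))^2, with f's last conv
zero-initialized so the add-on starts as the identity on the pretrained
output. Only the add-on trains (base weights are verified bit-frozen),
supervised with NLL-MPG against ground-truth volumes of spherical-shell
phantoms. The add-on is ~10-50% extra parameters depending on width.

## preDAO (one-shot digital adaptive optics)

Per-view disparities against the center view are estimated by normalized
cross-correlation: mean-subtracted, Hann-windowed, zero-padded FFT
correlation with the integer peak refined on a 16x-upsampled lattice by
matrix DFT (radius 0.75 px). Registration accuracy on band-limited
texture: <= 0.25 px RMSE for shifts up to +/-5 px.

The defocus component — the disparity part linear in u with a shared
scalar beta — is removed by least squares; it encodes global focus error,
not aberration. The residual is interpreted as the wavefront gradient
sampled at each view's pupil patch and decomposed into Zernike modes by
linear least squares. Three details matter (each verified against the
wave-optics centroid oracle; without them the 18-mode inversion fails even
on noiseless data):

* the design matrix uses **patch-averaged** analytic gradients — the
  centroid of a sub-aperture PSF is exactly the energy-weighted mean of
  the phase gradient over the patch, not the gradient at the patch center;
* tip/tilt nuisance columns absorb the nonzero mean gradient of the
  center reference view (disparities are relative measurements);
* the linear-in-u projection applied to the data is applied to every
  design column, which collapses the defocus mode's column to zero — its
  amplitude is reported through beta, and sampled test aberrations set the
  defocus coefficient to zero accordingly.

Sampled aberrations use a low-order-dominated prior (amplitudes
proportional to 2/(n(n+1)) before r.m.s. normalization), emulating smooth
tissue-induced wavefronts. Equal-weight high-order sampling at 1
wavelength r.m.s. produces speckle-like sub-aperture PSFs whose
disparities no correlation method can track; with the smooth prior,
measured mode correlation with ground truth is 0.96-0.99 at 1 wavelength
r.m.s. on the 13 x 13 system.

## Time-weighted motion correction

The classic blend M_TW = r M + (1 - r) sum_t w_t(r) ShiftCubic(M_L(t), S)
uses inverse-distance temporal weights w_t proportional to r^|t - T/2|
(T = 9, center 4.5) and cubic-spline upsampling of each scan frame
anchored at its scan offset. r is clamped to [1e-3, 1]. Static scenes that
are band-limited at the microlens pitch are preserved to <1% RMS in the
field interior; the hard field-of-view border cannot be represented by the
scan interpolants and is excluded from that statement.

TW-Net replaces the global r with a per-pixel map: a five-conv network
(~19k parameters, 3x upsampling, sigmoid head; 153-px views give 459-px
maps) trained self-supervised with
MSE(TW(M, r(x)), D) + lambda * mean(-log r(x)), where D is the temporally
smoothed estimate at a fixed reference weighting (r = 0.5). The per-pixel
stationarity 2 r d^2 = lambda / r (d = M - D) drives r to 1 where the
frames agree and down where they disagree. Views are normalized by their
RMS before entering the net so lambda (default 0.05) is scene-free. The
map is produced at 3x the view sampling and area-averaged back for the
blend.

## Tomography baseline

Richardson-Lucy spatial-angular deconvolution with a normalized
multiplicative update (ratio backprojection divided by the backprojected
ones), uniform positive initialization at mean(M), positivity floor 1e-8,
seeded random angle-subset schedule, and an early stop if the Poisson NLL
increases five epochs in a row. Optional per-iteration DAO registers the
forward projections to the measurements (defocus excluded) and shifts the
projections before the ratio.

## bubtub generator

Three structure families rasterized with anti-aliased analytic masks:
solid spheres (beads, radius 1-3.5 vx), hollow shells (bubbles, radius
4-10 vx, wall 1-2 vx), and tubes along cubic-spline paths through random
control points (radius 1-2.5 vx), with uniform counts and intensities
(0.5-1.0). Optional aberration sampling rebuilds the wave-optics PSFs
under a low-order Zernike draw. A seed fully determines the output,
including the noise draw. The generator emulates structural diversity and
photon-limited MPG noise; it does not model fluorophore photophysics,
scattering, or spatially varying background, so passing tests demonstrate
correctness of the physics pipeline, not performance on real tissue.

## Desk-scale study conditions

All learning experiments run on CPU at a reduced geometry chosen once: a
5 x 5 angular grid with S = 5 (measurement sampling equals reconstruction
sampling, upsampling product 1), 21 z-planes, 33 x 33 patches, geometric
PSFs with alpha = 0.35, photon scale 60 counts per unit intensity, read
noise sigma = 2. The mini trunk keeps the nine-conv architecture at widths
(12, 12, 12, 12, 10, 10, 8, 8, 1) (~30k parameters). Self-supervised
training uses 200 Adam steps over four bubtub samples; evaluation is on a
held-out sample against the integrated-refocus baseline. Axial
fine-tuning uses five shell phantoms, 800 Adam steps at lr 3e-3 with
three restarts (the winner chosen by final training loss — the add-on
lands in a poor init basin roughly one seed in five, visible as a clearly
higher loss; the held-out metric is never consulted), and is evaluated as
the Gaussian-fit FWHM of the upper shell-wall z-profile (3 x 3 lateral
average) on three held-out shells; fits whose width exceeds the profile
support are discarded as failures. The full-scale
13 x 13 / 3 x 3 geometry is exercised for shape contracts, PSF physics and
preDAO, where no training is involved.

## Known limitations

* The scalar pupil model ignores vectorial high-NA effects and
  system-specific apodization; wave-optics assertions are model-internal.
* The mini-scale trained models demonstrate that the self-supervised
  physics loop learns (loss decrease, baseline improvement, impulse
  localization); they are not resolution-calibrated reconstructions.
* preDAO assumes a laterally dominant, smooth aberration; strong
  high-order content defeats correlation-based disparity estimation.
* TW-Net's closed-form equilibrium holds for the fixed-reference smooth
  target; a fully self-referential temporal weighting (weights recomputed
  from the trained r map itself) would couple the target to r and is not
  implemented.
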
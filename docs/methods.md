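# Methods

## The model

`duodomain` implements a dual-domain generative framework for paired medical
image reconstruction and synthesis. Two representations of the same object
are linked by an invertible acquisition transform `F`: the image domain and
the acquisition domain — the sinogram for CT/PET (parallel-beam Radon
transform) or k-space for MRI (centered 2-D DFT). Four generative functions
map between source and target data: `G_t_I` and `G_s_I` translate images in
the two directions, `G_t_A` and `G_s_A` translate the corresponding
acquisition-domain grids. All losses are empirical mean absolute errors.

Training proceeds in three stages:

* **S1 (intra-domain).** Each function is trained independently against its
  own supervised L1 term, e.g. `|G_t_I(x_s) − x_t|₁` in the image domain and
  `|G_t_A(F(x_s)) − F(x_t)|₁` in the acquisition domain.
* **S2 (inter-domain).** For each direction the two domain maps are trained
  alternately, the partner frozen: the image map is additionally tied to
  `F⁻¹(G_t_A(F(x_s)))` (weight λ₁), the acquisition map to `F(G_t_I(x_s))`
  (weight λ₂); symmetrically λ₃, λ₄ for the target-to-source direction.
* **S3 (cycle).** Only the image-domain maps are fine-tuned, everything else
  frozen. The source-to-source direction adds an image-domain cycle
  `|G_s_I(G_t_I(x_s)) − x_s|₁` (weight ξ₁) and a cross-domain cycle
  `|F⁻¹(G_s_A(F(G_t_I(x_s)))) − x_s|₁` (weight ξ₂); the target-to-target
  direction mirrors this with ξ₃, ξ₄.

At test time only the image-domain map of the requested direction runs; for
accelerated MRI its output additionally passes through data consistency:
predicted k-space values at sampled lines are replaced by the measurements.

Task presets carry the published weight settings: λ=ξ=0.5 for low-dose
reconstruction and PET-CT synthesis (stage learning rates 0.005 / 0.002 /
0.002); λ=0.2, ξ=0.1 with image/acquisition loss scales 10 / 0.1 for metal
artifact reduction; λ₁=λ₂=ξ₂=ξ₄=0.5 for MRI, where only the source-to-target
functions are trainable and λ₃, λ₄, ξ₁, ξ₃ are flagged inactive (the reduced
losses drop those terms; requesting a loss whose defining weights are
inactive raises).

## Numerical core

No GPU tensor framework is used. A compact tape-based reverse-mode autodiff
engine (`autodiff.py`) over float64 numpy arrays supplies exactly the ops the
framework needs — 3×3 convolutions, instance normalization, leaky ReLU, 2×2
pooling/upsampling, affine maps along the last axis, L1 reductions, and a
generic linear-operator node whose vector-Jacobian product is the operator's
adjoint. Every op is verified against central finite differences in the test
suite. Single-threaded float64 arithmetic makes training bit-reproducible for
a fixed seed.

The Radon transform is an explicit sparse pixel-driven projection matrix `A`
(parallel beam, detector count = image diagonal rounded to odd, linear
splatting onto the two nearest bins), so forward projection and its adjoint
(the interpolating backprojector `Aᵀ`) form an exact pair and per-angle
detector sums conserve the image sum to machine precision. Filtered back
projection uses the band-limited ramp built from its real-space kernel
(h[0]=¼, h[n]=−1/(πn)² for odd n), with an optional Hann apodization, and
divides the filter by the splat kernel's sinc²(f) response to deconvolve the
projector's known interpolation blur. With that compensation the 64×64
round-trip RMSE at 180 angles is below an independent dense-angle (720
projection) reference reconstruction, and decreases with angle count. The
Fourier transform is the unnormalized centered DFT; gradients use the exact
adjoint `N²·F⁻¹`.

**Acquisition normalization.** Raw line integrals of a unit-range image reach
tens of pixels, and unnormalized DFT coefficients reach `N²`; a fully
connected map trained on such grids with the published learning rates is
unstable (a single Adam step perturbs the output by O(1)). Inside the loss
graph the transform therefore works in normalized units: `F̃ = F/c`,
`F̃⁻¹ = c·F⁻¹` with `c = n_pixels/n_detectors` (Radon; the mean projection of
the all-ones image) or `c = √(H·W)` (Fourier, the orthonormal scaling). This
leaves `F̃⁻¹(F̃(x)) = F⁻¹(F(x))` unchanged and keeps acquisition-domain
activations of order one. The public array-level `radon_forward` /
`fourier_forward` remain physical (unnormalized).

## Backbones

* Image domain: a small UNet (depth 2 by default, base 8 filters, instance
  normalization, leaky ReLU 0.1, average-pool down / nearest-neighbour up,
  skip concatenation). The residual variant ("RUNet") adds the input to a
  zero-initialised 1×1 head, so an untrained network is the identity — a
  stable start when source and target are already close. Depth 2 rather than
  a deeper encoder keeps 32×32 toy problems from pooling to trivial grids
  and keeps CPU cost linear; depth is configurable.
* Acquisition domain: a fully connected affine map along the detector /
  phase-encoding axis, shared across angles and rows, initialised at the
  identity (optionally a residual two-layer variant, or a UNet).
* MRI: complex data travels as two real channels; the source-direction roles
  are the non-trainable data-consistency maps, bound per sample to the mask
  and measured k-space (in normalized units inside the loss graph).

Freezing is enforced structurally — optimizers are built per role from the
role's own parameters — and additionally audited: in audit mode every
optimizer step checks the SHA-256 checksum of every frozen role.

## Synthetic study conditions

The generators emulate the four tasks' degradation mechanisms on random
ellipse phantoms (one body ellipse, internal soft/bone structures, 1–3
hotter lesions; reproducible from the ellipse list alone):

* **Low dose** — the standard image is forward projected; expected counts are
  `counts_full` (default 500) at the sinogram maximum — a PET-like count
  level chosen so that quarter-dose inputs land in the 35–42 dB PSNR band
  clinical low-dose studies report — scaled by `dose_fraction` (default
  0.25); Poisson counts are reconstructed by subset-free EM (4 iterations;
  FBP switchable). The target is the same reconstruction of the noiseless
  sinogram, so dose 1 without noise reproduces the target exactly, and the
  thinned/full count ratio is binomially calibrated to the dose.
* **Metal** — 1–4 small high-intensity ellipses are inserted; images pass
  through a [−1000, 2000] HU window and the water attenuation coefficient
  0.192; rays lose counts as `exp(−β·metal-excess)` and are floored (photon
  starvation), and both source and target are FBP reconstructions of their
  respective sinograms, so an implant with no contrast leaves the pair
  identical.
* **MRI** — Cartesian Gaussian line mask (σ = n_lines/6, `round(n/R)` lines,
  6 center lines always sampled), zero-filled magnitude source, fully
  sampled target; measured k-space kept in provenance for data consistency.
* **Synthesis** — shared tissue labels pass through two monotone transfer
  functions: CT-like (sharp, bone-bright) and PET-like (blurred σ=1.5,
  lesion-hot), plus mild Gaussian noise.

Datasets draw per-sample seeds from a `SeedSequence` of the split seed;
regeneration from the JSON manifest is bit-identical. What these phantoms do
*not* model: anatomy-scale texture, scatter/randoms, multi-coil sensitivity,
beam polychromaticity. Passing tests therefore demonstrate the mechanics and
internal consistency of the framework, not clinical image quality.

The toy training condition used by the long-running checks is the 32×32
low-dose task, 48 projection angles, 20 training pairs, batch 4, base
schedule 5+5+5 epochs, Adam with the published stage learning rates.
Ablation presets (S1, S1+S2, S1+S3, S2+S3, full, image-domain-only) are
compared at a matched total role-update budget: each preset's epochs are
scaled so its total number of optimizer passes equals the full plan's.

## Evaluation

PSNR is `10·log₁₀(range²/MSE)` (+∞ sentinel for identical images). SSIM uses
the canonical Gaussian window (σ=1.5 truncated at 3.5σ, i.e. 11×11, K₁=0.01,
K₂=0.03, sample-covariance correction, data range taken from the reference
unless configured); both agree with an independent reference implementation
to 10⁻⁶ and machine precision respectively in the tests. The noise power
spectrum treats recon − reference as the noise image, detrends overlapping
ROIs (32 px, 50 % step) with a first-order plane, ensemble-averages squared
DFT magnitudes scaled by pixel area / ROI size, and bins radially; its 2-D
integral recovers white-noise variance to within Monte-Carlo error
(Parseval). SUV bias is the signed percent error of mean and max uptake in
an explicit ROI — signed because over- and under-estimation are both
clinically meaningful, and the ROI is an explicit argument because the
choice of region is a study decision, not a package default.

## Known limitations and observed behaviour at desk scale

Two effects, both absent at clinical image sizes, shape the toy-scale
ablation behaviour that the long-running checks measure:

* The cross-domain anchors route through `F⁻¹∘F`. At 32×32 with 48 angles
  the FBP round-trip carries a systematic bias of roughly 30 dB — the same
  order as the degradation being corrected — so the stage-2/3 cross-domain
  terms inject operator error comparable to the supervised residual.
* The cycle terms assume the target-to-source map can reproduce the source;
  for Poisson-noise degradations that map is stochastic, so the image cycle
  has an irreducible floor and its gradient (amplified ~3× by the trained
  `G_s_I` Jacobian) competes with supervision.

Consequently, on the 20-pair toy task at matched update budgets, stage-1-only
training attains the best held-out PSNR and the full three-stage schedule
trails it — the controls (stage 3 with ξ=0 improves PSNR; stage 2 improves
the run it extends) show the trainer mechanics are sound and localise the
gap to the cycle objectives themselves under these conditions. Other known
limitations: parallel-beam geometry only, single-coil MRI only, no
adversarial or perceptual losses, no GPU path, and mid-run resume is by
deterministic replay from (config, seed) rather than serialized optimizer
state.
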
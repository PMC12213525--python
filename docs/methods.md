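# Methods

## Model and assumptions

The reconstruction treats a lower-field MR slice `x_in` as a degraded view
of an unobservable higher-field image. Because the degradation operator
between field strengths is not practically modelable, the higher-field
target is represented *implicitly* by a guidance slice `x_guid` from a
higher-field acquisition: the method assumes that what distinguishes the
two field strengths — the noise floor and the tissue-contrast
characteristics — is captured by the second-order feature statistics (Gram
matrices) of a frozen convolutional network, i.e. by "style" in the
style-transfer sense. The guidance image therefore does not need to be
registered to, or share anatomy with, the input; it only needs to carry
the target style. Content (anatomy) is preserved by initializing every
style-transfer pass at the image being improved and by anchoring the
candidate-selection loss to the original input.

The iteration is a line-search gradient descent on candidates

    x~ = x − μ̃ [ (x − x_t) + λ (x − x_d) ],    μ̃ = i·μ,  i = 1..Nline,

combining a pull toward style-transferred images `x_t = T_N(x, x_guid)` at
several depths `N = N0 + k·Nstep` with a pull toward a denoised image
`x_d = D(x)` (the regularization-by-denoising term, weight λ). Candidates
are scored by a one-step transfer loss — apply a single style-transfer
step to `x~`, then measure `α·L_content(·, x_in) + β·L_style(·, x_guid)` —
and the best candidate becomes the next iterate. The identity candidate
(the unchanged iterate) competes by default, which makes the winning score
non-increasing across iterations: the procedure can stall but never
regress under its own objective. Selection ties break toward the smallest
(depth index, step index), the identity candidate losing ties, so runs are
exactly reproducible.

Two behaviors the formulation leaves open are implemented as flags with
these defaults: the denoiser is applied to the *current iterate* every
outer iteration (`denoise_every_iteration=True`), matching the
regularizer's residual `x − f(x)` evaluated at the iterate, and the
style-transfer candidates are regenerated from the current iterate every
iteration (`refresh_candidates_every_iteration=True`), the "online update"
that lets directions track the reconstruction. Both once-only variants are
available behind the flags. The Armijo rule for adapting μ̃ is deliberately
not implemented; the fixed schedule μ̃ = i·μ is the method's stated choice.

## Losses and their scales

Per layer `l` with `N_l` feature maps of `M_l` positions each, flattened
to `F^l ∈ R^{N_l×M_l}`:

- content: `½ Σ_{ij} |F_ij − F_c,ij|^p`, summed over the content taps;
- style: `Σ_l ω_l /(4 N_l² M_l²) Σ_{ij} |G_ij^l − G_s,ij^l|^p` with
  `G = F Fᵀ`;

with `p = 2` (classic) or `p = 1` (default; the subgradient of `|·|` at 0
is taken as 0, and the L1 substitution applies to both losses). Layer
weights `ω_l` default to uniform `1/L` over the style taps.

The two losses live on wildly different scales: the content loss is an
un-normalized sum over tens of thousands of feature entries, while the
style loss carries the `1/(4N²M²)` normalization. For the pretrained
engines the published ratios α/β = 1e-6 (VGG16) and 1e-4 (ResNets) are
wired into the presets. For the `tiny-random` backbone the default is
α = 1e-9, β = 1: at displacements typical of a candidate step the two
terms are then comparable (content ≈ 10–50 % of the objective), so style
drives the descent while content drift is still penalized. These defaults
were calibrated once against the shipped frozen network (seed 0) and are
part of the method configuration — random re-draws of the feature network
change its feature scale by over an order of magnitude and would need
re-calibration (see Limitations).

## The inner optimizer

`T_N` is a stateless normalized gradient descent on the pixels: each step
moves the image by `step_size · g/‖g‖_∞` and clamps to [0, 1]
(`clamp=True`). Normalizing by the gradient's sup-norm keeps the step
interpretable in intensity units (default 0.005, i.e. ≤ 0.5 % of dynamic
range per step) across layers and backbones whose raw gradient magnitudes
differ by orders of magnitude; the update remains a pure function of the
current image, so running the descent once for `max(depths)` steps and
snapshotting at each requested depth is exactly equivalent to independent
runs — which is how the multi-depth candidate generation is computed. A
zero gradient (e.g. guidance = content at initialization) yields a null
step, making identical inputs an exact fixed point. An Adam option exists
(`optimizer="adam"`); being stateful, each depth is then run from scratch.
Note that re-running `T_1` on its own output re-anchors the content
target, so `T_1 ∘ T_1 = T_2` holds exactly only when the gradient is
independent of the content anchor (α = 0); the test suite checks exactly
that identity.

## Backbones

`tiny-random` is a 4-layer stack of 3×3, stride-1, *valid* (unpadded)
convolutions with ReLU, channels (8, 8, 16, 16), He-scaled weights and
small biases drawn once from a seed. Valid padding is chosen so that a
constant input produces constant feature maps in every layer and a
one-pixel shift of the input shifts every activation by one pixel — both
properties the tests exploit. Style taps: all four rectified outputs;
content tap: layer 2. Taps are post-nonlinearity. The forward pass and the
analytic vector–Jacobian product with respect to the input are hand-written
NumPy; weights are frozen by construction (a parameter checksum is
asserted unchanged across uses). Minimum input size 16×16.

The pretrained layouts follow standard practice: VGG16 style from the
first eight convolutional layers' rectified outputs, content from the
fourth; ResNet50/152 style from the initial 7×7 convolution and residual
stages 1–3, content from the 7×7 convolution and stages 1 and 3 (the
stage outputs, since finer sublayers are not specified). Grayscale input
would be replicated to three channels and normalized with the backbone's
native constants. Extraction requires the optional `torch`/`torchvision`
dependency with pretrained weights; without it these backbones raise a
`DependencyError` pointing at `tiny-random`.

## Denoisers

`DenoiserSpec` is a stateless pure-function interface. `bm3d` wraps the
optional `bm3d` package with `sigma` defaulting to the pipeline's assumed
corruption (20/255). The dependency-light default is `gaussian`
(`kernel` = blur std in pixels, default 1.0, reflect padding — chosen so
the filter strictly improves PSNR at the assumed noise level on the
band-limited phantoms below); `median` and `identity` complete the set.
Outputs are clamped to [0, 1].

## Metrics

PSNR is `10·log10(max(x_ref)²/MSE)` with the peak taken over the
*reference* (a fixed dynamic range is available via `data_range`);
identical images report `inf`. SSIM uses a uniform 7×7 sliding window,
`k1 = 0.01`, `k2 = 0.03`, dynamic range L = 1 for [0, 1] images; only
fully-interior windows contribute, and window variances/covariances use
the unbiased (n−1) normalization — the conventions of the scikit-image
implementation, against which the suite cross-checks to 1e-6 (the
in-package implementation is independent of it). A Gaussian-weighted
window exists behind a flag; it shifts SSIM slightly and is off by
default.

## Synthetic phantoms

`PhantomSpec` generates brain-like compositions of nested/overlapping
ellipses (a fixed, centered head ellipse plus seeded random interior
structures) at chosen tissue intensities, smoothed by a Gaussian
point-spread of 0.8 px — MR images are band-limited by acquisition, so a
realistic phantom has no perfect step edges (`psf_sigma=0` disables this
for geometry tests). The low-field degradation is a strictly monotone
contrast remap `y = gain·x^γ` (default gain 0.85, γ 1.3; monotone so
tissue ordering is preserved between "field strengths") followed by AWGN
with σ = 20/255 and clamping. `make_pair` mirrors the evaluation
protocols: *frozen* guidance (default) supplies a different-anatomy
phantom at high-field contrast — guidance shares style, not content —
while *matched* reuses the same anatomy. Generation is deterministic per
seed, with separate seed streams for geometry and noise.

What the phantoms do **not** emulate: Rician noise statistics, coil
sensitivity profiles, k-space sampling artifacts, partial-volume tissue
mixtures, or real neuroanatomy. Passing tests therefore demonstrate the
algorithm's mechanics (selection optimality, monotone selection loss,
quality gains under contrast shift + AWGN), not clinical performance on
scanner data.

## Problem sizes and defaults used in the checks

The self-checks run on 64×64 phantoms with a reduced outer schedule
(N0 = 20, Nstep = 10, Nstyle = 2, Nline = 3, Niter = 3, μ = 0.1, λ = 0.3,
Gaussian denoiser) — sizes at which the full pipeline, its exhaustive
re-scoring oracle, and a five-pair end-to-end study all complete in
seconds while exercising every code path at the published depth-schedule
structure. Under these conditions the reconstruction gains ≈ 4 dB PSNR
and ≈ 0.06 SSIM over the noisy input on every seeded pair;
`scripts/acceptance.py` recomputes exactly these quantities. The published
full-scale settings (N0 = 500, Nstep = 100, Nstyle = 3, Nline = 5, with
per-dataset Niter/μ/λ) are wired into the presets.

## Numerical choices

- All images are float64 in [0, 1]; inputs outside the range or non-finite
  are rejected, candidates are clamped after every update.
- `candidate_update` is computed as the algebraically identical
  combination `(1 − μ̃(1+λ))·x + μ̃·x_t + μ̃λ·x_d`, which returns `x` at
  μ̃ = 0 and `x_t` at (μ̃ = 1, λ = 0) bitwise.
- Divergence (non-finite loss) raises an error carrying the iteration
  index and partial trace rather than returning silently.
- Ellipse placement retries degenerate draws up to 50 times before
  erroring.
- 16-bit PNG output bounds the save/load round-trip error by 1/65535;
  intensity normalization on load defaults to percentile (0.5, 99.5),
  robust to MRI outlier voxels (min–max available; constant images are
  rejected under min–max with a pointer to percentile mode).

## Known limitations

- The α/β balance of the evaluation loss is calibrated to the frozen
  feature network in use. With arbitrary re-drawn `tiny-random` weights
  the style-loss scale varies by ~30×, and a poorly scaled balance lets
  the identity candidate win every iteration (the method stalls at the
  input — it never regresses). The shipped configuration fixes the
  network (seed 0); users swapping backbones should revisit α/β.
- With frozen different-anatomy guidance the method transfers contrast
  and noise statistics, not anatomy; it cannot hallucinate structure, and
  residual SSIM after the reduced schedule (~0.54 on phantoms) reflects
  remaining noise, not content errors.
- Per-slice 2-D processing only; no volumetric coupling between slices.
- The selection loss's content anchor is the *noisy* input, so
  over-aggressive denoising is penalized by design; at very high noise
  levels this conservatism slows convergence.
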
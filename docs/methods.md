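# Methods

`drls` segments a single hypodense lesion inside a volume of interest (VOI)
with a localized region-based level set whose energy weights, local-window
radius and initialization are regulated over the iterations by a 3-class
estimate of the contour's position relative to the lesion boundary. This
note records the model, the numerical choices, and what the synthetic
phantoms do and do not establish.

## Level-set model

The evolving surface is the zero set of `phi` on the voxel grid, interior at
`phi < 0`. The smoothed Heaviside is the interior profile with a compactly
supported C² quintic transition of half-width `eps = 1.5` voxels; its
derivative magnitude is the matching quartic Dirac bump. For each surface
voxel `x` a cubic window of half-width `rad` collects

    u_x, v_x   — Heaviside-weighted interior / exterior means of I,
    A_in, A_out — the corresponding weighted window volumes,

computed for all voxels at once with box filters (`O(volume)` per field,
independent of `rad`; windows clip at the grid border; an empty window side
falls back to the full-window mean and is flagged in the diagnosis string).

Three data speeds are implemented (positive speed raises `phi`, shrinking
the interior):

* **MS** (default) — first-order mean-separation flow
  `-(u_x - v_x) · [λ₁ T_in/A_in + λ₂ T_out/A_out]` with
  `T = Σ_B δ(phi(y)) (I(y) - mean)`. This is the gradient structure of the
  localized "maximize the interior/exterior mean separation" energy. Being
  linear in the residuals, zero-mean noise averages out over the surface
  patch inside the window.
* **MSQ** — the area-normalized squared-residual difference
  `λ₁ Σ δ(I-u)²/A_in - λ₂ Σ δ(I-v)²/A_out`.
* **UM** — the same without area normalization (localized
  piecewise-constant fit).

Two properties were decisive for the defaults, both verified by direct
force-sign probes on two-level spheres:

1. The `δ(phi(y))` factor inside the window sums (the discrete counterpart
   of the surface measure in the continuous speed integral) is essential:
   without it, window voxels far from the surface inflate the interior-fit
   term and create a spurious stable radius at roughly 1.5× the object
   radius, so contraction from a large initialization stalls.
2. MSQ has an irreducible `σ²/A_in` noise floor: from a small interior
   under additive noise the interior term dominates for *any* weight ratio
   attainable by the exponential regulation rule (which is confined to
   `[e^-1.5, e^1.5]`), and the contour collapses. The first-order flow has
   no such floor, recovers the phantom from 6- and 25-voxel
   initializations alike, and is therefore the default; MSQ and UM remain
   selectable for noiseless or well-initialized problems.

Curvature regularization `μ δ(phi) div(∇phi/|∇phi|)` uses central
differences with a `1e-8` gradient floor; `μ = 0.1` by default and has
little effect on the phantom results, as expected for a smoothness weight.

## Explicit update, time step and band

The force is evaluated on the narrow band `|phi| < 1.5·eps` without the
outer Dirac weight — the weight is the variational density, not a numerical
necessity, and keeping it pins the band edges. Per iteration the band
speeds are clipped at their 90th percentile `q` and scaled by `1/q`, and the
step is `cfl = 0.45` voxels; this robust normalization makes the dynamics
exactly invariant to affine intensity rescaling and scale-free across
contrasts. A fixed `dt` bypasses the normalization when set. `phi` is
clamped to ±4·eps; the far field carries no information beyond its sign.

## Stabilization without reinitialization

After each step the profile is relaxed by explicit substeps of

    phi += dtau · ν · (Δphi − div(∇phi/|∇phi|))

(defaults `ν = 1`, `dtau = 1/6`, 2 substeps; `ν·dtau ≤ 1/6` is the explicit
3D stability bound). The pair equals `div((1 − 1/|∇phi|) ∇phi)`: it
diffuses where the profile is steeper than a signed distance function and
sharpens where it is flatter, so an SDF is an exact fixed point, the zero
set stays put, and the kinks/plateaus created by the band update relax at
unit slope. Pure diffusion was tried first and rejected: it either cannot
repair plateaus fast enough (the front becomes diffusion-limited) or it
displaces the interface.

## Regulation

With `(p1, p2, p3)` = (contour inside, near-boundary, outside):

* weights: `λ₁ = exp((1+p1+p2)/(1+p2+p3))`, `λ₂` its reciprocal-exponent
  mirror; both in `[e^0.5, e^2]`, swap-symmetric under `p1 ↔ p3`, with
  `λ₁ > λ₂` iff `p1 > p3`. Under the sign convention above, λ₁ weights the
  interior-statistics channel and λ₂ the exterior one; an inside contour
  expands, an outside one contracts, and near the boundary the two balance
  and local texture decides.
* window radius: 8 voxels when `0.4 < p2 < 0.6`; otherwise
  `round(25·|p1 − p3|)` clamped to `[5, 25]` ("literal" rule). The printed
  form of the far branch is ambiguous, so an "additive" reading
  `round(5 + 5·|p1 − p3|)` is kept behind `window_rule`; the literal rule
  is the default because a far contour genuinely needs a window large
  enough to see the opposite region — that, not the weight asymmetry, is
  what makes recovery from far initializations work.
* initialization: SDF balls at the candidate radii (default 6, 10, 20, 30,
  40) are scored by the classifier; maximal `p2` wins, ties to the smaller
  radius (less risk of capturing background).
* the classifier is queried every 5 iterations (`query_period`; 1 is
  available), using the current contour from the first query on.

## Geometric oracle

For CNN-free operation and testing, the oracle scores a contour by
`s` = mean signed distance of the mask-border voxels to the ground-truth
boundary, normalized by the GT equivalent radius, and returns
`p2 = exp(-(s/0.25)²)` with the remaining mass on `p1` (s < 0) or `p3`.
Distances are referenced to the continuous boundary halfway between voxel
centers (a ±0.5-voxel correction on the center-to-center EDT plus a
0.5-voxel shell offset), so a mask identical to the GT scores `s = 0`
exactly. Training labels use the oracle's own class-switch distance
`0.25·√ln 2 ≈ 0.21` as margin, so label and oracle argmax agree everywhere.

## Contour-position CNN

Input encoding crops the intensity volume to the contour's bounding box
expanded by 20% per side, resamples trilinearly to a fixed tensor and
z-scores it; the contour's position is conveyed by the crop geometry alone.
The default architecture is four blocks of 3³ conv + batch norm + PReLU +
max pool (depths 16/32/64/128) and three dense layers ending in a 3-way
softmax. "2×2×2 pooling except the first layer" is read as a 2×2×1 first
pool: the receptive-field arithmetic then gives 46×46×24 for the 80×80×40
input, and the implementation reports its own computed field rather than
asserting a figure. A reduced profile (40×40×20 input, depths 8/16/32/64,
isotropic pooling, ≈92k parameters) is the desk-scale default for tests.

Training is SGD with momentum 0.9 and decoupled weight decay
`η = 4·10⁻⁵` (`v ← ζv − α∇ω − ηω`), batch = one volume, learning rate 0.01
with staircase decay ×0.1 every 100 global steps, dropout 0.7 (drop
probability) on the hidden dense layers, cross-entropy plus `(η/2)‖ω‖²` on
conv/dense weights. Hidden weights start truncated-normal (σ = 0.1, ±2σ);
the 3-node head starts at zero so the initial prediction is exactly uniform
(step-0 loss = ln 3). Two safeguards address one-volume batches: a global
gradient-norm clip at 5 (float32 momentum otherwise overflows on occasional
spikes), and a post-training "precise BN" pass that replaces the
exponential-moving-average normalization statistics — which at batch size 1
reflect only the last ~10 examples — with plain averages over the training
set. Everything is bit-deterministic per seed on one machine.

## Phantom generator

A phantom is a sphere, random-axis-ratio ellipsoid, or lobulated union of a
parent sphere with 2–4 surface children (30–60% radius), rendered at
VOI scale (default 80×80×60 voxels) as a two-level image (background 100,
lesion 60, HU-like), with optional smoothed multiplicative heterogeneity
inside the lesion (4-voxel correlation scale), Gaussian edge blur (the
partial-volume stand-in, default σ = 1 voxel), and additive Gaussian noise.
The ground truth is the noiseless support. The generator emulates the size,
contrast, heterogeneity and noise ranges of low-contrast liver lesions in a
VOI; it does **not** model CT physics (beam hardening, reconstruction
kernels, correlated noise), neighboring anatomy (vessels, liver edge,
adjacent organs), or multi-lesion fields. Passing tests therefore
demonstrate correct mechanics and the claimed qualitative behaviors
(recovery from far initializations, lower sensitivity to initialization
than a fixed-parameter baseline), not clinical-grade accuracy.

## Problem sizes used by the test suite

Chosen so the whole suite runs comfortably on one CPU: the noiseless
reference phantom is 80×80×60 with radius 15 and contrast 60, evolved for
the full 200 iterations; the robustness comparison uses ten 64³ phantoms
(radius 12, contrast 40, noise σ = 15) with initializations 6/10/15/20/30
and at most 100 iterations with volume-plateau early stopping (relative
interior-volume change < 10⁻³ over 10 iterations, earliest at iteration
40); classifier checks train the reduced profile on ~60 examples built from
four 64³ phantoms plus label-preserving augmentation.

## Known limitations

* The regulated flow assumes one lesion per VOI and a roughly blob-like
  topology; no shape priors, no multi-object coupling.
* The first-order mean-separation default can stall when the window sees no
  intensity asymmetry at all (exactly equal means); the window-radius
  regulation exists precisely to avoid that state, but pathological
  textures could still produce it.
* Batch-size-1 batch normalization is instance normalization in disguise;
  the precise-BN pass narrows, but does not eliminate, the train/eval gap.
* Surface metrics use border-voxel centers; sub-voxel surface positioning
  is not modeled.
* Anisotropic spacing is honored only by the surface-distance metrics;
  evolution and windows work in voxel units.
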
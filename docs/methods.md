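# Methods

This note records the mathematical model the package implements, the
defaults it ships with, and the numerical choices behind the solvers.

## Forward model

A hyperspectral scene is a non-negative cube `nh × nw × nc` of photon
rates (photons s⁻¹ voxel⁻¹). Each spatial slice is unrolled column-major
(row index fastest) into the scene matrix `X` of shape `(np, nc)` with
`np = nh·nw`, so a vertical track — a contiguous band of columns — is a
contiguous row block `X⁽ⁱ⁾` of `X`.

The instrument splits the field of view into `nτ` equal-width vertical
tracks. One *shot* displays a compound pattern (one subpattern per track)
on the spatial light modulator and integrates for `Δt` seconds; the
spectrometer records one spectrum per track:

```
G[i, ℓ] = ζ⁽ⁱ⁾ᵀ X⁽ⁱ⁾·,ℓ · Δt            (+ α·Δt dark current)
```

Counts are Poisson-distributed with that mean when noise is enabled.
Per-shot substreams are derived from `(seed, shot_key)` so shot order
never changes the draws.

### b-bit pattern realization and offset correction

A real-valued pattern `p` is displayed on a `b`-bit modulator as

```
ζ = c·(p/‖p‖∞ + 1),   c = (2^(b−1) − 1)/(2^b − 1),
```

snapped to the b-bit grid by round-half-away-from-zero. For patterns
whose entries lie in `{−a, 0, +a}` — Bernoulli rows and Haar functions —
the snap is exact. The constant *offset pattern* `ζ = c` is acquired
separately (averaged over repeats in noisy mode; 10 by default, matching
a 506 + 10 = 516 shot budget at ~6.2% sampling) and the affine map is
inverted per track and channel:

```
pᵀX·,ℓ = (2^b − 1)·‖p‖∞ / ((2^(b−1) − 1)·Δt) · (G − Ḡ_offset).
```

`b = 1` is rejected for compound patterns (the offset pattern would be
all-ones, making the correction degenerate); full sampling uses 1-bit
delta patterns that need no offset and bypasses that check internally.

## Non-adaptive block compressed sensing

Each track gets an independent `m × (np/nτ)` Bernoulli matrix with
entries `±1/m` equiprobable, regenerated on demand from `(seed, track)`.
The global operator is their block-diagonal stack. Reconstruction solves,
per spectral channel,

```
min_x  TV(x)   s.t.  Φx = y        (equality mode, noiseless data)
min_x  TV(x) + (μ/2)‖Φx − y‖²      (penalized mode, noisy data)
```

with anisotropic TV (forward differences, replicate boundary) and a
positivity constraint, by an augmented-Lagrangian / ADMM scheme in the
spirit of TVAL3:

- splitting variables for the TV term (soft-thresholding) and positivity
  (projection), with penalty `β = 32` on the rescaled problem;
- a direct Cholesky solve of the quadratic x-subproblem for signals up to
  8192 pixels, diagonal-preconditioned CG above;
- multiplier updates on the data constraint in equality mode, and a final
  exact affine projection onto `{Φx = y}` (min-norm correction through
  the cached Gram factorization) so square/complete systems recover
  exactly;
- internal rescaling (operator to unit spectral norm, signal to O(1)) so
  the default penalties work across intensity scales;
- best-iterate tracking under a fixed merit (TV + fixed-weight data
  residual): plain ADMM is not monotone, so the solver reports the best
  iterate so far, making the objective history non-increasing by
  construction.

Non-convergence is reported on the returned info object, never raised.
Channels share one set of factorizations; they are solved jointly as
multi-right-hand-side linear algebra.

## Adaptive basis scan with wavelet prediction

The adaptive method measures orthonormal 2D Haar coefficients directly,
one coefficient per track per shot (a level-j Haar function is supported
on one `2ʲ × 2ʲ` dyadic block, so it fits inside a track whenever `2ᴶ`
divides the track width — enforced by `SamplingSchedule.validate_for`).
The sign convention matches PyWavelets' separable Haar DWT with
periodization, which is also the inverse-transform engine.

The scan proceeds coarse to fine:

1. measure all level-J approximation coefficients (round-robin batches);
2. at each scale j: inverse-transform everything measured so far into the
   scale-j approximation image, average channels to grayscale, bicubic
   ×2-per-axis upsample (edge padding, no anti-aliasing), and one-level
   Haar transform — the detail subbands are the predicted scale-j
   coefficients;
3. sort each track's candidate indices by descending predicted magnitude
   (ties: orientation H, V, D, then raster position), keep the top
   `ceil(p_j %)` per track, zero the rest, and measure the retained ones
   with compound patterns; exhausted queues idle on the offset pattern
   and their detector rows are discarded.

With every `p_j = 100` and no noise this is a complete orthonormal
transform, so reconstruction is exact to roundoff. The shipped default
percentages `(80, 50, 25, 8)` for `J = 4` land the overall sampling ratio
in the few-percent regime on dyadic scenes; they are this package's
choice, documented here, not a published operating point.

## Synthetic scenes

Two generators, both seeded and exactly reproducible:

- `mosaic`: a binary-space-partition rectangle tiling with per-region
  random spectra — piecewise-constant, the TV-friendly cartoon model;
  region boundaries are generally non-dyadic, so fine-scale Haar detail
  coefficients are genuinely nonzero.
- `blobs`: smooth elliptical Gaussian-like blobs with narrow spectral
  peaks — a stand-in for diffuse fluorescent targets.

Both rescale so the maximum equals `intensity_scale` (default 5·10⁴
photons s⁻¹ voxel⁻¹). These are idealizations: no stray light, no
modulator diffraction, no spectral cross-talk between tracks.

## Studies and metrics

- PSNR uses peak = max of the ground truth and voxel-wise MSE; identical
  inputs report an infinity sentinel. Relative error is Frobenius.
- The comparison runner evaluates multitrack full sampling, single-track
  adaptive, multitrack non-adaptive, and multitrack adaptive on one
  scene; per-method failures are recorded per row, not raised.
- Sweeps vary illumination `max(X·Δt)`, dark current `α`, or integration
  time `Δt` over a grid with `replicates` independent noise streams
  (derived from one seed); the measurement plan is part of the instrument
  and is held fixed across the sweep, which also lets the TV solver's
  factorizations be built once. Sweep reconstructions use the penalized
  mode with a 120-iteration cap and `tol = 1e-5`: with Poisson noise in
  the data, useful accuracy saturates far above the solver's `1e-6`
  default. Trend assertions in the tests use medians over replicates.
- The timing model is affine: `shots·Δt + patterns/switch_rate +
  reconstruction_time`, with default `Δt = 0.1 s`, 255 patterns/s
  grayscale and 10 638 patterns/s binary switching. Problem sizes in the
  tests (64×64 cubes, 2–4 tracks) are desk-scale choices of this package.
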
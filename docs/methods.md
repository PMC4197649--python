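# Methods

## Model

Stereo half-images are ternary luminance-contrast grids: `+1` bright dot,
`−1` dark dot, `0` background. Four frame-level binocular operators act on a
window `W` of `k` pixels at window disparity `d` (left-eye coordinates; the
right eye is sampled at `x − d`, so `d = x_L − x_R`, negative = crossed):

- cross-correlation `C`: window mean of the pixelwise products `I_L I_R`;
- cross-matching `M`: window mean of the half-wave-rectified products
  `[I_L I_R]⁺` — the rectification acts at single-pixel resolution, so `M`
  counts the fraction of contrast-matched dotted pairs;
- generalized cross-matching `G`: rectification applied to the window
  *average*, `[C]⁺`, with the window size `k` as the extent of pre-threshold
  spatial pooling;
- the ON/OFF-channel form `Σ([I_L]⁺[I_R]⁺ + [−I_L]⁺[−I_R]⁺)/k`, which is
  identical to `M` on ternary inputs (the tests verify this exhaustively for
  all ternary windows up to k = 4).

Expectation over dot patterns is a separate averaging step, so the same pure
operators serve tuning curves, variability simulations and psychophysics.

### Trinomial theory

For Bernoulli single-pixel dots each window pixel is independently a
matched, reversed or background combination with probabilities
`p = ((1+c)ρ/2, (1−c)ρ/2, 1−ρ)` when the window disparity equals the
stimulus disparity and `p = (ρ²/2, ρ²/2, 1−ρ²)` otherwise; window counts
`n = (n_m, n_r, n_b)` are trinomial. `C = (n_m − n_r)/k` and `M = n_m/k`,
giving signal strengths (peak minus baseline)

    S_C = cρ,
    S_M = (c+1)ρ/2 − ρ²/2,
    S_G(k) = E[[n_m − n_r]⁺]/k (matched) − same (unmatched).

`S_G` is evaluated by exact enumeration over `(n_m, n_r)` pairs in log
space (`O(k²)` terms, `scipy.special.gammaln`), which is exact for every
`k` used here (up to 1024); `S_G(1) = S_M`, `S_G(∞) = [cρ]⁺`. Convergence of
`S_G(k)` to `[cρ]⁺` is *not* monotone from k = 1 for mixed-sign parameter
combinations (distance to the limit can grow between k = 1 and k = 8); the
tests assert monotone decrease from k = 8 onward.

Exact operator distributions come from the binomial marginal (`M`) or the
aggregated trinomial over `(n_m, n_r)` (`C`). The 95% interval convention is
equal-tail on the discrete pmf: each side excludes at most 2.5% mass, so
the enclosed mass is ≥ 95% (highest-density intervals would differ only at
strongly skewed cells).

## Stimuli

Single-pixel-dot RDS: a `34×34` surround with an embedded `32×32` central
square. Per central pixel, independently: dot with probability ρ
(bright/dark equiprobable in the left eye), contrast-matched in the right
eye with probability `(1+c)/2`. Bernoulli placement (rather than a fixed
dot count) makes the trinomial theory exact. The surround is perfectly
correlated (c = +1) at zero disparity and the same density — the standard
fusible-surround convention. Defaults: ρ = 0.25, d_s = −2 px (crossed).

Geometry. Both the embedded square and detector windows split their
horizontal offset symmetrically between the eyes: left x-offset
`(S − C + d)//2`, right offset = left − d. A left-anchored square cannot
host both d = −2 and d = +2 windows inside a 34-pixel image; the symmetric
split accommodates every |d| ≤ S − C while preserving `d = x_L − x_R`. The
near (d = d_s) window then coincides exactly with the embedded square, so
aligned windows sample pure matched-vector statistics and misaligned ones
pure false-match statistics.

Multi-pixel-dot RDS (for the energy model): `24×24` field, `8×8` dots,
`n_dots = round(ρ·area/dot_area)` dots at uniformly random positions, later
dots overwriting earlier ones; per-dot contrast reversal with probability
`(1−c)/2`; whole-field disparity by shifting dot x-positions between the
eyes (±d_s/2 each). Dot x-positions are uniform over the full width with
horizontal wraparound (a toroidal field): wraparound keeps the dot coverage
horizontally stationary, which makes the two eyes' monocular statistics
identical — with edge clipping instead, the near and far energy units see
different monocular energy and the *pure* energy model acquires a spurious
choice bias at c = 0. Vertical positions never clip, so no vertical wrap is
needed.

## Energy detectors

Each unit pools two simple-cell subunits in phase quadrature (carrier
phases 0 and π/2). Receptive fields are vertically oriented Gabors sampled
on the pixel grid: envelope SD 0.05° in both directions, pixel pitch
0.0175°/px, field 24×24 px. The unit's position disparity (±0.14° = ±8 px,
matching the dot size) is split between the eyes. The energy response is
`Σ_phases (⟨RF_L, I_L⟩ + ⟨RF_R, I_R⟩)²`; the binocular interaction removes
the monocular squares, leaving `2 Σ ⟨L⟩⟨R⟩`; the threshold-energy response
half-wave rectifies it.

Two choices are deliberately ours:

- **Carrier frequency** (10 cycles/°, i.e. one cycle per 2 SD of the
  envelope) — any stereo-plausible band-pass choice preserves the
  qualitative behaviour; it is an explicit `GaborParams` field.
- **Amplitude** (8.0) — the reference decision noise for energy detectors
  (σ = 1000) is meaningful only relative to a response unit. The default
  amplitude puts the opponent threshold-energy signal at roughly ±5σ, the
  same signal-to-noise regime the window operators occupy (signal range
  ±0.5 against σ = 0.1). Amplitude rescales responses quadratically, so
  this is a unit choice, not a model change.

## Psychophysics

Near/far 2AFC by opponent decoding: a near detector (window d = −|d_s| or
unit disparity −0.14°) and a far detector (mirror image) view the same
frames; per trial, responses are averaged over 16 independent dot patterns,
differenced (near − far), corrupted by a *single* Gaussian decision-noise
draw (σ = 0.1 for window operators, 1000 for energy detectors), and
thresholded at zero (exact ties: fair coin). Percent correct pools crossed
trials (correct = near) and uncrossed trials (correct = far); each
psychometric point uses 30 + 30 trials × 20 blocks = 1200 trials. The
zero-crossing (correlation at 50% correct) is read off by linear
interpolation between the adjacent bracketing levels.

Expected behaviour follows from the signal strengths: with the matching
detector the expected differential equals `S_M(c, ρ)`, so the curve crosses
chance at `c = ρ − 1` independent of σ, and at full anticorrelation sits at
`100·Φ(−ρ²/2σ)` percent — slightly below chance at ρ = 0.25 (≈ 38% at
σ = 0.1) and progressively lower at higher densities. The correlation
detector's differential is `cρ`, giving an odd-symmetric curve through
(0, 50%).

## Simulation sizes and numerics

- Variability maps: SD of the per-frame differential `C(−2) − C(+2)` (or
  `M`) over 1000 patterns, averaged over 20 runs per grid cell, on the
  21×20 grid c ∈ {−1, −0.9, …, 1} × ρ ∈ {0.05, …, 1} (the grid resolution
  is our choice). The two windows share pixels, so the simulated SD
  includes their covariance naturally. Frame SDs use the n−1 denominator.
- The acceptance script runs that full protocol; the test suite measures
  the same maxima on the coarse subgrid {−1, −0.5, 0, 0.5, 1} ×
  {0.25, 0.5, 0.75, 1} with 5 runs, which contains the maximizing cell
  (c = 0, ρ = 1, where the per-pixel product variance is maximal for both
  codes) and estimates each SD to well under 0.001.
- Tuning curves in tests use 3000 frames; psychometric tests use the full
  1200 trials per point where a published-scale claim is checked and
  200–600 trials for qualitative property checks.
- RNG: a single `numpy.random.Generator` drawn through in a documented
  order (surround, centre pattern, reversal mask) makes every stimulus,
  curve and surface bit-reproducible from its seed.

## What the synthetic stimuli do and do not capture

The generator reproduces the statistical structure the theory is about —
ternary contrast, independent refreshes, graded anticorrelation, an
embedded disparity plane — but not properties of physical displays:
luminance calibration, anti-aliased or sub-pixel disparities, temporal
correlation between frames, vergence noise, or eccentricity-dependent
receptive-field scaling. Passing tests therefore validate the computational
claims (operator identities, closed forms, qualitative psychometric
predictions), not quantitative agreement with any particular human data
set. Known limitations: window-operator tuning curves are piecewise sharp
(no band-pass smoothing by design — that is the energy model's role);
the energy-model carrier/amplitude are conventions as described; and the
decision stage omits lapse rates and any parametric psychometric fit.
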
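# Methods

## Data model

A **spectrum** is a strictly increasing Raman-shift axis (cm⁻¹) with one
intensity per channel in counts/s; a **map** is a set of spectra at unique
physical (x, y) positions in µm (origin lower-left, y up). Maps are stored as
plain text in a long format (`x,y,shift,intensity`) or a matrix format (first
row the axis, one row per point), with 9-significant-digit numbers so files
round-trip exactly. ROIs are axis-aligned rectangles with half-open
membership (`x0 ≤ x < x0+width`), so adjacent tiled ROIs partition a map
without double counting.

## Baseline estimation

The fluorescence background is estimated with a Whittaker smoother under
asymmetric least-squares (AsLS) reweighting. Given intensities `y` and
weights `w`, the smoother minimizes

    Σᵢ wᵢ (yᵢ − zᵢ)² + λ Σᵢ (Δᵈ z)ᵢ²,

a banded symmetric positive-definite system `(W + λ DᵀD) z = W y` solved by
banded Cholesky (`scipy.linalg.solveh_banded`), O(n·d²) per solve. Starting
from unit weights, each iteration assigns weight `p` to channels above the
current baseline and `1 − p` below, until the weights stop changing or
`max_iter` is reached (non-convergence returns the last iterate, flagged in
the spectrum metadata).

Defaults: `λ = 200`, `d = 2`, `p = 0.001`, `max_iter = 20`, `tol = 1e-6`.
λ is treated as a dimensionless penalty weight; the penalty operates on
channel index, which assumes an approximately uniform axis (non-uniform axes
are accepted but penalized by index — a documented limitation). With the
default 1.07 cm⁻¹ spacing the characteristic smoothing scale is a few
channels for retained (below-baseline) points, which lets the baseline track
a broad fluorescence bump while passing under Raman lines of ~10 cm⁻¹ FWHM.

Two behaviours of this estimator matter for interpretation:

* **Lower-envelope bias.** With `p` ≪ 1 the converged baseline sits near the
  lower envelope of the noise, about 2 standard deviations below the local
  background mean, so corrected signal-free channels average ≈ 2·σ_noise
  even before clipping.
* **Rectification.** By default negative channels after subtraction are
  clipped to zero, per spectrum, before any averaging. Together these
  produce a positive intensity floor on signal-free regions — the reason
  "negative" areas still read ≈ 50 cts/s — and the floor, not zero, is the
  correct reference for expression thresholds. When the true baseline is
  known and supplied explicitly (possible via `subtract_baseline(...,
  baseline=...)`), the clipped residuals are exactly rectified Gaussian
  noise: their positive part is half-normal with mean σ·√(2/π), which the
  test suite verifies analytically.

## Quantification

The **band intensity** is the arithmetic mean of intensity over channels
whose centre lies in a closed wavenumber interval, by default 950–960 cm⁻¹
(the main reporter peak). The mean is linear, so the band intensity of an
ROI's mean spectrum equals the mean of its per-point band intensities
exactly; this identity is asserted on every ROI summary.

**Expression classes** use two thresholds on indicative intensity:
`high` strictly above 200 cts/s, `negative` at or below `t_neg`, `low`
between. The low/negative boundary is not sharply defined by the observed
regimes (~100 vs ~50 cts/s); the default `t_neg = 75` is their midpoint and
is configurable.

**Between-ROI testing** is a two-sided two-sample t-test on per-point band
intensities (not per-channel spectra), pooled-variance Student by default
with Welch optional. Degenerate inputs follow conventions: both groups
constant and equal → t = 0, p = 1; constant but unequal → p = 0, flagged.
No multiple-testing correction is applied — reports involve a handful of
pairwise comparisons; users comparing many ROIs should correct externally.

**Calibration** fits `I(C) = floor + I_max·C/(C + K½)`, the simplest
two-parameter monotone saturating (Langmuir-type) response, by bounded
nonlinear least squares (non-negative parameters make the fitted curve
monotone increasing by construction; other monotone forms can be swapped in
at the API level). Initial values come from the blank mean, the intensity
range, and the median positive concentration. Flat series short-circuit to a
degenerate fit with `I_max = 0` and LOD = ∞.

**Limit of detection** uses the conventional k·σ criterion: the threshold is
`mean_blank + k·sd_blank` (k = 3 by default; blank sd from ≥ 2 replicates or
supplied explicitly) and the LOD is the concentration where the fitted curve
crosses it, solved in closed form:

    C* = K½ (T − floor) / (I_max − (T − floor)),

with C* = 0 when the threshold is at or below the fitted floor and ∞ when it
exceeds saturation.

**Signature similarity** is the cosine between a spectrum (linearly
resampled onto the reference axis, zero outside its support) and a
unit-L2-norm reference fingerprint; it is invariant to positive scaling of
either argument.

## Synthetic data

The generator emulates the statistical structure of nanoparticle Raman maps:

* axis 600–1800 cm⁻¹ at 1.07 cm⁻¹ spacing (the instrument-class resolution);
* a nanoparticle fingerprint of Gaussian lines (widths are FWHM, default
  8 cm⁻¹) whose 950 cm⁻¹ line is strictly tallest, scaled so the 950–960
  band mean of the profile is 1 — the response amplitude is then directly
  the clean in-band intensity in cts/s;
* a plastic-substrate signature (main line 1020 cm⁻¹ plus minor lines, one
  at 956 cm⁻¹ inside the band, peak amplitude 100 cts/s ⇒ ≈ 41 cts/s
  in-band), visible where nanoparticle signal is low;
* a broad fluorescence background (constant 300 cts/s + Gaussian bump of
  1200 cts/s, sd 400 cm⁻¹) — large compared to the Raman lines;
* additive Gaussian detector noise, default sd 4 cts/s, with an optional
  Poisson (shot) component that is off by default;
* a saturating response `I_max = 1000` cts/s, `K½ = 170` pM, floor 0.

The noise and substrate defaults were fixed once so that the pipeline's
signal-free floor lands near 50 cts/s (substrate-in-band ≈ 41 plus ≈ 2σ
envelope bias + rectification) and the 3σ LOD of the default dilution series
(blank + 0.1–1000 pM, log-spaced) lands near 1 pM — the operating regime the
package targets. They are configuration, not constants.

**Phantoms** plant labeled regions (rectangles or disks; later regions
overwrite earlier on overlap) on a pixel grid, default pitch 150 × 130 µm so
a 1500 × 900 µm² ROI holds exactly 70 points. Class presets `high`, `low`,
`negative` map to concentrations whose expected measured intensity
(including the ≈ 50 cts/s floor) is ≈ 250, ≈ 100 and ≈ 50 cts/s. Biological
heterogeneity is a smooth lognormal field (cv 0.12, correlation length
300 µm, standardized to mean 1) applied multiplicatively to the nanoparticle
*amplitude* — i.e. to bound-particle surface density — rather than to
concentration, so planted expected intensities are exact under the
saturating response; the per-point concentration recorded in the ground
truth is the response inverse of the modulated amplitude.

Determinism: one integer seed drives everything; per-point noise streams are
seeded by hashing the grid index with the global seed, so identical
configurations produce byte-identical map files regardless of generation
order.

What the generator does **not** emulate: optical effects (focus, depth of
field, tissue scattering and attenuation through skull/skin), cosmic-ray
spikes, detector saturation, wavenumber miscalibration, pharmacokinetics of
probe uptake, and spatially varying fluorescence background. Passing tests
on phantoms therefore demonstrate the correctness and power of the analysis
under the modeled conditions, not instrument-level robustness; in
particular, real tumor data show far larger point-to-point variance (the
phantoms' t-tests are much more significant than real comparisons would be).

## Validation and problem sizes

The test suite checks the banded Whittaker solve against a dense
normal-equations oracle (100 random instances of length ≤ 50, λ ∈ {0, 1,
200, 10⁶}, agreement ≤ 1e-8 relative; λ = 0 returns the input exactly; the
infinite-stiffness limit is verified at λ = 10⁹ on short instances, where
the minimizer coincides with the least-squares line to ≤ 1e-6 — at λ = 10⁶
the exact minimizer still differs from the line by up to ~5% on length-50
instances, which the dense oracle confirms). Pooled t-tests are checked
against a hand-derived example and a textbook implementation to 1e-10;
calibration recovery on noiseless and 5%-cv series; LOD against its
closed-form inversion; and end-to-end discrimination on 50 seeded phantoms
(classification accuracy and rejection rates). The acceptance script uses 50
recovery spectra, 200 noise spectra, 100 noisy calibration series, an
8-replicate dilution series and 10 phantoms — sizes chosen to make the
Monte-Carlo summaries stable at single-percent precision while keeping a
full run in seconds on one core.
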
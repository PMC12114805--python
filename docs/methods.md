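# Methods

## Scope and data model

The package estimates leaf phosphorus content (LPC, mg·g⁻¹ dry mass) from
visible–NIR reflectance spectra sampled at 1 nm from 325 to 1075 nm
(751 bands). The central container, `SpectraSet`, enforces the uniform
1 nm grid because the fractional differencing below assumes a unit step;
reflectance is held as a fraction in [0, 1] and percent-scaled files are
converted at the I/O boundary. This matters only for the difference index
DSI, whose magnitude (but not its correlation with LPC) is scale-dependent;
NDSI and RSI are scale-free.

## Preprocessing

Spectra are smoothed per sample with a Savitzky–Golay filter. The filter
family is standard for reflectance spectra; the window (11 bands) and
polynomial order (2) are package defaults — wide enough to suppress
band-to-band instrument noise, narrow enough to preserve the red edge —
and both are exposed in the configuration. Smoothing can push a deep
valley a hair below zero; outputs are clipped at 0 to preserve the
container invariant.

## Grünwald–Letnikov fractional differentiation

For order v ∈ [0, 2] on a unit grid, the backward G–L difference at band i
is `d^v f(i) = Σ_{m=0}^{i} w_m f(i−m)` with `w₀ = 1` and the recurrence
`w_m = w_{m−1}(m−1−v)/m`, equal to `Γ(m−v)/(m! Γ(−v))` and to the signed
generalized binomial coefficient `(−1)^m C(v, m)`. The recurrence is used
because the direct Gamma ratio overflows for large m; tests cross-check it
against direct Gamma evaluation for m ≤ 10.

Numerical choices:

- **Boundary convention.** The sum runs over the full available history
  (m up to the band index), so the first bands are edge-affected rather
  than dropped; `history_lengths` records the per-band term count and
  downstream consumers may mask early bands if they wish. The alternative
  — dropping a warm-up region — would exclude the blue end, where
  derivative screening can legitimately select bands.
- **Accumulation order.** The sum is accumulated term-by-term in ascending
  m (a shifted-add loop over the weight vector), which makes integer
  orders reproduce the classical first/second difference stencils
  bit-exactly and keeps every band equal to the direct sum evaluated left
  to right. Weights identically zero beyond m = v at integer orders are
  skipped.
- **Order range.** Orders outside [0, 2] are rejected rather than
  extrapolated; the default sweep is 0.0–2.0 in steps of 0.1 (21 orders).
- The discrete composition property holds exactly in this convention:
  applying v = 0.5 twice equals v = 1.0 to floating precision at *all*
  bands, since the weight sequences convolve to the integer-order weights.

## Band screening

Per order, Pearson r is computed between each band and LPC; the screen
reports max |r|, its wavelength (smallest nm on ties), and the count of
bands with |r| above the two-tailed critical value at α = 0.01, computed
exactly from the Student-t quantile: `r_c = t_c/√(n−2+t_c²)` with t_c the
upper α/2 quantile on n−2 df (0.330 at n = 60). No multiple-testing
correction is applied — the count is the conventional raw tally of
significant bands. Bands with zero variance are excluded, not errors.

The best *fractional* order for the model feature set is re-derived from
the screen (highest max |r| among non-integer orders) rather than
hard-coded; a configuration override can pin any order.

## Optimized two-band indices

For each index family (NDSI, DSI, RSI) and each derivative order, every
ordered band pair is scored by the squared Pearson correlation between the
per-sample index values and LPC. Implementation decisions:

- NDSI and DSI values are swap-antisymmetric, so their r² grids are
  symmetric and computed on one triangle then mirrored; RSI is nonlinear
  under swap and scanned in both orientations.
- Derivative "reflectance" can be negative or cross zero, so denominators
  with |·| < 1e−12 yield missing values; a pair with more than 10 %
  missing samples, fewer than 3 complete samples, or zero index variance
  is excluded from the argmax. This prevents spuriously perfect
  correlations from near-singular ratios.
- The argmax tie-break is deterministic: smallest λm, then smallest λn
  (row-major first occurrence).
- The grid stores r²; the signed r of the winning pair is kept alongside.
- No minimum band separation is imposed: adjacent-band pairs are
  legitimate optima for derivative spectra.

The scan is vectorized one row at a time (index of band m against all
other bands, then a column-wise correlation), which keeps the full
751-band scan of one (kind, order) combination well under a second while
agreeing with a nested-loop brute force to 1e−12.

## Split and random-forest model

Samples are split uniformly at random (seeded) into 60 % calibration /
40 % validation — 36/24 at n = 60. Features for one index family are the
index values at each configured order's optimal pair, evaluated on that
order's derivative matrix (four features by default). The regressor is a
random forest with 500 trees, all features per split, unlimited depth, and
a fixed seed; with only four features there is little to tune, and no
hyperparameter search is performed by design.

**R² convention.** The headline R² is the squared Pearson correlation
between predicted and observed LPC within each split — the common
convention in spectral chemometrics, and the one under which validation R²
can exceed calibration R². The residual-based coefficient of
determination (1 − SSE/SST) is computed and stored alongside for readers
who prefer it. RMSE is the root mean squared residual in mg·g⁻¹.

A single seeded split is the default; repeated-split summaries can be
obtained by re-running with different seeds.

## Synthetic data: what it emulates and what it does not

`leaf_model` mode builds each spectrum from named shape constants: a 0.18
visible baseline with Gaussian absorption dips at 460 nm (depth 0.06) and
680 nm (depth 0.08), a 540 nm green peak (height 0.07), a logistic red
edge centered at 715 nm (width 9 nm), and a NIR plateau of amplitude
A = 0.50 + slope·(LPC − mean LPC) clipped to [0.40, 0.60] with a Gaussian
water valley at 960 nm. LPC is uniform on [0.06, 0.12] mg·g⁻¹ by default
(a truncated-normal option, mean 0.090, sd 0.0146, is available). Noise is
independent Gaussian per band (sd 0.01 reflectance by default) plus a ±2 %
per-sample multiplicative brightness factor mimicking canopy-level
illumination variation; both noise sources are disabled together when
`noise_sd = 0` so that noise-free runs are exactly deterministic.

`planted` mode supports parameter recovery. Starting from the leaf model
with the NIR–LPC link off, the signal `δᵢ = slope·(LPCᵢ − mean LPC)` is
split across the two planted bands (+δ/2 and −δ/2), so DSI over the pair
equals δᵢ plus a constant exactly, while any pair sharing only one planted
band carries half the signal — this is what makes the pair identifiable
rather than tied with its neighbors. A smooth per-sample nuisance
component (a random scalar times a parabola whose only zeros are the two
planted bands) gives every *other* pair LPC-uncorrelated variance and
cancels exactly on the planted pair, making it the strict optimum even
without noise. The default slope of 4 index units per mg·g⁻¹ puts the DSI
signal-to-noise ratio at ≈ 5 under the default noise
(4·0.0173 / (√2·0.01)).

What the generator does **not** emulate: radiative-transfer physics
(PROSPECT-class leaf optics), treatment-specific non-monotone NIR
responses observed under extreme phosphorus stress, correlated
(wavelength-smooth) instrument noise, and cultivar structure. Passing
recovery tests therefore demonstrates that the pipeline's inference
machinery is correct and well-seeded, not that real cotton spectra carry a
recoverable phosphorus signal of this strength.

## Problem sizes and determinism

Default analyses use 60 samples × 751 bands, the full 21-order sweep, and
exhaustive 751² pair scans — the full study scale, which runs in seconds.
The pipeline derives per-stage seeds from one global seed (simulation,
split, forest), records sha256 checksums of every stage CSV in the run
manifest, and reruns are checksum-identical.

## Known limitations

- The G–L edge treatment makes the first few bands of high-order
  derivatives depend on short histories; screening near 325 nm at v close
  to 2 should be interpreted cautiously.
- The pair scan's missing-data policy (pairwise-complete, 10 % cap) is a
  pragmatic guard, not an inferential treatment of missingness.
- R²-by-correlation ignores calibration bias; the stored residual-based R²
  and the predictions table allow any alternative metric to be recomputed.
- With four highly collinear features the forest's feature importances are
  not meaningful and are deliberately not reported.
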
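# specphos

Estimation of leaf phosphorus content (LPC, mg·g⁻¹) from hyperspectral leaf
reflectance. The package implements the full chemometric pipeline used to
link visible–NIR reflectance (325–1075 nm at 1 nm) to a leaf nutrient:

1. **Savitzky–Golay smoothing** of each spectrum along the wavelength axis;
2. **Grünwald–Letnikov fractional-order differentiation (FOD)** over the
   order grid v = 0.0, 0.1, …, 2.0, generalizing the first/second
   derivative: `d^v f(x) ≈ Σₘ wₘ f(x−m)` with `w₀ = 1`,
   `wₘ = wₘ₋₁ (m−1−v)/m` (the signed binomial coefficients `(−1)^m C(v,m)`);
3. **Single-band Pearson screening** per order: max |r| against LPC, its
   wavelength, and the number of bands significant at the two-tailed 0.01
   level (exact t-test, `|r|_crit = t_c / √(n−2+t_c²)`);
4. **Optimized two-band spectral indices** — for every ordered band pair
   (λm, λn) the indices
   `NDSI = (R_λm − R_λn)/(R_λm + R_λn)`, `DSI = R_λm − R_λn`,
   `RSI = R_λm / R_λn`
   are scanned exhaustively for the pair maximizing r² with LPC, per index
   family and per derivative order;
5. **Random-forest regression** of LPC from the four per-order optimal
   index values (orders {0, 1, best fractional, 2}), with a seeded 60/40
   calibration/validation split, reporting R² (squared correlation between
   predicted and observed) and RMSE per split.

Because campaign spectra of this kind are rarely deposited, the package
ships a first-class **synthetic generator**: a phenomenological green-leaf
model (blue/red absorption valleys at 460/680 nm, green peak at 540 nm,
logistic red edge near 715 nm, 40–60 % NIR plateau with a 960 nm water
valley, phosphorus-linked plateau amplitude) and a **planted-signal mode**
in which the optimal DSI band pair is known by construction, enabling
parameter-recovery tests of the whole pipeline.

It is written for plant-phenotyping and remote-sensing researchers who work
in Python with numpy/pandas/scikit-learn.

## Worked example

```python
import specphos as sp

# planted-signal spectra: the true optimal DSI pair is (850, 950) nm
s = sp.generate_planted(sp.SynthConfig(mode="planted", seed=1))
res = sp.scan_pairs(s.reflectance, s.lpc, "DSI", s.wavelengths)
print(res.best.lambda_m, res.best.lambda_n, round(res.best_r2, 3))
```

prints

```
850.0 950.0 0.958
```

the exhaustive scan over all 751×750 ordered band pairs recovers the
planted pair exactly, with r² = 0.958 against LPC at the generator's
signal-to-noise ratio of ≈ 5. The `examples/` scripts walk through each
stage (simulation, derivatives, screening, index optimization, modeling,
and the one-command pipeline); `examples/05_lpc_model.py` ends with

```
calibration: R^2 = 0.99  RMSE = 0.0014 mg/g
validation:  R^2 = 0.93  RMSE = 0.0042 mg/g
```

meaning the random forest trained on the 36 calibration samples predicts
the 24 held-out LPC values to within ≈ 0.004 mg·g⁻¹ on a 0.06–0.12 mg·g⁻¹
range.

A thin CLI mirrors the stages:

```bash
specphos simulate --seed 1 --out spectra.csv --lpc-out lpc.csv
specphos run --seed 1 --outdir run1
```

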
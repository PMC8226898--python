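# focusurf

Focused-ultrasound simulation in layered tissue, plus machine-learned
surrogates of the simulator.

High-intensity focused ultrasound (HIFU) treatment planning needs fast
estimates of the acoustic and thermal dose delivered by a phased-array
transducer through a stack of tissue layers. `focusurf` implements the full
physics chain and then replaces it, for repeated queries, with regression
surrogates trained on a parameter sweep of the simulator:

1. **Source plane** — the Rayleigh–Sommerfeld integral radiates the phased
   array (element grid, kerf, per-element focusing phases) onto a plane a
   quarter wavelength from the aperture:
   `p(r) = (jρck / 2π) Σₙ v₀ e^{jφₙ} e^{-jkRₙ} / Rₙ ΔS`.
2. **Propagation** — the angular spectrum method marches that plane through
   the layered stack with a 2D-FFT transfer function
   `H = exp(-jΔz √(k² - kx² - ky²))`, complex wavenumber attenuation
   `k = ω/c - jα` with `α = a₀ f^b` (dB/cm/MHz converted to Np/m), and a
   per-spectral-component pressure transmission coefficient
   `T = 2 Z_b cosθ_in / (Z_b cosθ_in + Z_a cosθ_out)` at each interface
   (Snell refraction; total reflection and evanescent components dropped).
3. **Heating** — acoustic intensity `I = |p|²/(2ρc)` gives the deposited
   power `Q = 2αI`, and the steady-state Pennes bio-heat equation
   `-∇·(k_t ∇T) + W_b C_b (T - T_a) = Q` is solved with a 7-point finite
   difference stencil (direct sparse factorisation or preconditioned CG).
4. **Surrogates** — a sweep over array element counts (x, y) and focal depth
   produces a CSV of focal-zone maxima (pressure, deposited power,
   temperature). Four regressors — linear, CART, SVR, random forest — are
   trained on the min-max-scaled table and compared by pooled RMSE, R²,
   AIC and BIC on a held-out 20% split.

See [docs/methods.md](docs/methods.md) for the model details, numerical
choices and known limitations.

## Worked example

```python
import focusurf as fu

cfg = fu.load_packaged("pancreas_sweep_fast")   # 4-layer stack, 0.5 MHz
res = fu.simulate(cfg, nx=44, ny=40, focus_mm_z=46.0)
print(res.scalars)
# {'max_pressure_pa': 860861.0..., 'max_power_w_m3': 1533158...,
#  'max_temperature_c': 52.607..., 'target_layer': 'pancreas', ...}

df = fu.run_sweep(cfg, "sweep.csv")             # 120 combinations, ~30 s
report, predictors = fu.evaluate_all(df, seed=42)
print(report.to_frame("test"))                  # RMSE / R2 / AIC / BIC per model
print(report.best_model("test"))                # 'random_forest'
```

The same steps from the shell:

```bash
focusurf simulate --config pancreas_sweep_fast --out field.h5
focusurf sweep    --config pancreas_sweep_fast --out sweep.csv
focusurf train    --data sweep.csv --out models/
focusurf evaluate --models models/ --external other_sweep.csv
focusurf validate-scenario --calibrate-peak 6.2
focusurf make-fixture --kind tiny_sweep --seed 0 --out-dir fixtures/
```

Three scenario configs ship with the package: `pancreas_sweep_fast` (coarse
grid, 120-combination sweep, minutes), `pancreas_sweep` (the full
19,227-combination study design; hours) and `prostate_validation` (an
endorectal heating scenario checked semi-quantitatively — see
`examples/03_validation_scenario.py`). Custom scenarios are YAML files with
the same schema (`media`, `stack`, `grid`, `array`, optional `sweep`);
unknown keys are rejected and all units are converted to SI on load.

More narrative walk-throughs live in [examples/](examples/).

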
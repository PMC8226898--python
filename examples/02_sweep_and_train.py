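"""Build a sweep dataset and train the four surrogate models on it.

Runs the packaged 120-combination fast-profile sweep (element counts x
focal depth), then trains linear regression, CART, SVR and a random
forest on the min-max-scaled focal-zone scalars and prints the pooled
RMSE / R^2 / AIC / BIC comparison on the held-out 20% split.

Run:  python examples/02_sweep_and_train.py   (~1 minute on one CPU)
"""

from pathlib import Path
from tempfile import mkdtemp

import focusurf as fu

cfg = fu.load_packaged("pancreas_sweep_fast")
combos = fu.enumerate_sweep(cfg.sweep)
print(f"sweep design: {len(combos)} combinations "
      f"(x {cfg.sweep.x_elements}, y {cfg.sweep.y_elements}, "
      f"focus {cfg.sweep.focus_mm} mm)")

out = Path(mkdtemp()) / "sweep.csv"
df = fu.run_sweep(cfg, out, resume=False)
print(f"dataset written to {out} ({len(df)} rows)")
print(df.head().to_string(index=False))

report, predictors = fu.evaluate_all(df, seed=42)
print("\nheld-out test split:")
print(report.to_frame("test").to_string(index=False))
print(f"\nbest model: {report.best_model('test')}")

# predict an unseen combination with the best surrogate
best = predictors[report.best_model("test")]
x = report.scaler_features.apply(df.iloc[[3]])
y = report.scaler_targets.inverse(best.predict(x))
print(f"surrogate prediction for row 3: pressure {y[0, 0]:.4g} Pa, "
      f"power {y[0, 1]:.4g} W/m^3, temperature {y[0, 2]:.4g} degC")
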
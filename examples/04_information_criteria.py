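"""Information-criterion conventions used by the surrogate comparison.

The package scores every model with a Gaussian pooled-error likelihood:
ln L = -(N/2) (ln(2 pi MSE) + 1), AIC = 2k - 2 ln L and
BIC = k ln N - 2 ln L with k = 3 fitted inputs. Because the two criteria
share the likelihood term, BIC = AIC + k (ln N - 2); `bic_from_aic`
applies that identity, letting a BIC be recovered from a reported AIC
and sample count alone.

Run:  python examples/04_information_criteria.py
"""

import numpy as np

import focusurf as fu

# metrics on a small synthetic prediction set
rng = np.random.default_rng(0)
y_true = rng.uniform(size=(10, 3))
y_pred = y_true + rng.normal(scale=0.1, size=(10, 3))
m = fu.metrics(y_true, y_pred)
print("pooled metrics on 10 rows x 3 targets:")
for key in ("rmse", "r2", "log_likelihood", "aic", "bic"):
    print(f"  {key:15s} {m[key]: .6f}")

# recovering BIC from a reported AIC
print("\nBIC from AIC via the shared likelihood term:")
for aic, n in ((-82.56, 10), (-44164.63, fu.test_split_size(19227))):
    print(f"  AIC {aic:12.2f} at N = {n:5d} -> BIC "
          f"{fu.bic_from_aic(aic, n):12.2f}")
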
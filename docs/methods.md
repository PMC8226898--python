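# Methods

This document records the physical model, the numerical choices and the
conventions `focusurf` commits to, including the places where the
implementation had to choose among ambiguous alternatives.

## 1. Acoustic model

### 1.1 Media and attenuation

Each `Medium` carries density ρ (kg/m³), sound speed c (m/s), an
attenuation coefficient a₀ in dB/cm/MHz^b with power-law exponent b, and
the thermal set (specific heat, conductivity k_t, blood perfusion rate
W_b in kg/m³/s, blood specific heat C_b). Attenuation at frequency f (MHz)
is converted to Nepers per metre as

```
α(f) = a₀ · f^b · 100 / (20 / ln 10)        [Np/m]
```

(100 converts /cm to /m; 20/ln10 ≈ 8.6859 dB per Neper). A nonlinearity
parameter is stored for forward compatibility but unused: the model is
linear time-harmonic.

### 1.2 Source plane (Rayleigh–Sommerfeld)

The rectangular phased array is a grid of `nx × ny` rectangular elements
separated by a kerf; element width is `(aperture − (n−1)·kerf)/n`. Each
element vibrates with normal velocity v₀ and a focusing phase
`φₙ = k·|rₙ − r_focus| mod 2π` referenced to the first (couplant) layer's
sound speed. The pressure radiated into the half-space is the discrete
Rayleigh–Sommerfeld integral

```
p(r) = (jρck / 2π) Σₙ v₀ e^{jφₙ} · e^{−jkRₙ} / Rₙ · ΔSₙ
```

evaluated by midpoint quadrature over sub-sources no wider than λ/4. The
propagator is seeded with this integral evaluated on a plane at
z₀ = λ/4 from the aperture (close enough to capture the near field,
far enough to avoid the R → 0 singularity). A brute-force
`direct_field_oracle` evaluates the same sum at arbitrary 3D points and
serves as the independent reference in the test suite.

### 1.3 Angular-spectrum propagation

The source plane is zero-padded (factor 2 by default) and transformed
with a 2D FFT. Each spectral component (kx, ky) advances over Δz by

```
H = exp(−jΔz √(k² − kx² − ky²))      propagating, kx²+ky² ≤ Re(k)²
H = exp(−Δz √(kx² + ky² − Re(k)²))   evanescent (pure decay)
```

with the complex wavenumber `k = ω/c − jα` carrying attenuation. An
optional separable raised-cosine angular taper (on by default) rolls the
spectrum off between 90% and 100% of the propagating cutoff to suppress
wrap-around aliasing from the periodic FFT; it also zeroes the
evanescent branch, which is negligible beyond the first millimetres.

Layer interfaces are snapped to the nearest plane boundary (the midpoint
between consecutive z-planes); a step that crosses an interface is split
as `H_a(Δz/2) · T · H_b(Δz/2)`. The per-component pressure transmission
coefficient is

```
T(kx, ky) = 2 Z_b cosθ_in / (Z_b cosθ_in + Z_a cosθ_out)
```

with `sinθ_in = k_r / Re(k_a)`, Snell's law `sinθ_out = (c_b/c_a) sinθ_in`,
and Z = ρc. Components past total internal reflection (`sinθ_out > 1`)
and evanescent components are set to T = 0 (the one-way marching scheme
cannot represent reflected energy). A layer split into two identical
sub-layers therefore reproduces the unsplit field exactly, which the
tests assert to 1e−9.

The propagator refuses grids with `dx, dy > λ_min/2` (spatial
undersampling). Fields are inverse-transformed and cropped to the
physical grid at every output plane.

## 2. Thermal model

Acoustic intensity and volumetric heat deposition are

```
I = |p|² / (2ρc),     Q = 2 α I        [W/m³]
```

using the local layer's ρ, c, α. The steady-state Pennes bio-heat
equation

```
−∇·(k_t ∇T) + W_b C_b (T − T_a) = Q
```

is discretised with a 7-point finite-difference stencil; face
conductivities between unlike layers use the harmonic mean. Boundaries
are Dirichlet `T = T_a` (arterial temperature, default 37 °C) — adequate
when the grid extends several perfusion lengths `L = √(k_t / W_b C_b)`
(≈ 7.3 mm for prostate-like tissue) beyond the heated zone. The sparse
SPD system is solved directly (`splu`) up to 60,000 unknowns, above that
with Jacobi-preconditioned conjugate gradients (relative tolerance
1e−10); the assembled operator/factorisation is cached per (stack, grid)
so parameter sweeps pay the setup cost once. The solver is verified
against the perfusion Green's function `e^{−r/L} / (4π k_t r)`.

`contour_width` reports the lateral extent (mm) of the connected region
around the hottest voxel exceeding a given temperature rise, in the x–z
plane through the peak, with sub-cell linear interpolation at the edges.

## 3. Sweep dataset

A sweep varies three inputs — x element count, y element count, focal
depth (mm) — over inclusive ranges, row-major (x outer, focus inner).
Each combination reruns the full chain on a fixed grid/stack and records
the maxima of |p|, Q and T **over the target layer only** (upstream
layers can be hotter near the source; they are not the clinical target).
Rows are written incrementally to CSV with a JSON sidecar carrying the
config hash and package version; interrupted sweeps resume by recomputing
only missing (nx, ny, focus) keys.

The full design (x 16→128 step 4, y 16→64 step 4, focus 25→75 mm step 1)
has 29 × 13 × 51 = 19,227 combinations and takes hours. The packaged
fast profile is this package's own scaled-down choice: a coarser grid at
0.5 MHz and a 5 × 3 × 8 = 120-combination lattice (x step 28, y step 24,
focus step 7) chosen to keep the three axes' relative resolutions close
to the full design's 29:13:51 proportions, so the surrogate comparison
exercises the same anisotropy of the input space.

## 4. Surrogate models and metrics

The dataset is split 80/20 with scikit-learn's `train_test_split`
(test size = ⌈0.2 N⌉); features **and** targets are min-max scaled with
parameters fitted on the training split only (constant columns are
rejected). Four model families are trained on the scaled table:

| model          | settings                                                       |
|----------------|----------------------------------------------------------------|
| linear         | ordinary least squares, 3 targets jointly                      |
| CART           | decision tree, `max_leaf_nodes = 20`                           |
| SVR            | per-target RBF ε-SVR; pressure/temperature C=5, ε=0.1, γ=scale; power C=100, ε=0.1, γ=auto |
| random forest  | 1000 bootstrap trees, fixed seed                               |

`grid_search` offers cross-validated hyperparameter selection (KFold,
fixed seed, ties broken toward the simplest model), but the defaults
above are what `evaluate_all` uses.

Metrics are **pooled over the three scaled targets** (3N residuals):
RMSE, R², and information criteria from the Gaussian likelihood of the
pooled errors,

```
ln L = −(N/2)(ln(2π·MSE) + 1)
AIC  = 2k − 2 ln L
BIC  = k ln N − 2 ln L          (k = 3 fitted inputs, N = rows)
```

so that `BIC − AIC = k (ln N − 2)`; `bic_from_aic` applies this identity.
The BIC definition follows the standard `k ln N` penalty, which is also
the convention consistent with the AIC↔BIC differences in the reference
results this package reproduces (an alternative `2k ln N` form appears
in some write-ups but contradicts those differences). An optional
external dataset can be scored with the training-split scalers; rows
whose (nx, ny, focus) keys overlap the training data are rejected.

## 5. Validation scenario

`prostate_validation` models an endorectal exposure at 2.3 MHz focused
40 mm deep through water / rectal wall / periprostatic tissue / prostate,
with the published property set for those four media. The published
reference heating (≈ 6.2 °C peak rise, ≈ 5–6 mm wide 4 °C contour) cannot
be reproduced absolutely because the source acoustic power and the layer
thicknesses were not reported; the scenario therefore:

- assumes thicknesses 5 / 4 / 6 / 45 mm (documented in the config),
- arranges the 990 elements as 55 × 18 over a 40 × 23 mm² aperture,
- calibrates the source amplitude so the peak steady rise matches a
  requested value (rise is linear in Q, Q quadratic in v₀), and
- reports the 4 °C-contour width, peak depth and the assumption list for
  a semi-quantitative comparison.

## 6. Interpretation choices and known limitations

- **Simulation volume axes.** The reference study quotes an
  80 × 60 × 12 mm³ volume; this package reads it as depth (z) 80 mm,
  lateral x 60 mm, lateral y 12 mm, matching the elongated-aperture
  geometry.
- **One-way propagation.** Reflections, standing waves and mode
  conversion are outside the model; transmission losses enter only
  through T. Total-reflection components are dropped, not reflected.
- **Linear acoustics.** No harmonic generation; at therapeutic focal
  pressures this underestimates local heating.
- **Steady-state thermics.** No transient dose (CEM43) modelling;
  perfusion is the homogeneous Pennes sink, not discrete vasculature.
- **Interface snapping.** Layers thinner than a z-step can vanish from
  the grid; a warning is logged when that happens.
- **Pancreas sweep media.** The fast/full sweep scenarios use a
  couplant/skin/fat/pancreas stack with literature-typical property
  values; they are labelled assumptions in the config comments, not
  published constants.
- **Surrogate validity.** The surrogates interpolate the sweep's input
  box; min-max scaling does not clip, so extrapolated queries are
  returned but untrustworthy.
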
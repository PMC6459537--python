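# Methods

## The model space

A D-part age composition x(t) lives on the unit simplex. The pipeline
compares six ways of removing that constraint before time-series
modelling, crossed with four forecasting families, and selects the
pairing with the lowest out-of-sample compositional error. Components are
always ordered (young, middle, old) = indices 1..3; ILR and DRHT
coordinates depend on this order, so it is a library-wide convention
recorded in every output.

### Transforms

**ILR (pivot coordinates).** w_d = √(d/(d+1)) ln(gm(x₁…x_d)/x_{d+1}).
The inverse expands w to the centred-log-ratio (clr) vector
v_d = Σ_{i=d}^{D−1} w_i/√(i(i+1)) − √((d−1)/d) w_{d−1} (with w₀ = w_D = 0)
and maps back by x = exp(v)/Σ exp(v). A clr vector sums to zero by
construction, so the inverse must be the softmax, not a division by Σv
(which is identically zero); the round-trip identity with the forward map
fixes this choice. ILR is an isometry between Aitchison geometry and
Euclidean ℝ^{D−1}, which the test suite uses as an independent oracle for
both the transform and the distance.

**DRHT.** The forward map operates on y = √x (so Σ y² = 1, a point on the
unit sphere): θ_D = arccos y_D and θ_d = arccos(y_d / Π_{i>d} sin θ_i)
downward to d = 2. Operating on square roots (rather than on x itself) is
forced by the inverse map, which returns squared cosines/sines; only then
are the two maps mutually inverse. arccos arguments are clamped to [0, 1];
when the sine product underflows (all remaining mass zero) the remaining
angles are set to 0 — any value reproduces the composition under the
inverse, so the convention only fixes the representation. Forecasted
angles are clipped into [0, π/2] with a logged count.

**LCC.** D−1 shares are modelled directly; the dropped one is 1 − Σ. The
completed part can leave [0, 1]; such rows are flagged invalid, preserved
raw in outputs, and repaired only at metric time (clip to [ε, 1],
re-close, warn with the year).

**Base.** Each raw share series is fitted directly as a control. Forecast
rows are re-closed (negative parts clipped to ε first). For the VAR
family the D raw columns are exactly collinear (they sum to 1), so the
joint model is fitted on the first D−1 shares and the last is completed
as the complement — equivalent in information and the only non-singular
formulation.

### Error metrics

d_S(x, x̂) = ‖clr(x) − clr(x̂)‖₂ (square root included: it is the
Aitchison distance, and the isometry oracle against ILR coordinates makes
that testable). CoDa-RMSE is implemented as the *mean* of the per-year
distances — the conventional definition in this comparison setting,
despite the name — with a true root-mean-square available behind
`root_mean_square=True`, never the default. CoDa-MAPE divides each
distance by the observation's Aitchison norm ‖x‖_S (distance to the
uniform composition); an exactly uniform observation makes it undefined
and raises, naming the year.

**Zero handling.** Log-ratio operations use multiplicative replacement:
zero parts become ε (default 1e-6, configurable), non-zero parts are
scaled down proportionally, the vector is re-closed, and the replacement
is logged. DRHT tolerates zeros natively.

## Forecasting backends

All backends are deterministic functions of (series, config, seed).

* **ARIMA** — order search over p ≤ 3, d ≤ 2, q ≤ 3 by corrected AIC,
  with the deterministic-trend term the differencing order permits
  (mean for d = 0, drift for d = 1, none for d = 2); fixed orders
  available via config. Candidates that fail to converge are skipped.
* **ETS** — additive-error state space, trend ∈ {none, additive, damped
  additive}, chosen by corrected AIC; annual data, so no seasonality.
* **VAR** — joint least-squares fit on all coordinates, lag order by AIC
  up to `var_max_lag` (default 5). An all-constant matrix forecasts the
  constants; a single constant column raises naming the column.
* **NNETTS** — single-hidden-layer autoregression with logistic
  activation, trained on the standardised series by L-BFGS least squares
  from `restarts` (default 20) seeded uniform(−0.5, 0.5) initialisations;
  the lowest final loss wins, so the loss is non-increasing in the number
  of restarts for a fixed seed. Multi-step forecasts iterate the one-step
  map recursively. Degenerate (zero-variance) series short-circuit to the
  constant for ARIMA/ETS, where the likelihood is otherwise singular.

Default seed 20190411; every stochastic routine takes an explicit seed.

## Selection protocol

The series is split at a calendar year (not an index, so gaps in
ingestion fail loudly): training years ≤ boundary, test years after. For
every transform the NNETTS (m, D_h) pair is first tuned on a
3-lag × 5-hidden-unit sub-grid by CoDa-RMSE on the same held-out window,
and the winner enters the main 6 × 4 comparison. Cell-level failures are
recorded in the report, never raised. The winner is the lexicographic
minimum (CoDa-RMSE, CoDa-MAPE, transform order ILR < DRHT < LCC.Y <
LCC.M < LCC.O < Base, model order ARIMA < ETS < VAR < NNETTS). An
exclusion filter can restrict the candidate set — e.g. to the one-to-one
compositional transforms, the restriction under which the published
Vietnam grid yields ILR+ETS rather than the global minimiser LCC.Y+NNETTS.

Residual diagnostics run on the proportion scale (observed minus fitted
share per component, aligned on the indices all coordinate models can
predict), because that is the scale on which the age groups are reported.
Box–Pierce Q = n Σ r_j² and Ljung–Box Q = n(n+2) Σ r_j²/(n−j) over
h = min(10, ⌊n/5⌋) lags by default (configurable), referred to χ²_h.

The final forecast refits the winning pairing on the full series; the
default horizon is 18 years, overridable.

## Synthetic data: what it does and does not emulate

The generator draws w_t = a + b·t + e_t in ILR space with AR(1) noise
e_t = φ e_{t−1} + ε_t and maps back to the simplex. It emulates the
features the pipeline depends on: smooth monotone-ish share trends,
serial correlation, strict positivity, exact unit sum, 57 annual
observations. It does not emulate structural breaks (policy shocks,
famines), cohort dynamics, or measurement revisions — so passing tests
demonstrate correct mechanics and recoverability under the stated model,
not forecasting skill on real national data. The linear-ILR form was
chosen because the best-performing published pairings are ILR-space
linear-family models, making the generator a fair stress test of the
pipeline's main path; it is scaffolding, not a claim about any country.
Noise starts at e_0 = 0 rather than the stationary distribution, for
exact reproducibility of short series.

Preset parameters (china-like, india-like, vietnam-like) were set by
interpolating plausible 1960/2016 endpoint shares in ILR space — e.g.
china-like runs from roughly (40, 55, 5)% to (17.5, 71.6, 11)% — with
φ = 0.5 and σ ≈ 0.04–0.05 log-ratio units, values at which the trend is
clearly visible but the series is not trivially smooth. They reproduce
the qualitative shapes (steep vs moderate ageing, rising middle share),
nothing more.

`recover_parameters` inverts the generator: per-coordinate OLS of w on t
for (a, b), then a pooled lag-1 regression of the detrended residuals for
φ and the innovation σ. At the default noise level the slope estimates
are unbiased within Monte-Carlo error and mean absolute error < 0.005.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 6 × 4 grid (with the 15-cell
NNETTS sub-grid) on all three presets at n = 57 with the 48/9 split — the
scale of the motivating application; Monte-Carlo checks use 200–1,000
replicates, enough to resolve the tolerances they assert. Round-trip and
isometry identities hold to 1e-10; clr centring to 1e-9; unit-sum
conservation to 1e-9 on forecast paths. NNETTS optimisation caps L-BFGS
at 300 iterations per restart, ample for the ≤ 31-parameter networks the
sub-grid reaches. Ties in model selection break deterministically by the
fixed orders above; ties between NNETTS restarts keep the first minimum.

## Known limitations

* Published error grids are reproduced as fixtures for the selection
  harness; the underlying national share series are not redistributed
  and their vintage is not archived, so cell-by-cell recomputation of
  those grids from raw data is out of scope.
* The untransformed Base path guarantees validity only after re-closure;
  like LCC it can require repair, which is logged.
* ETS automatic selection is restricted to additive error/trend forms —
  multiplicative forms add nothing for shares bounded well inside (0, 1).
* CoDa-MAPE is undefined at exactly uniform observations by construction.
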
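# Methods

## Problem and data model

The package compares parametric growth curves on breed-mean age–weight
trajectories: one body weight (g) per age (days), measured at a small number
of ages. The canonical design is eight observations at 1, 7, 14, 21, 28, 35,
42 and 49 days — the weekly weighing scheme used for meat-duck lines — and
all defaults, fixtures and published reference statistics assume n = 8. Age
is measured in days from hatch; there is no day-0 observation, and two
models (Morgan, Lomolino) are singular at t = 0 and raise a domain error
there rather than returning a limit.

## Functional forms and their restoration

Parameter counts are p = 2 for the negative exponential, p = 4 for Richards
and Weibull, p = 3 for the rest. These counts are not arbitrary: with n = 8
they make the published RMSE, AIC and BIC table cells mutually consistent
(see "Statistic conventions" below), which pins down p per model exactly.

Several published renderings of these equations lose superscripts and
fraction bars, so the package fixes the following readings:

- **Richards** is implemented as a(1 − b e^(−kt))^(−1/m). With the published
  duck parameters (b < 0, m ≈ 0.2) only the −1/m exponent produces day-one
  weights near the actual ~59 g hatch-week weight; the +1/m reading produces
  ~10⁵ g. Negative b makes 1 − b e^(−kt) decrease towards 1 from above, so
  the negative exponent yields a rising sigmoid with asymptote a.
- **Lomolino** uses the standard base-10 form a/(1 + b^(log₁₀(k/t))). Here k
  is the age at which weight reaches a/2, which the initial-guess heuristic
  exploits.
- **Schumacher** and **Morgan** are implemented as printed:
  a b² k (t+b)^(−2) e^(bkt/(t+b)) and a b^k k t^(k−1)/(t^k+b^k)². Both are
  algebraically the first derivatives of sigmoids (a e^(bkt/(t+b)) and the
  Hill curve a t^k/(t^k+b^k)); the published fitted magnitudes (Schumacher
  a ≈ 42, Morgan a ≈ 2.3×10⁵) are only plausible under the derivative-like
  forms, so those are the default. The antiderivative sigmoids remain
  available via `get_model(name, variant="sigmoid")`, and a unit test checks
  the derivative identity linking the two readings.
- The **negative exponential** "a − a e^(−kt)" is simplified to
  a(1 − e^(−kt)); identical algebra.

No positivity constraints are imposed by default: published Brody and
negative-exponential fits to duck data sit at a < 0, k < 0 (the window ends
while growth is still accelerating, so the least-squares optimum is an
exponential-growth branch with no finite plateau), and Richards fits use
b < 0. Optional per-model box bounds can be supplied through `FitConfig`,
which switches the solver to a bounded trust-region method.

`asymptote` returns the t → ∞ limit where finite (a for the saturating
sigmoids, 0 for the derivative-like Schumacher/Morgan humps) and `None` when
the sign pattern makes the curve diverge (k ≤ 0 in the Brody family). The
Weibull parameterisation a − (a−b) e^(−((k−1)/k)(t/IP)^k) has its inflection
exactly at t = IP when k > 1 (set d/dt log y′ = 0), so `ParameterSet`
enforces k > 1 and IP > 0 for it.

## Fitting

Estimation is unweighted nonlinear least squares via damped least squares
(Levenberg–Marquardt, `scipy.optimize.least_squares`, numeric Jacobians).
One solver is used for all ten models; applied studies sometimes mix two
software packages here, and standardising on one is a deliberate design
choice. Tolerances are tight (1e−10 relative on step and cost, 400-iteration
budget) because each problem has ≤ 4 parameters and ≤ a few dozen residuals.

Start values come from a deterministic per-model heuristic: a ← 1.2 × max
observed weight; b solved from the curve's value at the first age against
the first observed weight (clamped); k from a log-linearising first/last
slope (clamped positive — monotone-increasing data always give k > 0);
m ← 0.3; IP ← midpoint of the steepest observed interval; for the
derivative-like Schumacher/Morgan forms, shape guesses (b near the window
scale, k ≈ 0.5 / 2.5) with a solved from the largest observation. Because
the sign-flipped Brody/negative-exponential optima are unreachable by
sign-preserving jitter of a saturating start, `fit` adds one deterministic
exponential-branch start (a = −3 × max weight, k < 0 from the log-slope of
the last observations) whenever the data are still accelerating at the end
of the window. Multi-start then draws `restarts − 1` (default 15)
multiplicative log-normal perturbations (sd 0.5 on the log scale, sign
preserved, seeded; default seed 20250214) cycling over the base starts, and
the lowest-RSS solution wins. Non-finite residuals during optimiser
excursions are replaced by a large finite penalty; a solution touching the
penalty region is discarded. If every start fails, the heuristic start is
returned with `converged=False` — fitting never raises on numerical
difficulty, only on contract violations (n ≤ p, ages in a singular domain).

Standard errors are the asymptotic Jacobian-based estimates
√diag(RSS/(n−p) · (JᵀJ)⁻¹), reported as unavailable when JᵀJ is numerically
singular (condition number > 1e12) — which legitimately happens for the
nearly-unidentified sign-flipped Brody/negative-exponential and Morgan fits.

## Statistic conventions

- adjusted R² = 1 − ((n−1)/(n−p))(1−R²), R² = 1 − RSS/TSS.
- RMSE = √(RSS/(n−p)). Some applied papers print n−p−1 in the formula while
  their tables are computed with n−p; reconstructing published AIC/BIC cells
  from published RMSE cells via RSS = RMSE²·(n−p) reproduces them to the
  printed precision, while n−p−1 matches nothing, so n−p is the default and
  `ddof="n-p-1"` gives the literal variant.
- AIC = n ln RSS + 2p and BIC = n ln(RSS/n) + p ln n. The asymmetry (RSS vs
  RSS/n inside the log) is intentional: it is the pairing that reproduces
  the published comparison tables. The two differ by the model-independent
  constant n ln n, so rankings are unaffected. Four published BIC cells
  (Lomolino and Weibull, both breeds) are inconsistent with this
  reconstruction — plausibly computed by a second software package — and are
  excluded from the internal-consistency tests; every other cell reproduces
  within ±0.1 (the rounding of the printed RMSE).
- Durbin–Watson = Σ(eₜ−eₜ₋₁)²/Σeₜ² on residuals in age order, reported
  descriptively with bands dw ≤ 1.5 "positive", dw > 2.5 "negative",
  otherwise "none". The band edges are the unique simple thresholds that
  reproduce the published classification of all ten Danish-line fits
  (boundary case: DW = 1.50 is called positive, hence ≤). No significance
  testing is attempted — n = 8 is far below tabulated critical values.
- Ranking is ascending AIC with ties broken by BIC, then RMSE, then name;
  the published tables never need a tie-break, but a deterministic rule is
  required for a reproducible report. Failed fits rank last and are flagged.
- A perfect fit (RSS = 0) sends both criteria to −∞; it ranks first and its
  RMSE is reported as 0.

## AGR analysis

The AGR profile evaluates the analytic derivative on a regular grid, default
1–49 days step 0.1 (the observation window). The peak is the closed-form
inflection when the model has one inside the window, otherwise a bounded
scalar maximisation; a peak on the window edge (monotone AGR, e.g. Brody
with k > 0) is flagged `boundary_peak` rather than treated as an inflection.
Peak age is additionally reported rounded half-up to a whole day, the
convention behind statements like "growth peaks at day 23": 23.41 → 23,
23.96 → 24.

## Synthetic data

The generator emulates the study design, not individual birds: one weight
per age, weight(age) = curve(age) + noise. Defaults are the Gompertz curve
with the bundled Danish parameters, the eight weekly ages, and additive
Gaussian noise with sd 20 g — chosen as a plausible between-replicate scale
for breed-mean weights spanning 50–2200 g (about 1% of the asymptote);
proportional noise (cv, default 5% when used) is available because weight
variance plausibly grows with age. Negative draws are clipped to 0.1 g with
a warning (disable `clip_negative` when deliberately simulating from
sign-flipped curves whose early values are negative). What passing tests on
these data do **not** show: robustness to individual-bird variance
structure, sex or line effects, serially correlated measurement error, or
unbalanced designs — none of which the generator models.

`recovery_experiment` runs the standard simulate-refit loop and reports
per-parameter bias, relative RMSE and median |relative error|, plus how
often the RSS-form AIC ranks the generating model first among a candidate
set. At the default noise level, 200 replicates select the generating
Gompertz model over logistic and Brody in ≈99% of replicates with median
asymptote error ≈2% — problem sizes chosen so the full suite (including
this loop) runs in about two minutes.

## Pipeline

`read_dataset` accepts tidy CSV/TSV (`age_days`, `weight_g`, optional
`group`; dialect by extension) and reports malformed rows with line numbers.
`run_comparison` writes, per group: a parameters table (estimate (SE),
4 significant digits), the statistics × models table (2 decimals, 4 for
adjusted R²) with a full-precision JSON sidecar, a ranking file with a
best-model verdict, per-model predicted curves at whole-day ages over the
observed range, the best model's AGR profile and peak summary, and a run
log (seed, solver settings, convergence flags, variant switches). All
floats are written at fixed precision so reruns with the same seed are
byte-identical. Exit codes: 0 all fits converged, 3 partial convergence or
per-model errors, 1 input error.

## Known limitations

- Single-trajectory fits only: no mixed effects, no bootstrap or profile
  confidence intervals; the asymptotic SEs are unreliable exactly where the
  fits are ill-conditioned (and are then reported as unavailable).
- Whether the "as printed" or antiderivative reading of Schumacher/Morgan
  is biologically intended cannot be settled without raw data; both are
  implemented, and conclusions about those two models depend on the choice.
- The multi-start scheme is tuned for ≤ 4-parameter curves on ≤ dozens of
  points; it is not a global optimiser for harder problems.
- With n = 8 and p = 4 the information criteria rest on 4 residual degrees
  of freedom; small-sample corrections (AICc) are deliberately out of scope
  to keep the statistic suite exactly comparable with the published tables.
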
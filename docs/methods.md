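# Methods

## Model

The relaxivity of dissolved oxygen in a simple fluid is modelled as

    r1Ox(B0, T) = C1 / (1 + C2 * B0^2) + C3 + CTemp * T

with r1Ox in 10⁻⁴ s⁻¹/mmHg, B0 in tesla and T in °C. The functional
form follows the nuclear magnetic relaxation dispersion of water
protons relaxed by the oxygen electron spin: the paramagnetic
contribution to R1 is Lorentzian in the electron Larmor frequency, and
since r1Ox is proportional to that contribution, its field dependence
inherits the same shape with re-scaled constants. The microscopic
dispersion parameters (electron-nuclear correlation time, amplitude)
are deliberately not modelled — the four constants are purely
empirical. C1 is the amplitude of the dispersive component, C2 (T⁻²)
sets the knee field 1/√C2, C3 is a field-independent floor, and CTemp
a linear temperature slope. Temperature enters additively and linearly;
over the calibrated 21–40 °C range no curvature is resolvable from the
available data.

Assumptions worth stating explicitly:

* a single pooled model covers water, saline, vitreous fluid and blood
  plasma — material differences (proteins slightly depress relaxivity)
  are absorbed into the residual scatter because no material has enough
  (B0, T) coverage to support its own fit;
* blood and tissue are out of scope: deoxyhemoglobin, cells and lipids
  change the R1–pO2 relationship qualitatively, and such records (the
  schema supports `blood`/`tissue` labels) are excluded from the
  default fit set;
* validity is limited to the calibrated ranges B0 ∈ [0.011, 8.45] T and
  T ∈ [21, 40] °C. Evaluation outside them is permitted but warns
  (`CalibrationRangeWarning`); below ~0.01 T the true dispersion of
  oxygen-like paramagnets is expected to turn back down toward zero,
  which the Lorentzian plateau cannot represent.

The linear R1/pO2 relation `R1 = R1,0 + r1Ox * pO2` uses SI s⁻¹/mmHg;
model constants stay on the 10⁻⁴ scale so the optimizer works with O(1)
quantities. Conversion between the scales is the explicit pair
`relaxivity_to_si` / `relaxivity_from_si`, never implicit.

## Bundled dataset and the one correction applied

The package ships 28 curated literature measurements
(`oxyrelax/data/table1.csv`): 7 saline, 18 water, 1 vitreous fluid,
2 plasma, spanning 0.011–8.45 T and 21–40 °C. Two records (Kramer et
al.) did not report temperature; they carry `temperature_assumed=true`
(37 °C) so sensitivity re-runs can drop them. The CSV reproduces the
source compilation verbatim, including one row that is internally
inconsistent as printed: the Graf series entry "3.89 at 0.159 T" breaks
the series' otherwise monotone dispersion (6.60 at 0.137 T, 6.13 at
0.259 T) and sits out of the series' increasing-field row ordering,
between the 0.713 T and 2.139 T rows. Reading the field as 1.059 T — a
digit transposition — restores both the monotone dispersion and the row
ordering, and is the only reading under which the published calibration
constants and agreement statistics are reproducible from the table
(as printed, the fitted C1 lands outside its own published confidence
interval and the full-data MSE roughly doubles). The correction is
therefore treated as an erratum: recorded in `TABLE1_ERRATA`, flagged
in the row's `comments` field, applied by `load_table1(corrected=True)`
(the default for fitting and for the acceptance pipeline), and fully
reversible with `corrected=False` / the CLI `--as-printed` flag.

## Fitting pipeline

One fit is a bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`) of the active parameters on the
10⁻⁴ scale, minimizing the unweighted residual sum of squares over all
records (the sources report no per-measurement uncertainties, so
weighting is not attempted). Defaults:

| setting | value | rationale |
|---|---|---|
| initial guess | (5, 1, 1, 0.01) | order-of-magnitude start near the plateau/knee of the data |
| bounds | C1 ∈ [0, 100], C2 ∈ [0, 100], C3 ∈ [−10, 10], CTemp ∈ [−1, 1] | non-negative amplitude/width keep the dispersion physically decreasing; others loose |
| ftol/xtol | 1e-10 | fits are cheap; run to tight convergence |
| multi-start | 1 (option `n_starts`, jittered ×U(0.5,2)) | the 4-parameter loss is well behaved on these data; jittered restarts are a guard for harder user datasets |

The calibration repeats this fit `n_iterations = 1000` times, each time
on a shuffled train subset of 90% of the records
(`sklearn.model_selection.train_test_split`; with 28 records the ceil
rule gives a 25/3 train/test split). Iteration k uses split seed
`(master_seed + k) mod 2^31`, making every iteration individually
reproducible and the whole ensemble bit-identical across runs with the
same master seed. Convergence failures are dropped and counted (never
imputed); more than 50% failures aborts. The final parameters are the
per-parameter medians of the ensemble; the 95% confidence intervals are
the empirical 2.5/97.5 percentiles with numpy's linear interpolation.
Percentile CIs were chosen over a Gaussian approximation because the
ensemble distributions are mildly skewed (C2 especially); this choice
can shift CI endpoints by a few percent relative to other conventions.
Each iteration also predicts its 3 held-out records with its own fitted
parameters; pooling the 3 × n_iterations pairs gives the out-of-sample
agreement estimate.

## Model selection

Eight nested variants are enumerated: every subset of {C2, C3, CTemp}
may be fixed at zero while C1 is always retained (dropping C2 collapses
the Lorentzian to a constant; dropping all three leaves a flat
one-parameter model). Each variant runs through the identical
resampling pipeline, and its AIC uses the Gaussian least-squares form

    AIC = n * ln(RSS/n) + 2k,

lower is better, with RSS evaluated on the full dataset at the
variant's ensemble-median parameters — matching how the final model's
headline R²/MSE are computed from the substituted medians. The report
also carries a `score = −AIC` column (so "higher score = better model"
phrasing maps onto it) and the small-sample AICc (n = 28 is small);
ranking claims are made on AIC. On the bundled data the full model
ranks first, drop-C3 second, drop-CTemp third.

## Agreement statistics

R² is the squared Pearson correlation between modelled and measured
values — the R² of the simple linear regression one would annotate on
an agreement scatter plot. It is invariant to affine rescaling and
blind to calibration offsets; `r_squared_identity` (1 − RSS/TSS about
the identity line) is computed alongside for when calibration itself is
the question. MSE is the plain mean squared difference on the 10⁻⁴
scale. Bland–Altman statistics use differences d = modelled − measured:
bias = mean(d), limits of agreement = bias ± 1.96·SD(d) with the sample
(n−1) SD (configurable to the population convention; at n = 28 the
difference is ~2%). Subsets with fewer than 3 pairs (e.g. the single
vitreous record) get a partial report with R² suppressed rather than a
meaningless correlation.

## Synthetic data

`oxyrelax.synthetic` draws datasets from the model surface itself at a
chosen design — by default the 28 (B0, T) points of the bundled
compilation — plus additive homoscedastic Gaussian noise,
`noise_sd = 0.4` on the 10⁻⁴ scale by default. That value makes the
synthetic residual scatter comparable to the literature fit's
(full-data MSE ≈ 0.18 implies residual SD ≈ 0.43); it is a testing
convention, not a measurement-error estimate. The generator emulates
exactly what the fit assumes — independent, identically distributed
errors on the table scale — and none of what real compilations contain:
inter-laboratory systematics, digitization error, material effects,
heteroscedasticity. Recovery tests on synthetic data therefore verify
the pipeline's correctness, not the model's real-world accuracy.

A related caution, quantified during development: the resampling CIs
describe the spread of refits on 90% subsamples of one fixed dataset.
They are systematically narrower than the sampling spread of the
estimator across independent datasets at the same noise level — at
noise_sd = 0.4 on the 28-point design, the asymptotic standard error
of C1 (≈ 0.24) exceeds the half-width of its subsample CI (≈ 0.17).
Subsample CIs from small datasets should not be read as frequentist
coverage intervals.

## Numerical and degenerate-input choices

* Fits with no more records than active parameters raise immediately
  (underdetermined).
* A measured R1 below the zero-oxygen baseline inverts to a negative
  pO2, returned unclamped with a `NegativePO2Warning` — clamping would
  hide the inconsistency.
* `aic(rss=0, ...)` returns −∞ (perfect interpolation is outside the
  criterion's Gaussian derivation) rather than raising.
* Pressure conversions are exact rational factors via mmHg
  (760 mmHg = 1 atm = 101.325 kPa; Torr ≡ mmHg), round-tripping to
  1e-12 relative.
* Temperature is °C throughout; kelvin is converted at the boundary
  (CLI `--kelvin`, `kelvin_to_celsius`).

## Problem sizes

The bundled calibration (1000 iterations × 25-point fits) runs in a few
seconds on one CPU; the eight-variant AIC comparison at the same
iteration count in well under a minute. The test suite uses
100-iteration ensembles for recovery properties (medians agree with the
1000-iteration values well within tolerance) and the full 1000
iterations wherever a published statistic is being reproduced.

## Known limitations

* One pooled model for four materials; saline agreement (R² ≈ 0.74) is
  visibly worse than water (R² ≈ 0.94).
* No extrapolation guarantee outside 0.011–8.45 T / 21–40 °C, and a
  known qualitative failure below ~0.01 T.
* Unweighted least squares; all records count equally regardless of
  source quality or era.
* The blood/tissue literature values mentioned by the source
  compilation's supplement are not bundled; the schema accepts them as
  user data but the model does not apply to them.
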
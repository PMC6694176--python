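# Methods

This note records the models implemented in `nestrisk`, the assumptions and
numerical choices behind them, and what the synthetic-data tests do and do
not establish about real monitoring data.

## Exposure model

A nesting female is assumed to contact every gram of soil she excavates.
Chronic soil exposure is `excavated_volume × bulk_density`
(25.19 cm³ × 1.33 g/cm³ ≈ 33.5 g over the ~30-day construction and
provisioning of one five-cell nest); acute (48 h) exposure divides the
chronic amount by 15, the ratio of the two windows. Larval pollen ingestion
is `single-grain mass × grains per provision`, with the grain mass measured
as anther pollen mass over grain count (0.0302 g / 18 438 ≈ 1.64 × 10⁻⁶ g).
Adult pollen contact is `cells_per_nest × provision`. Adult nectar ingestion
converts a daily sugar demand (10.4 mg/day, a honey-bee forager value)
through the nectar sugar content into nectar mass; the published "40% sugar"
figure is nominally by volume, but we implement it as a mass fraction — the
choice that reproduces the conventional 780 mg / 30 d figure — and expose it
as the `nectar_sugar_fraction` parameter for users who prefer a density
correction upstream.

Deliberately not modelled: larval nectar ingestion (no reliable amounts
exist), larval soil contact (nest cells carry a water-resistant lining), and
males (they neither excavate nor provision). Exposure amounts are kept at
full floating precision internally; figures like "33.5 g" or "0.0542 g" are
report-time rounding. Note the conventional printed product 33.51 g differs
from 25.19 × 1.33 = 33.5027 in its last digit; downstream arithmetic uses
the unrounded product.

All parameters are plain dataclass fields with the defaults above, validated
strictly positive, and overridable through the YAML pipeline configuration.

## Hazard-quotient screen

`HQ = concentration × exposure / endpoint`, summed over analytes within
pesticide class, matrix and life stage. Route selection is structural:
contact endpoints for soil and adult pollen handling, oral endpoints for
nectar and larval pollen ingestion. Design choices:

- The hazard flag fires at HQ ≥ 1 (boundary included, conservative).
- Non-detects and below-LOQ residues enter the deterministic screen as zero
  dose; their information is used properly only by the censored likelihood.
- The solitary-bee surrogate endpoint is the honey-bee value / 10, the
  standard safety factor for untested species; when not tabulated explicitly
  it derives from the honey-bee geometric-mean endpoint.
- Endpoints reported as ">x" (e.g. chlorantraniliprole) are used at x, so
  their HQs are conservative upper bounds.
- Packaged endpoint and mean-concentration tables carry a `note` column
  marking cells that are typographically ambiguous in the source material;
  those individual cells should not be treated as reference-grade, though
  their contribution to the soil totals is negligible either way.
- "Lowest" honey-bee endpoints are supported by the API but not shipped:
  the per-source endpoint lists behind them are not published.

Report formatting follows the field convention: two decimals at or above
0.01, scientific notation below.

## Censored maximum likelihood and family selection

Each observation contributes `log f(x)` (quantified), `log F(LOD)`
(non-detect, left-censored on (0, LOD)), or `log[F(LOQ) − F(LOD)]`
(detected below LOQ, interval-censored). Non-detects are treated as genuine
left-censored draws from the concentration distribution, not as structural
zeros; a zero-inflated mixture is out of scope.

Numerics: optimization is Nelder-Mead in transformed parameter space (log
for positive parameters; the log-normal location is unconstrained), with
moment-based starting values computed on censoring-midpoint-imputed data and
two perturbed restarts on failure. Zero-probability regions return a large
negative sentinel rather than −∞ so the simplex keeps moving.
Non-convergence raises, never passes silently. Where the MLE has a closed
form and no censoring is present (log-normal, exponential), the default
`auto` path uses it; `method="numeric"` forces optimization (the two agree
to ~1e-6, and a test asserts it). Likelihood kernels are written directly
against `scipy.special` primitives so bootstrap refits are cheap.

Families: log-normal (μ, σ), gamma (shape, rate), Weibull (shape, scale),
exponential (rate). Selection minimizes AIC = 2k − 2ℓ; ties (within 1e-9)
break toward fewer parameters, then the fixed order above. On exponential
data the gamma fit's AIC beats the exponential's on roughly the expected
~16% of draws (the likelihood-ratio gain exceeding 1 is a χ²₁ tail event);
tests assert the majority behaviour, not a per-draw certainty.

Minimum-data rule: fitting refuses datasets with fewer than 2 observations
or with **no fully quantified observation**. A dataset containing only
censoring bounds (even interval ones) is reported as "not assessed",
mirroring how monitoring studies handle compounds never measured above the
LOQ; with one interval row and the rest non-detects the likelihood is too
weakly identified to defend a fit. Fits with fewer than 5
quantified-or-interval rows proceed with a warning.

## Bootstrap and exceedance

Uncertainty is a nonparametric bootstrap: censored observation records are
resampled with replacement (keeping their censoring status) and refitted,
warm-started from the full-data MLE; 1000 iterations by default. Replicates
whose resample has no quantified row, or whose refit fails, are dropped and
counted; more than 50% failures marks the fit with a warning. Parameter and
exceedance intervals are 2.5/97.5 percentile bounds. The published EED
figures show 95% bands without stating their propagation; we evaluate
1 − F(benchmark) at every parameter replicate and take pointwise percentile
bounds — on the CDF, not on parameters — and note the ambiguity here.

Exceedance of a benchmark B (= endpoint / soil amount, per scenario) is
`1 − F(B/T)` for translocation fraction T; dividing the benchmark by T is
mathematically identical to multiplying all concentrations by T and avoids
refitting per scenario. Default T grid: 10/25/50/75/100%. Risk is
acceptable when exceedance < 5% (configurable), the conventional 95%
population-protection criterion. Empirical plotting positions are Hazen's
(i − 0.5)/n with censored observations ranked at their interval midpoint
(non-detects at LOD/2).

The pipeline seed deterministically derives per-analyte bootstrap streams
via `numpy` seed sequences, so reruns with the same inputs are
byte-identical regardless of analyte count or ordering.

## Synthetic data generator

The generator emulates composite residue monitoring samples: i.i.d. draws
from a log-normal or gamma concentration distribution, reported as
quantified (≥ LOQ), detected-below-LOQ ([LOD, LOQ)) or non-detect (< LOD).
Presets reproduce the published scenario shapes — sample sizes and detection
frequencies — by fixing σ = 1.0 and solving the log-normal μ from
`P(X ≥ LOD) = detection frequency`. The fittable presets use LOQ = LOD so
every detection is quantified, keeping them fittable at n = 29 the way the
corresponding compounds were in the study; the `cucurbita_thiamethoxam`
preset places the LOQ far above the concentration range so detections are
never quantifiable and fitting must refuse. Preset seeds are fixed and
explicit.

What the generator does **not** emulate: farm-level spatial correlation
(samples are i.i.d., real ones are composited per farm), the true
*Cucurbita* LOD/LOQ values (unpublished; the public field-crop LOD of
0.05 ng/g stands in, flagged in preset metadata), and the published
concentration magnitudes (with σ and the LOD fixed there is no free
parameter left to also match the quantified-value geometric means).
Consequently, passing pipeline tests demonstrate correctness of the
machinery under study-shaped censoring — not reproduction of the published
exceedance percentages, which would require the undeposited datasets.

## Problem sizes used in the test suite

Simulation-based checks run at: parameter recovery over 50 seeds at
n ∈ {29, 40, 60, 82} with 20–90% censoring (median mean relative parameter
error asserted < 25%); bootstrap coverage of the exponential rate over 200
outer simulations of n = 100 with 300 replicates each (coverage asserted
within 95 ± 5%); family-selection consistency at n = 500–1000; and the full
preset pipeline at the default 1000 bootstrap iterations, run twice to
assert byte-identical output.

## Known limitations

- Contact with soil is equated to the full residue dose in the contacted
  mass, scaled only by the translocation fraction; no dermal-uptake kinetics.
- Honey-bee endpoints proxy solitary-bee sensitivity; the /10 surrogate is a
  safety factor, not a measured species difference.
- Single-compound assessment only; no mixture toxicity beyond HQ addition,
  no sublethal endpoints, no pharmacokinetic accumulation modelling.
- Right-censored observations are representable in the data model but no
  monitoring pathway produces them here.
- MLE only; Kaplan–Meier or regression-on-order-statistics nonparametric
  estimators for censored data are out of scope.
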
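# Methods

## Scope and data model

The package analyzes the standard computational chain of a preclinical
radioimmunotherapy (RIT) experiment: in-vitro radioligand assays, in-vivo
biodistribution with an imaging surrogate nuclide, tumor absorbed-dose
estimation for the therapeutic β⁻ conjugate, and treatment-outcome
classification. All stages operate on plain CSV/JSON and on small frozen
dataclasses (`Nuclide`, `BiodistributionTable`, `TimeActivityCurve`,
`AbsorbedDoseResult`, `GrowthRecord`), validated at construction.

Time is carried in hours internally; day-indexed inputs convert as
day × 24 exactly. Built-in nuclide records: ⁹⁰Y (T½ = 64.1 h, mean β energy
0.9331 MeV; maximum energy 2.3 MeV and 11.3 mm water range are stored as
annotation only), ¹¹¹In (67.31 h) and ¹²⁵I (59.4 d) as γ-emitting labels
without a β dose. The registry is overridable from the run configuration;
surrogate half-lives never enter the dose chain because biodistribution
tables are decay-corrected by convention.

## Binding assays

**Lindmo immunoreactive fraction.** The bound fraction bf(c) at cell number c
is linearized as y = 1/bf against x = 1/c; the regression
y = 1/r + (K/r)·x extrapolates to infinite antigen excess, giving
r = 1/intercept with a delta-method standard error. The reciprocal transform
inflates variance at low bound fractions under multiplicative noise, so the
default regression is weighted by bf² (unweighted available). A non-positive
intercept raises a fit failure rather than returning a meaningless r;
r > 1 is returned but flagged.

**Homologous competition.** The model B(c) = NS + (B₀ − NS)/(1 + c/IC50) is
fitted by bounded least squares (B₀, NS ≥ 0; IC50 ∈ (10⁻⁶, 10⁴] nM) from six
log-spaced IC50 starts, keeping the best residual sum of squares. Because
labeled and unlabeled ligand are the same antibody, Kd = IC50 − L where L is
the hot-ligand concentration; both IC50 and the corrected Kd are reported so
users preferring a heterologous correction can apply their own. When
IC50 ≤ L (possible on noisy curves) Kd is floored at 10⁻⁶ nM and flagged.
Curves whose top concentration is below 10 × IC50 are flagged for missing
the lower plateau.

**Internalization.** Compartment counts (internalized, membrane-bound,
medium protein-bound, medium free) are reduced to fractions of their
per-time-point sum; a zero total raises an error naming the time point. No
kinetic rates are fitted — rate constants exist only in the generator.

## Biodistribution

%ID/g = 100 × counts / (injected standard × tissue weight), divided by the
physical decay factor over the counting delay, then multiplied by
body weight / 20 g. The normalization direction (lighter animals adjusted
downward) follows common usage; the reference weight is configurable.
Animals are normalized individually and then aggregated per (tissue, day)
cell as mean ± sample SD (n − 1 denominator). Tumor-to-blood ratios divide
cell means; the body-weight normalization cancels. The two packaged tables
carry the printed values verbatim (10 tissues × days 1, 2, 4, 7, 10, n = 5).

## Dosimetry

The tumor time–activity curve measured with the surrogate is assumed to
describe the therapeutic conjugate's biological kinetics exactly (identical
antibody, identical chelate). The chain:

1. multiply each decay-corrected value by e^(−λt) of the therapeutic nuclide
   (a guard refuses to decay an already-physical curve twice);
2. trapezoidal integration over [0, t_last] with a prepended (0, 0) anchor —
   no activity in the tumor at the moment of injection — and no extrapolated
   tail beyond the last measurement (a deliberate truncation: the omitted
   tail of a 64 h nuclide beyond day 10 is small and the convention matches
   how such uptake windows are reported);
3. unit conversion (%ID/g)·day → s/kg: × 86 400 (day → s) × 10
   (percent → fraction ÷ 100, per g → per kg × 1000);
4. D [Gy] = A₀ [Bq] × AUC [s/kg] × Δ [Gy·kg/(Bq·s)], Δ = E̅β·1.60218×10⁻¹⁹ J/eV.

Self-dose only: complete local β absorption, no escape correction for small
tumors, no cross-dose, no organ S-values. Phantom-based red-marrow dosimetry
is out of scope; reports carry a literature annotation instead. The
zero-anchor and the integration window are configurable flags; the defaults
are the documented convention.

## Treatment outcomes

Tumor volume is w × h × d / 2 (mm³), symmetric in the three calipers.
Responses are classified per animal on ≥ 3 time points:

* **complete_regression** — volume ≤ 1 mm³ (the operational "disappeared"
  threshold) at some day ≥ 7 and still ≤ 1 mm³ at the end of observation
  (day 28 default);
* **regression_with_regrowth** — reached the threshold but later exceeded
  2 × threshold (regrowth factor, configurable);
* **progression** — final volume above baseline and never below baseline;
* **growth_delay** — everything else (transient or net shrinkage without
  disappearance).

The thresholds formalize qualitative descriptions ("completely disappeared",
"started to increase again") and rescale consistently: scaling volumes and
thresholds together leaves labels unchanged. Arm summaries report mean
relative volume (volume / day-0 volume) per day; an animal's measurements
after its first volume > 200 mm³ (humane endpoint) are censored out, with
per-day n reported. The minimal curative dose is the smallest arm dose whose
animals achieved complete regression allowing k exceptions (default k = 1);
arms above the threshold that fail the criterion are listed as violations,
so a non-monotone dose–response is visible rather than hidden.

Apoptosis quantification reduces TUNEL field counts (≥ 5 fields at 400×) to
per-field positive fractions, summarized as mean ± SD per arm with a Welch
two-sample t comparison offered descriptively. Repeated-measures ANOVA of
growth curves is deliberately not reimplemented — it is routine statistics
available elsewhere; the package emits the descriptive per-day summaries
such a test would consume.

## Synthetic-data generators

All generators take a `numpy.random.Generator` or integer seed and are
deterministic given (truth, seed). Noise models: unit-mean multiplicative
lognormal (exp(σZ − σ²/2), σ² = ln(1 + CV²)) for assay signals and %ID/g —
strictly positive and unbiased in the mean, CV 0.1 default for
biodistribution cohorts of n = 5 — and Poisson/binomial for field counts.

* **Binding**: bf(c) = r·cK/(1 + cK), saturating to the true immunoreactive
  fraction; 8 log-spaced cell numbers spanning 10⁵–10⁸ by default.
* **Competition**: one-site homologous curve with IC50 = Kd + [hot].
* **Internalization**: three-rate compartment model — membrane → internalized
  (k_int), membrane → medium protein-bound (k_off, dissociation),
  internalized → medium free (k_release, catabolite release) — solved in
  closed form from an all-membrane initial state. Residualizing (metal
  label) preset k_int = 0.07, k_off = 0.05, k_release = 0 /h puts ~53% of
  activity in the internalized pool at 20 h, inside the 45–65% band typical
  of residualizing anti-c-kit conjugates; the non-residualizing (iodine)
  preset adds k_release = 0.7 /h, placing the interior maximum of the
  internalized fraction near 3 h with gradual loss to the medium thereafter.
* **Biodistribution**: per-tissue sum-of-exponentials c(t) = ΣAᵢe^(−λᵢt) with
  closed-form AUC (biological, and physical after adding the therapeutic
  decay constant), sampled per animal with lognormal noise and converted back
  to gamma-counter counts so the %ID/g computation round-trips exactly.
  The "12A8-like" and "67A2-like" tumor presets were fitted once by bounded
  least squares to the packaged tumor rows and frozen:
  A(e^(−λ₁t) − e^(−λ₂t)) with A = 29.588 %ID/g, λ₁ = 0.0941, λ₂ = 0.5583 /day
  and A = 91.323, λ₁ = 0.1734, λ₂ = 0.4146 /day respectively — both peak
  near day 4 as the tables do. Blood is a single exponential through the
  day-1 and day-10 printed values.
* **Treatment cohorts**: v(t) = v₀·exp((g − κD)t) during the radiation-effect
  window, resuming rate g afterwards. Calibration, chosen once from the
  study conditions: baseline volume 4.4 ± 3.2 mm³ truncated at 1.5 mm³ (an
  enrolled tumor must be measurable, i.e. above the 1 mm³ detectability
  threshold); g = 0.14 /day so an average untreated tumor passes the 200 mm³
  endpoint within the 28-day window; κ = 0.01447 /(Gy·day) with a 14-day
  effect window, placing the regression boundary (minimum volume reaching
  1 mm³, v₀ = 4.4: (κD − g)·14 = ln 4.4) at D = 17 Gy — between the arms
  observed to regress completely (≥ 18 Gy) and those that only slowed
  (≤ 10.5 Gy), with disappearance around two weeks. Tumors driven below the
  threshold regrow with probability e^(−(D−14)/2.5) (≈ 0.2 at 18 Gy,
  ≈ 0.06 at 21 Gy, ≈ 0 at 36 Gy); sustained regressions keep shrinking.
  Ground-truth labels come from this regime algebra (sign of g − κD, the
  minimum volume, the regrowth draw and its day-28 projection), not from the
  classifier, so label agreement is a genuine closed-loop check; it is exact
  only at zero noise. Body weight shows a transient dip (≤ 15% at high dose)
  recovering within the first week — descriptive only.

What the generators do **not** emulate: receptor saturation and
protein-dose effects, inter-animal correlation, measurement-day jitter,
cold-antibody pharmacology (the growth delay seen under unlabeled IgG), and
organ-specific uptake beyond simple exponentials. Passing closed-loop tests
therefore demonstrates correctness of the estimators under the stated noise
model, not robustness to every feature of real cohort data.

## Numerical choices and problem sizes

* Trapezoid quadrature is exact for piecewise-linear curves sampled at their
  knots; against the generator's smooth biexponential it converges as h².
  The noisy closed-loop dosimetry test uses a 0.05-day sampling grid, where
  the quadrature offset is an order of magnitude below the Monte-Carlo
  standard error of a 200-replicate mean, so the 3-SE comparison isolates
  noise propagation; quadrature convergence is checked separately on a dense
  grid at 1%. The published 5-point schedule (days 1, 2, 4, 7, 10) is tested
  against its own trapezoid reference.
* Replicate counts: 200 for parameter-recovery and dosimetry loops (seconds
  of runtime), 5 animals per day/arm matching the study design.
* Fits: competition fitting is bounded Levenberg–Marquardt/TRF via
  `scipy.optimize.curve_fit` from six deterministic log-spaced starts; the
  Lindmo fit is closed-form weighted least squares. No randomness enters any
  fit, so reports are reproducible byte-for-byte.
* The 67A2 doses recomputed from the packaged (printed, rounded) table sit
  ≈ 4–5% below the originally reported 7.2/18.0/35.9 Gy; the original
  unrounded data are unavailable, and the package documents 5% as the
  agreement tolerance for that arm (12A8 agrees within 1%).

## Known limitations

Self-dose approximation overestimates absorbed dose for tumors small
relative to the β range; no tail extrapolation slightly underestimates AUC;
the homologous-competition Kd assumes equal affinity of labeled and
unlabeled antibody; response classification depends on the operational
1 mm³ / factor-2 thresholds where the underlying reports are qualitative;
the growth generator's exponential-kill model has no radiobiological
dose-rate structure (no LQ/TCP).
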
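# Methods

This note documents the models implemented in `metalrisk`, the defaults
shipped in `src/metalrisk/data/reference_library.yaml`, the design choices
made where conventions genuinely diverge in the literature, and what the
synthetic-data validation does and does not demonstrate.

## Data model

A survey is a `ConcentrationTable`: a sites × elements matrix of mean
concentrations for one medium (water, µg/L; sediment, mg/kg), optionally
with a matching standard-deviation matrix. SDs are parsed from the
`mean±sd` cell dialect and retained for provenance, but every index operates
on means — the indices in this field are defined on central values, and
propagating measurement SDs through them is out of scope. All values must
be finite and non-negative; duplicate site or element labels are rejected at
construction.

The `ReferenceLibrary` holds, per element: maximum admissible
concentrations for three regulatory sets (a national industrial-effluent
standard, the WHO drinking-water guideline, and the USEPA drinking-water
set), the average-shale crustal background, sediment screening benchmarks
(TRV, TEL), the Hakanson toxic-response factor, pathway-specific reference
doses and slope factors, and the dermal permeability coefficient. Every
entry is overridable from a user YAML file; nothing is hard-coded in logic.

Two deliberate departures from the bundled survey's printed reference rows:

* **Cadmium background = 0.3 mg/kg** (the Turekian–Wedepohl crustal value).
  The survey's own table prints 0.03, but all of its published cadmium
  enrichment factors (32.02, 30.48, 30.61, 37.02, 8.46) reproduce only with
  0.3 — the printed 0.03 is a decimal slip.
* **Cadmium toxic-response factor = 40.** With the otherwise standard
  extended Hakanson set (Hg 40, As 10, Pb/Cu/Ni/Co 5, Cr/V 2, Mn 1) this
  reproduces the survey's published ecological-risk values to better than
  1% and its site ordering exactly; the more commonly quoted Cd factor of
  30 does not. Se and Be have no established factor and are excluded from
  PER by default, with a logged notice.

## Water indices

`HPI` uses the common simplification `k = 1` and ideal values `Iᵢ = 0`, so
`Wᵢ = 1/Sᵢ` and `Qᵢ = 100·Cᵢ/Sᵢ`; a single element at its standard scores
exactly 100. Both `k` and the ideal values are configurable. `HEI` and
`C_d` are plain ratio sums, so they are additive over elements — the test
suite exploits this as an oracle. Elements without a standard in the chosen
limit set are dropped per site rather than imputed. The default limit set
for the bundled survey is the national industrial-effluent standard, the
set under which the survey's published conclusions (all HPI < 10, all
HEI < 1) hold; the WHO set would push the Mn-dominated site over 1.

Class bands: HPI < 15 low, 15–30 medium, > 30 high; HEI < 10 low, 10–20
medium, > 20 significant; HEI < 1 additionally "fit for domestic use".

## Sediment indices

`Igeo` uses the conventional 1.5 background multiplier; a zero concentration
is reported as −∞ with the "uncontaminated" class and a logged note rather
than raising. `EF` normalises to a conservative reference element — Mn
here, configurable — and is exactly 1 for the reference element itself.
`PLI` is the geometric mean of the contamination factors and is undefined
when any CF is zero; the error message says which element to exclude.
`PER` bands follow the usage of comparable surveys: low < 110, moderate
110–200, considerable 200–400, very high ≥ 400 (the original Hakanson low
cut of 150 would relabel two published "moderate" sites). USEPA sediment
screening classes cover Pb, Cu, As, Cd, Ni and Mn only; Cd has a published
"heavily polluted" cut (> 6 mg/kg) but no lower band, so everything below
is "non-polluted".

## Deterministic health risk

Chronic daily intake per pathway, with concentration converted µg/L → mg/L:

* ingestion `C·IR·EF·ED/(BW·AT)`
* dermal `C·SA·Kp·ET·EF·ED·CF/(BW·AT)`, `CF = 10⁻³ L/cm³`
* inhalation `C·IR_inh·EF·ED/(K·BW·AT)`, `K` a dimensionless volatilization
  attenuation constant (default 1000) for the water-to-air pathway; the
  functional form of this pathway varies across surface-water studies, so it
  is both configurable and switchable off by passing a reduced pathway tuple.

Exposure defaults (YAML, overridable): adults drink 2.2 L/day at 70 kg for
70 years; children 0.78 L/day at 15 kg for 6 years (the USEPA RAGS child
drinking-water default — larger literature values for child intake drive
the arsenic hazard quotient above 1, which contradicts the screening-level
character of these defaults). Skin areas 18,000 / 6,600 cm², exposure
times 0.58 / 1.0 h/day, exposure frequency 365 d/y. The non-carcinogenic
averaging time is ED·365 per cohort. The carcinogenic averaging time is
also ED·365 per cohort rather than a fixed 70-year lifetime: lifetime
averaging makes adult cancer risk dominate child risk purely through the
longer exposure duration, whereas intake-per-kilogram — the quantity these
cohort comparisons are meant to rank — is higher for children. RfD, SF and
Kp defaults are an IRIS-style compilation shipped as data; dermal values
are GI-absorption-adjusted where published, and inhalation values fall back
to the ingestion dose when no pathway-specific value exists.

Carcinogenic risk is computed for As, Pb, Cd, Cr and Ni (the elements with
a compiled slope factor); requesting it for any other element is an explicit
error, not a silent zero.

These parameter tables are screening defaults, not a claim about any one
study's unpublished parameter set, so the package pins the *behaviour* of
this stage — linearity in concentration, HI/TCR additivity, child > adult
orderings, all-HQ-below-1 on the bundled survey — rather than exact HQ/CR
magnitudes.

## Probabilistic risk

The Monte Carlo stage takes a TCR arithmetic mean and SD and fits the unique
log-normal with those moments in closed form (`σ² = ln(1+CV²)`,
`μ = ln m − σ²/2`), rather than fitting logs of data — matching the
single-point-deposition practice of probabilistic screening studies.
Draws come from numpy's seeded PCG64 generator; percentiles use numpy's
default linear interpolation between order statistics (at n = 10,000 the
estimator choice shifts results far below tolerance). Analytic quantiles
`exp(μ + σΦ⁻¹(p))` serve as the exact oracle; simulated percentiles are
tested against them at three standard errors of the order-statistic
estimator. Exceedance is the plain fraction of draws above a configurable
threshold; no published exceedance percentage is targeted because the
moment-matched distribution implied by the bundled survey's own percentiles
puts essentially zero mass above 10⁻⁶ (its printed 0.5%/0.3% figures are
internally inconsistent with its percentiles).

## Source statistics

Pearson p-values come from the two-tailed t transform on n−2 degrees of
freedom; constant columns yield missing correlations with a logged warning
rather than an error. PCA is an eigendecomposition of the element
correlation matrix (no rotation; rotation is a deliberate non-feature since
the reproduced variance fractions are unrotated), with component signs fixed
so each component's largest-magnitude loading is positive. Ward clustering
uses scipy's linkage on the site profiles. The default is **no
standardization**: that is the common statistical-package default under
which the bundled survey's published water clusters reproduce exactly, and
it is what makes the high-Mn outfall a singleton; `standardize=True`
z-scores each element first for surveys where scale should not dominate.

## Synthetic surveys

The generator draws log-normal concentrations through a Gaussian copula:
a block-structured correlation matrix (validated positive-definite by
Cholesky before sampling), per-element log-mean/log-sd, and optional
multiplicative site-cluster offsets. It emulates the three features the
analysis stages assume — positivity with right skew, correlated element
groups (shared sources), and clustered site profiles — and returns the
ground truth (target correlation, cluster labels) beside the table.

It does **not** emulate censoring at detection limits, spatial
autocorrelation, seasonal structure, or measurement error correlated across
elements; passing recovery tests therefore demonstrates statistical
correctness of the estimators, not robustness to those real-data features.
Validation sizes were chosen for tight sampling error at interactive cost:
1000 sites for null-correlation and moment recovery, 500 for block
correlation, 100 replicates × 100 sites for the planted-block PCA recovery
check.

## Known limitations

* The bundled survey's published sediment dendrogram and part of its
  sediment correlation table involve elements absent from its published
  concentration table; those outputs are not reproducible from the bundled
  data and are not targeted.
* The published pollution-load-index range is likewise not reproducible
  from the published table under any background set tried; PLI is pinned by
  its geometric-mean invariants instead.
* Dermal and inhalation dose forms are the simple screening variants; no
  event-based dermal absorbed-dose model (DAevent) is implemented.
* Water indices treat elements independently; no speciation or
  bioavailability correction.
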
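# Methods

## Scope and model

`pahrisk` estimates the *excess lifetime cancer risk* — the incremental
probability, beyond background, of developing cancer over a 70-year
lifetime — attributable to PAH exposure via inadvertent soil ingestion and
inhalation. The model is the standard regulatory intake equation: chronic
daily intake averaged over the lifetime, multiplied by a linear, no-threshold
dose-response slope. Its assumptions are the usual screening-level ones:

- carcinogenic potency of a PAH mixture is additive across analytes after
  PEF weighting (no interaction, no mixture-specific potency);
- the dose-response is linear through the origin (CSF for ingestion, IUR
  for inhalation), appropriate for the low doses screened here;
- exposure factors are constant within a receptor's lifetime; the averaging
  time AT equals 365·ED days (ingestion) or 24·365·ED hours (inhalation),
  so ED cancels and the time weighting reduces to EF/365 (resp. ET·EF per
  year over the annual hour count);
- the dermal route and age-stratified (child) receptors are out of scope.

## Parameters, units, defaults

| symbol | meaning | unit | default | rationale |
|---|---|---|---|---|
| Cs | BaP-equivalent soil concentration | mg/kg d.w. | — | measured; API accepts ng/g and divides by 1000 |
| IR | soil ingestion rate | mg/d | — | tracer-study population: 95th pct 361, 90th 152, median 37; regulatory adult default 20 |
| CF | mass conversion | kg/mg | 1e-6 | unit bookkeeping |
| EF | exposure frequency | d/yr | 365 | 153 models May–September-only exposure in a boreal climate |
| ED | exposure duration | yr | 70 | lifetime risk |
| BW | body weight | kg | 80 | current adult regulatory default |
| AT | averaging time | d | 25550 | 365 × 70 |
| CSF | oral cancer slope factor (BaP) | (mg/kg·d)⁻¹ | 7.3 | Health Canada; OEHHA's 2.9 available as a parameter |
| CA | BaP-equivalent air concentration | mg/m³ | — | API accepts µg/m³ (÷1e3) and ng/m³ (÷1e6) |
| ET | exposure time | h/d | 24 | continuous residence |
| AT (inh.) | averaging time | h | 613200 | 24 × 365 × 70 |
| IUR | inhalation unit risk (BaP) | (mg/m³)⁻¹ | 0.0033 | Health Canada |

Risks are flagged against 1e-5 (primary negligibility threshold) and 1e-6
(the stricter screening convention); both are configurable.

## BaP equivalency

`bap_equivalent` is an exactly-rounded (fsum) weighted sum over *detected*
analytes; non-detects contribute zero. This matches how the bundled panel's
total-PAH rows were computed and avoids imputation; half-detection-limit
substitution is available on the CSV reader (`nd_substitute`) for
sensitivity checks but is deliberately not a default. Analyte names are
canonicalised (case, brackets, hyphens, benzo/benz variants) before any
join.

Two published PEF schemes ship with the package: the Nisbet & LaGoy (1992)
TEFs (default) and the CalEPA/OEHHA (1994) PEFs. The bundled soil panel's
printed BaP-equivalent row is treated as the authoritative input for all
downstream stages: under both shipped schemes the weighted sum of the
printed analyte rows falls systematically short of the printed equivalents
(the originating laboratory's own PEF assignments are not public), so
recomputation is exposed as a diagnostic, never substituted for the printed
column. Downstream results are therefore independent of the PEF choice.

## Site summaries and the distance regression

Summaries use the sample SD (n−1) and the even-n median convention of
averaging the two central order statistics (this yields 1.95 ng/g on the
bundled panel; the published rounded value is 2.00). The distance
relationship is ordinary least squares of the *untransformed* BaP-equivalent
concentration on distance to the nearest extraction pad, with the slope
tested by F = r²(n−2)/(1−r²) on (1, n−2) df; untransformed OLS reproduces
the published F(1,16) = 1.73 on the bundled panel. Degenerate input (all
distances equal) is an error, not a silent NaN.

## Threshold inversion

Because the dose equation is linear in Cs, the concentration producing a
target risk is `Cs* = target · BW · AT / (IR · CF · EF · ED · CSF)` —
exact to floating precision, with the round-trip
`ingestion_risk(threshold_concentration(t)) = t` enforced by property test
at 1e-12 relative. Threshold concentrations are rounded to whole ng/g only
at report time.

## Monte Carlo

- **Lognormal parameterisation.** Input tables state arithmetic mean/SD, so
  the sampler moment-matches: σ² = ln(1 + (s/m)²), µ = ln m − σ²/2. The
  product-of-means identity (for independent inputs with fixed denominators)
  gives an analytic expectation used both as a cross-check in tests and as
  the reference for acceptance bands.
- **Determinism.** Variables are sampled in a fixed order (Cs, IR, EF, ED,
  BW, AT, CSF) from a single `numpy` Generator seeded explicitly; identical
  spec + seed reproduces draws bit-for-bit. There is no time-based seeding.
- **Estimators.** Percentiles are linear-interpolation empirical quantiles
  (numpy's default); exceedance probabilities are strict-inequality
  fractions. Single-run Monte Carlo statistics are stochastic, so tests
  compare the mean against the analytic value within 4 Monte Carlo standard
  errors (SE estimated from the draw variance) rather than asserting a
  specific run's value.
- **Independence.** Inputs are sampled independently; no correlation
  structure (copula) is modelled, and neither Latin hypercube sampling nor
  two-dimensional (variability/uncertainty) Monte Carlo is in scope.
- **Sensitivity.** Spearman rank correlation between each varying input's
  draws and the risk draws, average ranks for ties, ranking by |ρ|.
  Zero-variance inputs are excluded with a warning (a fixed factor cannot
  drive output variation); fewer than two varying inputs is an error. For
  the bundled sensitivity scenario EF is taken uniform on (153, 365) — the
  seasonal-to-year-round range — since only that range, not a distribution,
  is stated; accordingly only the rank order (IR > Cs > EF) and coarse
  magnitudes are asserted.

## Synthetic data

The site generator draws BaP-equivalent totals from a moment-matched
lognormal (defaults: arithmetic mean 15.70, SD 29.67 ng/g — the bundled
panel's structure), adds an optional linear distance effect over distances
uniform on 0.1–34 km, and can decompose each total into per-analyte
concentrations such that the PEF-weighted sum reconstructs it exactly
(infeasible if a mass-carrying analyte has PEF 0). Totals are generated on
the BaP-equivalent scale because that is the scale the inferential chain
consumes. The population generator draws ingestion rates from a lognormal
(defaults 52/119 mg/d, the measured population's arithmetic moments).

What the generators deliberately do *not* emulate: spatial autocorrelation,
censoring/detection limits, correlated analyte profiles, or seasonal
variation in ingestion rates. Passing tests therefore demonstrate that the
pipeline recovers known parameters under the assumed (lognormal,
independent) structure — not that real fields satisfy those assumptions.

## Numerical and reporting conventions

- Risks are reported at 3 significant figures; report tables round decimal
  half-up (so e.g. a computed 7.095e-10 prints as 7.10E-10, matching
  printed-table convention, while the raw double is preserved everywhere
  else).
- Published comparison values that were themselves computed from rounded
  printed concentrations are matched at 1–2% relative tolerance; values
  computable from exact inputs are matched at 3-s.f. precision.
- Problem sizes in the test suite: 10,000-trial Monte Carlo runs (the
  assessment's own convention), 1e5–1e6-draw sampler checks, 100-seed null
  regression simulations, 300-permutation uniformity checks — all chosen to
  keep the suite a few seconds while leaving Monte Carlo bands several
  standard errors wide.

## Known limitations

- The PEF shortfall against the bundled panel's printed equivalents is
  unresolved; users supplying their own panels should supply the PEF table
  actually used by their laboratory.
- Only the two shipped distribution families (plus point masses) are
  supported for Monte Carlo inputs.
- The incidence contextualisation (`incidence_context`) rounds to whole
  cases per 100,000, which makes any risk below ~5e-6 invisible by
  construction; that is the point of the comparison, but it is not a
  substitute for the risk value itself.
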
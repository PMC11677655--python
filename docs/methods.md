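# Methods

This note records the models implemented, the defaults chosen where the
design was open, and what the synthetic generators do and do not
emulate.

## Headspace model

The gas phase in equilibrium with the liquid oil is treated as an ideal
(Raoult) solution: partial pressure `p_i = γ_i x_i P_vap,i` with all
activity coefficients `γ_i = 1` by default (a per-compound map can be
supplied, since liquid-phase non-idealities are real but unmodeled
here). Mole fractions come from GC area percentages treated as
mass-proportional, `x_i ∝ area_i / M_i`. Conversion to mass
concentration uses the ideal-gas law, `C_i = p_i M_i / (R T)` with
R = 8.314 J/(mol·K), reported in mg/m³ — the unit odor thresholds are
tabulated in; measured series in µg/mL convert at the boundary
(1 µg/mL = 1000 mg/m³). Default temperature is 298.15 K (experiments at
25 °C); the property registry carries one temperature tag per file.

This approximation ranks compounds by volatility-weighted abundance.
It ignores transport (no diffusion modeling along a sampling tube — 
measured per-port series are ingested as data) and liquid-phase
interactions, so predicted concentrations are indicative, not
quantitative.

## Odor values and the radar

`OV_i = C_i / ODT_i`. Compounds without a tabulated threshold cannot be
scored; they are excluded before scoring via a dedicated signal and
logged individually — an absent threshold is never treated as zero.
Family ranks come from the registry (primary first, up to three, fixed
vocabulary of eight families); rank weights are 100%, 70/30 and
60/30/10. Weights sum to 1 per compound, so the family total conserves
the compound total. Normalization to unit sum makes profiles
scale-invariant: rescaling all concentrations by any λ > 0 leaves the
radar unchanged. An all-zero profile is returned flagged degenerate
rather than raised, except where coordinates are requested. Ties in
the dominant family are reported as a tie list.

"Expressive" compounds are selected by a configurable minimum share of
the summed odor value (default 0.1%); trace contributors are dropped
before radar construction and logged. One caveat is worth recording:
under the vapor-pressure approximation applied to the packaged oil
tables, the retained set is {α-pinene, β-pinene, limonene,
Z-β-ocimene} — Z-β-ocimene's very low threshold (0.010 mg/m³) gives it
a large predicted odor value, while β-caryophyllene (threshold
1.5 mg/m³, vapor pressure 4 Pa) falls under the default cut. A radar
built from *measured* headspace, where Z-β-ocimene appears only in
traces, selects a different four-compound set. Both routes are
provided; the woody dominance of the profile is robust to the choice.

## Release kinetics

The power law `M_t/M_∞ = k t^n` is fitted by minimizing the
linear-space SSE with the Nelder–Mead simplex over `(ln k, ln n)` — the
log-parameterization enforces positivity without constraints. The
initial point is the log–log OLS line; on noiseless power-law data the
simplex solution coincides with that closed form, which the tests use
as an independent oracle. Optimizer defaults: 2000 iterations max,
absolute SSE tolerance 1e-10, deterministic for fixed input.

Usable points require t > 0 and 0 < fraction < 1; saturated points are
excluded by default (model validity), and an optional cap restricts the
fit to fractions ≤ 0.6 (the classical early-release validity window),
off by default. When the normalizing asymptote M_∞ is not supplied, it
is plateau-estimated as the mean of the longest trailing window (≥ 3
points) whose relative spread is below 2%; its provenance (supplied vs
plateau-estimated) is recorded on the curve.

Goodness of fit: `SSE`, `R² = 1 − SSE/SST`,
`R²_adj = 1 − (1−R²)(N−1)/(N−p−1)`, `RMSE = sqrt(SSE/N)` (divisor
configurable to N−p). The standard adjusted-R² definition necessarily
satisfies `R²_adj ≤ R²`; published tables that print the opposite
ordering must have used a different, unstated formula, and are not
reproduced.

Mechanism classification depends only on (n, geometry, tolerance).
Reference exponents: sphere 0.43/0.85 (Fickian/Case II), cylinder
0.45/0.89, slab 0.50/1.00. Bands are strict: |n − n_ref| < tol (default
tol = 0.02) labels the reference mechanism, and band edges fall in the
neighbouring class — so an exponent exactly at reference + tolerance
reads as anomalous transport rather than pure diffusion, which matches
how fitted exponents near but off the Fickian value are interpreted in
the controlled-release literature. Below the Fickian band:
quasi-Fickian/combined; between bands: anomalous (non-Fickian); above
the Case II band: super Case II.

## Assay formulas

* `EE% = 100 (m_if − m_uf)/m_i0`. A non-detected filtrate mass is
  treated as 0 and the result flagged as a lower bound (everything
  recovered in suspension was encapsulated). `m_uf > m_if` yields a
  flagged negative EE with a warning, not an exception.
* `%SR = 100 (A_control − A_sample)/A_control`; the control absorbance
  must be positive.
* `CV% = 100 σ/|μ|`. The absolute value keeps CVs positive for
  sign-carrying quantities (zeta potential). When mean ± sd are
  supplied directly, sd is used as given; computed from replicates, the
  sample convention applies.
* Calibration is OLS with intercept by default; a through-origin flag
  exists. Quantification inverts the line and flags extrapolation
  beyond the fitted range.

Stored values are never rounded; two-decimal rounding is display-only.

## Synthetic data

The generators reproduce the statistical structure of the study's
inputs, at its conditions:

* **Release**: `min(1, k t^n (1+ε))`, ε ~ N(0, σ²) i.i.d.
  (multiplicative, emulating relative GC quantification error).
  Defaults: k = 0.0234 min⁻ⁿ, n = 0.45 (the pure-oil fit), 20
  log-spaced points over 1–2000 min, σ = 0.02.
* **Composition**: Dirichlet draw with α = c·p centered on the packaged
  table's proportions, rescaled to its total so identified/unidentified
  bookkeeping is preserved. Default concentration c = 500 makes the
  per-compound spread comparable to the printed triplicate standard
  deviations (tenths of an area point for mid-sized peaks, a couple of
  points for the major ones).
* **DPPH**: saturating exponential
  `%SR(t) = SR_∞ − (SR_∞ − SR_0)e^(−rt)` with additive noise, inverted
  to absorbance pairs at unit control. Defaults SR_0 = 4.5%,
  SR_∞ = 80%, r = 0.15/day, sampled every 5 days for a month — the
  free-oil time course shape.

One integer seed drives everything; each generator derives a named
stream (seed-sequence spawn keyed per operation), so results are
independent of call order. The generators do not model spatial
transport (port-to-port attenuation), compound-specific release
differences, or instrument drift — passing tests demonstrate correct
arithmetic and estimator behavior under the assumed noise models, not
validity of those models for any particular instrument.

## Problem sizes and numerical choices

Parameter-recovery checks use 50 seeded replicates of 20-point curves;
the full suite runs in a few seconds. Hypothesis property tests are
derandomized with 50 examples each. Degenerate inputs (all-zero areas,
constant fractions, zero variance) raise typed errors rather than
returning NaNs; the all-zero radar is the one flagged-not-raised case,
since an odorless sample is a meaningful measurement outcome.

## Known limitations

* The ideal-solution headspace ignores activity coefficients by
  default; for oxygenated/terpene mixtures deviations can be large.
* Odor thresholds span orders of magnitude across literature sources;
  radar shapes are sensitive to the threshold table used.
* The power law is only valid for the early release fraction; fits
  including near-saturation points estimate an effective, not
  mechanistic, exponent (hence the default exclusion of saturated
  points).
* No peak detection or chromatogram integration: inputs are integrated
  areas. pH series are ingested as plain time series only.
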
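# Methods

## Scope and model family

The package treats microbial growth on an oily carbon source as a static
relation μ(C₀) between the specific growth rate μ (h⁻¹) and the initial
carbon concentration C₀ (g of elemental carbon per litre). Nine classical
substrate-inhibition models are implemented:

| model | μ(C₀) | parameters |
|---|---|---|
| Monod | μmax·C₀/(Ks+C₀) | μmax, Ks |
| Andrews | μmax·C₀/((Ks+C₀)(1+C₀/Ki)) | μmax, Ks, Ki |
| Aiba | μmax·C₀/(Ks+C₀)·e^(−C₀/Ki) | μmax, Ks, Ki |
| Haldane | μmax·C₀/(Ks+C₀+C₀²/Ki) | μmax, Ks, Ki |
| Han–Levenspiel | μmax·C₀(1−C₀/Cmax)ⁿ/(C₀+Ks(1−C₀/Cmax)ᵐ) | μmax, Ks, Cmax, n, m |
| Luong | μmax·C₀/(Ks+C₀)·(1−C₀/Cmax)ⁿ | μmax, Ks, Cmax, n |
| Moser | μmax·C₀ⁿ/(Ksⁿ+C₀ⁿ) | μmax, Ks, n |
| Webb | μmax·C₀(1+C₀/K)/(Ks+C₀+C₀²/Ki) | μmax, Ks, Ki, K |
| Yano | μmax·C₀/(Ks+C₀+(C₀²/Ki)(1+C₀/K)) | μmax, Ks, Ki, K |

The Haldane form used here is the standard one with denominator
Ks + C₀ + C₀²/Ki, which nests Monod as Ki → ∞ and has the closed-form
maximizer C* = √(Ks·Ki); a circulating variant writes Cmax/Ki in the
denominator, which collapses to a shifted Monod and is treated as a
transcription error, not implemented.

All model domains are carbon concentrations. Oil-mass domains (what a
practitioner weighs out) are reached only through the composition-based
conversions in the chemistry module, never by scaling model parameters.

### Numerical contracts

- **Cutoff clamping.** For Han–Levenspiel and Luong the factor (1−C₀/Cmax)
  is clamped at 0 before exponentiation, so non-integer exponents never see
  a negative base; μ ≡ 0 for C₀ ≥ Cmax by definition.
- **Degenerate bases.** Moser with C₀ = 0 returns 0 for any n > 0 (0⁰ never
  evaluated); Han–Levenspiel at C₀ ≥ Cmax short-circuits to 0 regardless of
  n, m.
- **Peak finding** brackets the maximum on a 101-point grid over (0, U]
  (U = Cmax where the model has one) and refines with bounded scalar
  minimization to |ΔC₀| ≤ 10⁻⁴ g/L. The two-stage search exists because the
  fitted optima are extremely flat — a single local search from an
  arbitrary start can stall on the plateau. Correctness is checked against
  a 10⁵-point brute-force grid across randomized parameter draws.
- **Webb's μ can exceed μmax** (its numerator carries 1+C₀/K); the bound
  μ ≤ μmax is asserted for the other eight models only. Webb is unimodal
  exactly when K > Ki, otherwise monotone; the unimodality test allows at
  most one sign change of the discrete differences.

## Specific growth rate from endpoint OD

μ = ln(OD_end/OD_start)/Δt assumes exponential growth over the whole
cultivation window; with a 24-h endpoint this is a window-averaged rate,
which is exactly the quantity the models are fitted to. Replicate flasks at
one carbon level are aggregated under one of three policies: `mean_od`
(default — average the ODs, then one μ per level), `mean_mu` (one μ per
flask, then average), or `pooled` (each flask keeps its own observation).
The default reflects how endpoint assays are usually reduced; at realistic
noise the policies differ only in the third decimal of μ. Negative μ values
are retained, but a configurable detection floor maps "no measurable
biomass" to μ = 0, which is how complete inhibition presents in practice.

## Fitting and model selection

Parameters are estimated by minimizing the sum of squared μ residuals with
bounded trust-region least squares (scipy `least_squares`, method `trf`),
multi-started from a deterministic, data-driven grid:

- μmax₀ = 1.05 × max observed μ; Ks₀ = lowest C₀ reaching half the maximum μ;
- Cmax₀ ∈ {1.05, 1.2, 1.5} × the largest C₀ that still grew;
- n₀, m₀ ∈ {0.1, 1, 5}; Ki₀, K₀ ∈ {1, 10, 100} × that C₀ scale;

followed by a polish pass from the incumbent at tight tolerances
(xtol = ftol = gtol = 10⁻¹⁵). Anchoring the Cmax starts and lower bound to
the largest *growing* level matters when the design contains zero-growth
levels: the true cutoff sits just above that level, not above the grid
maximum. Bounds keep all parameters positive, cap the exponents at 50
(unbounded exponents admit overflow-driven pseudo-fits with absurd Ki
values), and force Cmax above the largest growing level so the cutoff power
is defined on the data. Requesting more starts than the grid appends
seeded log-uniform random starts, so the search is deterministic given
(dataset, options) and enlarging the start budget can never worsen the
optimum.

Fits are scored by R² = 1 − SSres/SStot and RMSE = √(SSres/n) and ranked
with R² first and RMSE as tiebreaker (the selection criterion the endpoint
study design supports); exact ties go to the model with fewer parameters.
Ranking refuses fits whose recorded observation hashes differ, so fits of
different datasets cannot be compared silently. Degenerate or non-converged
fits are flagged but still reported — with eight observations several
four-parameter models are near-unidentifiable, and hiding them would
misrepresent the comparison.

**Known limitation — the μmax/Ks ridge.** In the Han–Levenspiel model, when
Ks(1−C₀/Cmax)ᵐ dominates the denominator only the ratio μmax/Ks is
identified, and noisy datasets can drive both parameters up a likelihood
ridge without changing the fit. On the crude-oil design the ridge is benign
(recovered μmax is within a few percent of truth); on the saponified design
— fewer growing levels, larger Ks — μmax itself is weakly identified even
though the *fit* (R², RMSE, predicted curve, Cmax) is recovered well.
Parameter-recovery claims are therefore made on the crude design.

## Stoichiometry

Fixed molar masses (g/mol): KOH 56.11, K 39.098, N 14.007, NH₄Cl 53.491.
All conversions are linear in composition mass fractions: carbon loading
= conc × c_fraction (crude oil 76.74 % C, saponified 58.11 % C, measured
saponified potassium 12.92 % K), nitrogen from NH₄Cl = conc × 14.007/53.491.
Minimum KOH molarity for complete saponification is SV × oil-loading
/ (1000 × 56.11). Blend design splits a total carbon loading between crude
and saponified oil by a carbon share and inverts each component's carbon
fraction; the components' carbon loadings sum back to the target exactly.
The measured 12.92 % potassium fraction is authoritative for loadings; it
sits between the no-excess stoichiometric prediction (~10.4 %) and the
full-excess-KOH prediction, and the dried-product mass basis behind it is
not recoverable, so no theoretical correction is applied. Composition
measurement uncertainties are carried as data, not propagated — the
downstream quantities are reported as point values.

A reporting note: chained published figures are reproduced from unrounded
intermediates wherever possible. Two documented rounding cascades remain:
the potassium load of the sucrose-carbon-equivalent oil mass is 88.27 g/L
from the unrounded chain but 88.24 from the rounded 683 g/L intermediate;
and the blend run's Y_PHA/oil is 0.545 from printed concentrations but 0.54
from unrounded assay values. The package always reports the unrounded
chain.

## Fermentation metrics

Yield coefficients divide endpoint biomass (or PHA) by the *initially
supplied* mass of oil, carbon or nitrogen — they are supply-basis yields,
not consumption-basis, because residual-substrate measurements are not part
of the summary record. For blends the oil basis is the crude-oil-equivalent
feed (the crude mass carrying the same carbon), making oil-basis yields of
blended and single-substrate runs comparable; the equivalent feed is an
explicit field, never inferred silently. Residual biomass is total − PHA;
PHA content is 100·PHA/total; productivities divide by elapsed time. The
nitrogen basis is the nominal supply from NH₄Cl (2.17 g/L → 0.568 g N/L)
rather than a measured total-nitrogen value.

## Synthetic data

The generator inverts the endpoint formula: OD_end = OD₀·e^(μ(C₀)·t)·e^(σZ)
with Z standard normal, i.e. lognormal multiplicative noise on the final
OD. On the μ scale this is additive mean-zero noise of SD σ/t, so replicate
means converge to the truth and no lognormal mean-correction is applied
(the induced bias on OD itself, of order σ²/2, is irrelevant to μ-based
analyses). Default σ = 0.03 matches the few-percent replicate scatter
endpoint OD assays show.

The reference design is eight oil levels evenly spaced over 3.72–30.00 g/L
— only the range endpoints are documented, so even spacing on the oil-mass
scale is assumed — converted to carbon with the crude-oil fraction
(≈2.9–23.0 g C/L) for both substrates (the saponified flasks matched the
crude carbon levels), duplicate flasks, OD₀ = 0.24, 24-h endpoint, and the
fitted Han–Levenspiel sets as truth. On the saponified design the two
highest levels exceed Cmax = 19.11 g C/L and produce zero-growth flasks,
exercising the detection-floor and Cmax-bound logic.

What the generator does **not** emulate: lag phases and time-varying μ
(endpoint μ is window-averaged by construction), substrate carry-over
between levels, per-flask initial-OD variation, and level-dependent error
structure. Passing recovery tests therefore demonstrate that the estimation
machinery is correct under the assumed error model, not that real
shake-flask data meet those assumptions.

Validation study sizes: the selection/recovery study uses 200 seeded
datasets (100 per substrate) at σ = 0.03; the optimizer oracle uses 100
random parameter draws against a 10⁵-point grid; the noiseless
identifiability check covers all nine models on both substrate designs,
with solver-tolerance thresholds RMSE ≤ 10⁻⁵ and R² ≥ 1 − 10⁻⁶.

## Interface choices

The package is primarily a Python library (`examples/` holds one narrative
script per capability); the CLI is a thin wrapper kept for shell-driven use
— every subcommand delegates to one or two library calls, validates its
inputs strictly (unknown config keys are errors), and embeds the package
version and a configuration hash in its JSON reports so runs are
attributable. Displayed values round to field precision (3 decimals for
kinetic parameters, 2 for yields) while JSON retains full precision,
avoiding rounding cascades in chained calculations.
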
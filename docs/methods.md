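# Methods

## The physical model

A drug molecularly dissolved in a spherical polymer matrix (radius *R*,
effective diffusivity *D*<sub>eff</sub>) releases into a well-stirred medium
across an external boundary layer with mass-transfer coefficient *h*. Under
sink conditions and a uniform initial distribution, the cumulative fraction
released is

F(t) = 1 − Σₙ 6L² / (βₙ²(βₙ² + L² − L)) · exp(−βₙ² D_eff t / R²),

with Biot number L = hR/D_eff and eigenvalues βₙ the positive roots of
β·cot β + L − 1 = 0. This is the classical conduction/diffusion solution for
a sphere with a surface film. Assumptions worth keeping in mind when
applying it to microsphere data:

- *M*<sub>∞</sub> is the amount released **at the end of the experiment**,
  not the loaded dose; curves normalised by final observed release always
  end at 1 even when a large fraction of the dose stays trapped in the
  polymer. The `normalization_mode` field records which convention a curve
  uses.
- The sphere population is treated as monodisperse at a single radius. The
  default R = 50.7 µm is half the volume-median laser-diffraction diameter
  (101.4 µm) of the estradiol microspheres; which radius statistic entered
  the original analysis is not documented, so the radius is explicit
  configuration everywhere rather than a constant.
- Matrix erosion, swelling, and drug–polymer partitioning are lumped into
  the two constants; the model is purely diffusive.
- The external film here stands in for everything between the sphere surface
  and the bulk (including a surrounding hydrogel, when present), which is
  why *h* rather than only *D*<sub>eff</sub> is of formulation interest.

Limits: at L → ∞ the roots approach nπ and F reduces to the film-free
series 1 − (6/π²)Σ exp(−n²π²τ)/n² in dimensionless time τ = D_eff t/R².
`LARGE_L_THRESHOLD = 1e3` controls automatic dispatch to the simplified
series under `model_variant: auto`; at L = 10³ the first-root error of the
π-multiple approximation is below 10⁻³ relative. The two series differ by
O(3(1−F)/L) at finite L — about 2.8·10⁻⁶ at L = 10⁶ and τ = 10⁻³ — which is
the scale the cross-check tests assert.

## Numerics

**Eigenvalues.** Root n is bracketed in ((n−1)π + ε, nπ − ε), ε = 10⁻⁹, where
the residual runs from +∞ to −∞, so exactly one root lies inside for any
L > 0; for L ≤ 1 the first bracket tightens to (ε, π/2]. Bisection to a
bracket width of 10⁻¹² is followed by one Newton step. Bisection-first is
deliberate: pure Newton is unsafe near the cotangent poles. The solver is
vectorised over batches of Biot numbers, which is what makes the genetic
algorithm affordable. The residual tolerance is applied to
|f|/max(1, |f′|): near the poles (large L) the residual slope reaches ~10¹¹
and a machine-exact root still has a raw residual of ~10⁻⁴, so the scaled
quantity — a bound on the error in the root itself — is the meaningful one.

**Series truncation.** The number of terms adapts to the smallest requested
τ (terms decay like exp(−n²π²τ); the count is chosen so the next term and
the geometric tail bound fall below 10⁻¹⁰ and 10⁻⁸), hard-capped at 10⁴
terms. Below τ = 10⁻⁶ the series converges too slowly to certify a value and
physical release is negligible, so the model returns 0 and logs a note. One
term count is used for a whole time grid, which keeps the evaluated curve
exactly monotone in t.

**PDE cross-check.** `fd_reference.released_fraction_fd` solves the radial
diffusion equation with the Robin surface condition by Crank–Nicolson on
u = r·c (400 radial intervals, time step capped at min(10⁻⁴, τ/200), eight
backward-Euler startup steps to damp the incompatible-initial-data
oscillations). It shares no code with the series and agrees with it to
better than 10⁻⁴ absolute for L ∈ {1, 10, 10³}.

## Parameter estimation

The residual sum of squares between observed and predicted fractions is
minimised over (log₁₀ D_eff, log₁₀ h); the log parameterisation is forced by
the decade span of the parameters (10⁻¹⁶–10⁻¹⁵ m²/s, ~10⁻¹⁰ m/s here).
Defaults: bounds (−20, −10) and (−14, −6) log₁₀ units — several decades of
slack around the plausible range — population 60, 200 generations,
tournament size 3, uniform crossover at rate 0.7, Gaussian log-space
mutation (rate 0.2, σ 0.35 decades), elitism of one, then a Nelder–Mead
polish whose result is kept only if it does not increase the RSS. The
optimiser literature would call this overkill for a smooth 2-D problem, but
the GA makes the fit robust to the long flat valleys the RSS surface has in
the weakly-identified-h regimes, and the whole fit costs about a second
because the objective is evaluated population-at-a-time through the batched
eigenvalue solver. Every result records its seed; identical inputs and seed
give bit-identical results.

**Identifiability.** When L is large the curve barely depends on h, and
D_eff and h trade off along a valley. After each fit the RSS response to
doubling and halving h (everything else fixed) is compared with
max(10⁻³·RSS, 10⁻¹²); below it — or when the estimate sits within 0.5% of a
log-space search bound — h is flagged `h_weakly_identified` rather than
reported as precise. The `simplified_eq6` variant ignores h entirely and
always carries the flag. Replicates are fitted independently (seed offset
per replicate) and aggregated as mean ± sample SD; a single fittable
replicate yields NaN SDs with `sd_defined = False` rather than a silent 0.

## Synthetic data

`synthetic_data` generates what the estimator assumes: per replicate,
forward-model fractions at a shared time grid plus iid additive Gaussian
noise on the fraction scale, truncated to [0, 1]. The default noise SD of
0.02 matches the few-percent repeatability of normalised spectrophotometric
readouts; the default grid is 12 log-spaced points spanning model fractions
0.05–0.99 so both the early (film-sensitive) and late (diffusion-sensitive)
parts of the curve are sampled. Built-in scenarios: `meoh_water`
(D_eff = 2.28·10⁻¹⁵ m²/s, h = 7.56·10⁻¹⁰ m/s — fast methanol:water medium),
`sls` (5.58·10⁻¹⁶, 4.01·10⁻¹⁰ — slow aqueous surfactant medium), both at
R = 50.7 µm, and `low_biot` (L = 1), where h is strongly identified. The
gravimetric generator constructs weight triples whose mass-loss and
water-uptake percentages hit specified trajectories, optionally with
Gaussian noise on the percentages.

What the generator does **not** emulate: sampling-time irregularity and
sparse early sampling of real dissolution schedules, polydispersity of the
sphere population, autocorrelated drift in the assay, or dose-normalisation
error. Passing round-trip tests therefore show the estimator is correct and
well-conditioned under the stated error model, not that real curves from a
given lab will constrain h equally well. In particular, with the default
log-spaced design, h at L ≈ 36 *is* identified to ~20% from noisy data;
sparser early sampling degrades that rapidly, which is the regime where the
weak-identifiability flag earns its keep.

## Design choices and limitations

- Phase boundaries for `phase_rate` are user-supplied; changepoint detection
  is out of scope, as biphasic profiles are conventionally segmented by
  inspection. The burst window defaults to 24 h and is configurable.
- Negative mass loss (dry weight above initial) is returned with a warning,
  never clipped: it is diagnostic of weighing problems.
- Replicate aggregation is mean ± sample SD across independent per-replicate
  fits; optimiser-derived uncertainties (bootstrap, profile likelihood) are
  intentionally absent.
- No model selection across release laws (Higuchi, Korsmeyer–Peppas, …) and
  no polydisperse (size-distribution-weighted) forward model.
- Internal units are strictly SI (seconds, metres); unit conversion happens
  only in the CSV layer, which accepts s/min/h/day.
- Problem sizes in the test suite and the reproduction script (12-point
  curves, 20-replicate identifiability studies, 3 Biot values for the PDE
  cross-check) were chosen so each check isolates one property at the
  smallest size that exercises it.
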
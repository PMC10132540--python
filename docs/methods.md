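# Methods

## Model and assumptions

The package compares six quantitative randomized-response mechanisms under
a common set of moment assumptions: the sensitive variable Y has mean μ_Y
and variance σ²_Y; the additive scrambler S has mean θ and variance σ²_S;
the multiplicative scrambler T has mean 1 and variance σ²_T; Y, S, T are
mutually independent; respondents are drawn by simple random sampling
*with replacement*, so no finite-population correction appears anywhere
and Var(μ̂) scales exactly as 1/n.

All six mechanisms share the estimator μ̂ = (1/n) Σ Zᵢ, which is unbiased
exactly when θ = 0 and E(T) = 1. The package therefore fixes θ = 0 as the
default and rejects a non-zero additive-scrambler mean at spec-construction
time unless `allow_biased=True` is set; in that opt-in mode
`estimate_mean(..., model=params, theta=θ)` subtracts the known offset
E(Z) − μ_Y (θ for the plain additive model, (1−p)θ for the optional
additive ones, (1−p)αθ for the mixed model). This correction is an
extension beyond the standard design and is labelled as such.

The two-branch mixed model is evaluated under uncorrelated (S, T), the
assumption all of the models here share; correlated scrambling is out of
scope.

## Closed forms

With g = σ²_T(σ²_Y + μ²_Y):

| model | Var(μ̂)·n | ∇ (printed) | ∇ (first principles) |
|---|---|---|---|
| additive | σ²_Y + σ²_S | σ²_S | same |
| multiplicative | σ²_Y + g | g | same |
| optional additive | σ²_Y + (1−p)σ²_S | (1−p)σ²_S | same |
| optional multiplicative | σ²_Y + (1−p)g | (1−p)g | same |
| mixed (α) | (1−p)g + σ²_Y + α²σ²_S | (1−p)(g + α²σ²_S) | same |
| three-branch (A) | (1−p)(1−A)g + σ²_Y + (1−p)σ²_S | (1−A)g + σ²_S | (1−p)[σ²_S + (1−A)g] |

δ = Var(μ̂)/∇ throughout (MSE = Var for these unbiased estimators).

Two deliberate fidelity decisions:

1. **Three-branch privacy.** The published closed form for the three-branch
   optional model lacks the scrambled-branch probability (1−p) that a
   direct application of ∇ = E[(Z−Y)²] to the mechanism produces, and is
   therefore constant in p. Both variants are first-class:
   `privacy_as_printed` reproduces the published tables (the default for
   grid building), `privacy_first_principles` carries the (1−p) factor and
   is the only variant consistent with simulation. The Monte-Carlo suite
   asserts both facts: printed mode *fails* the empirical check for every
   p > 0 and first-principles mode passes.
2. **Mixed-model variance.** The published variance for the mixed (α)
   model carries the α²σ²_S term without a (1−p) factor, whereas a direct
   derivation from its mechanism attenuates that term by (1−p). The
   printed form is implemented (it is what the published grid tabulates);
   at the default grid the two differ by ≤ 0.3%, below the resolution of
   the 5-sigma Monte-Carlo check at R = 10⁴ replicates (relative MC
   standard error ≈ √(2/R) ≈ 1.4%), so the empirical variance check passes
   under either reading. The corresponding privacy formula *does* carry
   (1−p) on both terms and matches simulation exactly.

δ at ∇ = 0 (p = 1, or all scrambler variances zero) is undefined in the
source definition; the package returns tagged sentinels instead of raising
— `inf` when Var > 0, `nan` for the 0/0 corner — so p-sweeps over the
closed endpoints do not abort. p is accepted on the closed interval
[0, 1]; A must lie strictly inside (0, 1); α is any finite real.

Efficiency conditions: the additive-vs-multiplicative pairs reduce to
g > σ²_S; the three-branch-vs-mixed pair to
A(1−p)g + α²σ²_S > (1−p)σ²_S. For the optional pair the cancelled (1−p)
factor is retained internally so the boolean agrees with direct variance
comparison even at the degenerate boundary p = 1 (where the two variances
coincide and neither model is strictly more efficient).

## Synthetic data

The generator emulates the moment assumptions, not any particular survey:
distribution families are pluggable and matched to the requested
(mean, variance) by method of moments. Defaults: Y ~ normal(μ_Y, σ²_Y);
S ~ normal(0, σ²_S); T ~ gamma with mean 1 (shape 1/σ²_T, scale σ²_T) —
positivity is natural for a multiplicative scrambler and avoids sign flips
in reported responses. Alternatives: gamma or lognormal Y, symmetric
two-point scramblers (a centred additive scrambler cannot be gamma).
Zero variance degenerates to a constant for every family.

What passing tests do and do not show: because the analytic results depend
only on moments, agreement between simulation and the closed forms is
verified across families — but real survey data bring non-sampling
features (lying despite the scrambling, respondent-chosen p, measurement
error, finite populations) that no family choice here emulates.

Seeding: one master seed; per-variable substreams derived via
`SeedSequence(seed, spawn_key=(crc32(role),))` for the roles population /
additive / multiplicative / branch / subbranch. Streams are bitwise
reproducible, and adding a model or variable to a run never perturbs the
draws of the others. Branch selection consumes explicit pre-drawn uniforms
(`u < p` truthful; for the three-branch model a second uniform `u2 < A`
picks the additive sub-branch), so the same respondent stream can be
replayed across models as common random numbers.

## Monte-Carlo verification

`run_replicates` simulates R independent surveys of size n (one vectorized
block of R·n draws per variable) and compares (i) the mean of the R
estimates against μ_Y, (ii) their variance against the closed-form
Var(μ̂), (iii) the grand mean of (Z−Y)² against the analytic ∇ — each as a
z-score against a Monte-Carlo standard error, passing at |z| ≤ k_sigma
(default 5, a negligible false-failure rate across the full grid while
still detecting transcription-level formula errors). The MC standard error
of the empirical variance uses the sample fourth central moment,
Var(s²) = (m₄ − (R−3)/(R−1)·m₂²)/R, because reported responses are
decidedly non-normal under gamma scramblers; the normal-theory 2σ⁴/R
shortcut would understate it.

Problem sizes: the test suite runs the full verification at R = 10⁴,
n = 500 for every model and both scrambler-variance blocks (the default
replicate budget), with smaller R for auxiliary power/family checks;
`rrcompare verify` accepts any R from the command line.

## Comparison grids

The default grid is the published one: μ_Y = 10, σ²_Y = 2, n = 500;
(σ²_S, σ²_T) blocks (6, 8) and (10, 4); p ∈ {0.3, 0.5, 0.7}; (A, α)
panels (0.8, 0.9), (0.5, 0.6), (0.2, 0.3) — 108 cells per metric. Models
without p (or without A/α) repeat their value across those columns exactly
as the printed tables do. Regression tests compare every cell at that
cell's own printed precision (the tables mix 2–6 decimals), asserting
agreement within 0.5 unit in the last printed place. Rankings: variance
and δ ascending, privacy descending (higher ∇ = better protection); ties
are broken by canonical model order and flagged.

A is treated as a design-fixed constant (not respondent-chosen); the three
branch probabilities p, (1−p)A, (1−p)(1−A) sum to 1 for any A.

## Known limitations

* Binary/qualitative randomized-response designs are out of scope.
* No stratified or unequal-probability sampling; no finite-population
  correction by design (with-replacement sampling).
* Heavy-tailed scrambler families without finite variance are unsupported
  (every formula here needs second moments).
* The printed-mode three-branch privacy (and hence its δ column) mirrors
  the published tables but is not simulation-consistent; use
  `privacy_mode="first_principles"` for internally coherent numbers.
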
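# Methods

## The dyadic similarity model

The unit of analysis is the *dyad*: an unordered pair of faecal samples from
two distinct birds captured in the same field period (one breeding season of
one year; pairing across periods is never allowed, so temporal turnover of
the microbiome cannot masquerade as social structure). Each dyad carries a
similarity response — the negated Aitchison distance between the two samples,
or the negated absolute difference in richness/Shannon diversity — so larger
values always mean "more similar", and regression coefficients read as
effects on similarity.

Fixed effects are the social predictor of interest (same vs different
breeding group; or, within groups, the five status-pair categories Dom–Dom,
Dom–Help, Dom–Sub, Help–Sub, Sub–Sub, or their nest-sharing lump) together
with nuisance covariates: absolute age difference (years), sex difference
(same as reference), season (major as reference), absolute difference in
minutes after sunrise, absolute difference in day-in-season, pedigree
relatedness, and a shared-nest-at-hatch indicator. Reference levels follow
the convention that the first-listed level is the baseline (between group,
same sex, major season, no shared nest, Dom–Dom, nest-sharing).

Every bird appears in many dyads, which pseudo-replicates the data. The model
therefore includes a **multi-membership random effect**: a single
bird-identity random factor whose incidence matrix has a 1 in the column of
*each* member of the dyad (row sums 2; a 0.5-per-member weighting is
available via `build_design(..., mm_weight=0.5)`). Sample year enters as an
ordinary random intercept. Random blocks with a single observed level are
dropped: a one-level random intercept is confounded with the fixed intercept
and leaves the REML criterion flat.

## REML estimation

With `H(γ) = I + Σ_k γ_k Z_k Z_kᵀ` and variance ratios `γ_k = σ²_k/σ²_e`,
the residual variance is profiled out and

`−2·rl(γ) = (n−p)(log σ̂²_e + 1 + log 2π) + log|W(γ)| + log|XᵀH⁻¹X|`,

where `W = I_q + D^{1/2} ZᵀZ D^{1/2}` (Woodbury/Sylvester), `q` the total
number of random levels. All cross-products (`ZᵀZ`, `ZᵀX`, `XᵀX`, …) are
precomputed once, so each evaluation costs O(q³) regardless of the number of
dyads — a fit with ~28 000 dyads and ~350 birds is dominated by a few hundred
Cholesky factorisations of a ~350×350 matrix.

Optimisation runs on log γ (nonnegativity by construction) with L-BFGS-B from
two starts (γ = e⁻¹ and e⁻⁵) followed by a Nelder–Mead polish (relative
objective tolerance 1e-8, the package default). Boundary solutions
(γ ≈ 0) are legitimate and reported with a `singular` flag;
non-convergence flags the fit rather than raising. β is obtained by
generalised least squares at the optimum; `reml_loglik` reports
`−½[log|V| + log|XᵀV⁻¹X| + rᵀV⁻¹r + (n−p)log 2π]`.

## Inference

- **Satterthwaite df.** For a contrast c, `df = 2C²/(gᵀ Var(θ̂) g)` with
  `C = cᵀcov(β)c`, g the finite-difference gradient of C in the variance
  components θ = (σ²_year, σ²_bird, σ²_e), and `Var(θ̂) = 2·H⁻¹` from a
  finite-difference Hessian of −2·rl (central differences, forward at a zero
  boundary). If the Hessian is not positive definite the residual df `n−p` is
  used (logged); df is clamped to [1, n−p]. With all variances zero the fit,
  its standard errors and p-values collapse exactly to OLS.
- **Post hoc contrasts.** All pairwise status-level differences are tested
  with a single-step familywise adjustment: the adjusted p of a contrast with
  statistic t is `P(max_i |Z_i| ≥ |t|)` under the joint normal approximation
  `Z ~ N(0, R)` of the standardised contrasts. Because contrasts in a mixed
  model with unequal standard errors are not exchangeable, this equicoordinate
  construction is used instead of the studentized-range distribution. The
  probability is evaluated by scrambled-Sobol quadrature (2¹⁵ points, fixed
  internal seed → deterministic output; the contrast correlation matrix is
  rank-deficient by construction, handled via an eigendecomposition square
  root). With two levels the adjusted p equals the unadjusted p exactly.
  Contrasts are run when the omnibus Wald F on the factor (df2 = smallest
  Satterthwaite df across the factor's coefficients, a conservative choice)
  is significant at the configurable gate (default 0.05).
- **Collinearity.** Generalised VIFs are computed on the correlation matrix
  of the fixed-effects columns (intercept excluded) and reported with every
  fit, uncapped.

## Compositional processing

Counts are ASV-level. Samples under the rarefaction depth (default 8000
reads) are removed entirely; alpha diversity (richness; Shannon in nats) is
computed on a single seeded without-replacement rarefaction draw
(multivariate hypergeometric), not an average over draws. Composition uses
the unrarefied counts of the retained samples: taxa with < 50 reads total or
< 5% prevalence are dropped (both thresholds evaluated on the input table and
applied jointly, so filter order is irrelevant; prevalence is retain-if
≥ 5%), then CLR with pseudocount 1 (configurable; the analyses depend only on
relative distances, and a documented constant shift is the simplest
zero-handling policy), then Euclidean distances on CLR rows (= Aitchison).

Aerotolerance classes (aerotolerant = aerobic + facultatively anaerobic;
anaerobic; unknown) are assigned at genus level and inherited by ASVs;
unknown-class taxa appear in the overall analysis but in neither stratum.
Strata are **re-closed**: the subset is taken from the filtered counts,
re-filtered with the same thresholds, and re-CLR-transformed — the CLR of a
subcomposition is not a subset of the full CLR values, and re-closure treats
each stratum as its own composition.

## The synthetic-data generator

The generator emulates the study system the pipeline targets: a closed island
population of ~115 territories of 2–5 birds (size weights 0.45/0.35/0.15/0.05,
expected population ≈ 320), each with exactly one dominant pair; subordinates
are helpers with probability 0.42 (females) / 0.20 (males). Each field period
(major/minor season) every bird is sampled with probability 0.8 — the field
teams of such long-term systems attempt to catch every group member each
season — with day-in-season 0–97 and minutes-after-sunrise 0–634 drawn
uniformly per capture.

**Relatedness** comes from a two-generation pedigree: subordinates are natal
with probability 0.8; natal subordinates are offspring of the dominant female
and, with extra-group paternity probability 0.44, an extra-group dominant
male. Founder pairs within a group carry a small "background relatedness"
(0 / 0.125 / 0.25 with probabilities 0.62/0.20/0.18), reflecting unrecorded
shared ancestry in a closed population; these two knobs were calibrated once
so the within-group mean relatedness lands near the observed 0.26. The
two-generation design caps attainable relatedness near 0.6 (real pedigrees
reach ~0.77 through deeper inbreeding loops); this truncation does not affect
the dyadic models, which use relatedness only as a covariate.

**Transmission.** Latent log-abundance of taxon j in sample i is
`μ_j + period_jt + env (aerotolerant j) + u_bird (anaerobic j) + ε_ij` with
`μ_j ~ N(0, 1.5²)` (abundance skew), period effects `N(0, σ²_period)` shared
population-wide, group-level environmental draws `N(0, σ²_env)` per
(group, period, aerotolerant taxon) shared by all group members, and
persistent bird effects for anaerobic taxa
`u_b = σ_bird(√ρ·v_unit + √(1−ρ)·e_b)`, where v is shared within the *nest
unit* — the dominant pair plus their helpers, the birds that physically
interact at the nest; non-helping subordinates form singleton units. Unknown
-class taxa receive only baseline + period + residual variation. Counts are
multinomial (softmax of the latent row) at a gamma-Poisson depth around
`depth_mean` (default 20 000, dispersion shape 25).

Default effect sizes are σ_env = 0.8, ρ_nest = 0.4, σ_bird = 1.0,
σ_resid = 0.5, σ_period = 0.5, with 120 aerotolerant / 60 anaerobic / 10
unknown taxa (the aerotolerant:anaerobic ratio of real assignments is roughly
3:1; 2:1 at this scale keeps both strata informative after prevalence
filtering). These are "moderate, clearly detectable" settings: group
environmental sharing is the dominant route, contact sharing is substantial
but subtler.

**What the generator does not emulate:** within-host ecological dynamics,
strain-level variation, read-level (FASTQ) error, contaminant taxa, batch
effects, diet composition, and real spatial structure of territories. Passing
recovery tests therefore demonstrates that the *pipeline* detects the
transmission structure it is pointed at under realistic compositional noise —
not that any particular field dataset satisfies the model's assumptions.

## Validation design and problem sizes

The test suite validates each stage against independent oracles: dense
brute-force maximisation of the explicit REML criterion (20 random instances
of ≤ 40 dyads), OLS collapse with variances pinned to zero, closed-form
balanced one-way ANOVA estimators, naive double-loop Aitchison distances,
hand-enumerated filter fixtures, a Monte-Carlo max-|Z| null for the
single-step contrast adjustment, and the two-predictor VIF closed form
1/(1−r²). End-to-end behaviour is checked by type-I calibration (500 null
replicates at 30 groups × 1 period: same-group rejection rate within the 95%
binomial envelope of 0.05) and by parameter recovery (100 replicates at 40
groups × 2 periods: same-group positive and significant in ≥ 80% of
replicates in both strata; nest-sharing significant in ≥ 70% of anaerobic
runs and ≤ 20% of aerotolerant runs). The replicate counts and population
sizes are the package's chosen validation scale: large enough for the
binomial envelopes to be meaningful, small enough that the whole suite runs
in about a minute.

## Numerical and design notes

- Rarefaction keeps all-zero taxon columns; pruning is a separate explicit
  step, so column identity is stable across seeded draws.
- Dyads whose bird pair is missing from the relatedness matrix are dropped
  with a logged count (zero-filling would understate kin structure).
- Helper–Helper within-group pairs have no slot in the five status-pair
  categories and are excluded with a logged count.
- A bird sampled twice in one period would contribute all cross-bird pairs;
  the multi-membership random effect absorbs the repetition. The generator
  emits at most one sample per bird per period.
- In small within-group datasets a nuisance covariate can be exactly
  collinear with the status dummies; the pipeline then drops the aliased
  nuisance term (logged) and never the social predictor. `build_design`
  itself always errors on rank deficiency, naming the aliased columns.
- p-values are two-sided throughout; significance marks in output tables are
  `*` (p < 0.05) and `.` (p < 0.10).
- Outputs contain no timestamps, so a rerun with the same seed reproduces
  every artefact byte for byte.

## Known limitations

- The multi-membership structure supports exactly the two stated random
  terms (year, bird identity); no crossed residual covariances, GLMMs, or
  Bayesian estimation.
- Satterthwaite df relies on a finite-difference Hessian; at variance
  boundaries it falls back to residual df, which is anti-conservative for
  coefficients informed by few random levels (the intercept, season).
- The single-step contrast adjustment uses the normal (not t) approximation;
  with the large Satterthwaite dfs typical of dyadic data the difference is
  negligible, but with very few within-group dyads the adjusted p can be
  slightly liberal.
- Phylogenetic metrics (UniFrac), rarefaction curves and completeness
  estimation are out of scope.
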
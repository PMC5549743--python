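# Methods

## The sampling design and its quantities

The package targets nested presence/absence surveys: `L` locations along an
elevational gradient, each with one stand per forest-use habitat (`OG`
old-growth, `DE` degraded, `SE` secondary), each stand sampled with `n`
fixed-area plots (defaults: 8 locations, 3 habitats, 5 plots — 120 plots).
All quantities derive from a binary plots × species matrix:

* **α** — presences per plot.  All-zero plots are legal (species-free
  lowland plots occur in real surveys); they count toward means with α = 0.
* **γ** — richness of the union of a location's plots.
* **Pairwise β** — Sørensen dissimilarity `1 − 2C/(A+B)`.  If both plots are
  empty the index is undefined (0/0) and the pair is excluded from every
  summary; if exactly one is empty, `S = 0` and `β = 1`, which is
  well-defined.  Comparison schemes follow the nested design: all `C(n,2)`
  pairs within a habitat cell, and the full `n × n` cross product between
  two cells of the same location.  Pairs are pooled per *habitat
  transition* — the unordered pair of habitat codes, canonicalized with
  `OG < DE < SE` so six levels exist for three habitats.
* **Endemic proportion** — endemic species present / α.  The denominator is
  the plot's own richness (a within-plot fraction suitable for beta-family
  regression), and empty plots yield a missing value, since 0/0 has no
  meaning and beta regression cannot take it.

## Bootstrap standard errors for transition means

Pairs that share a plot are dependent, so the bootstrap resamples **plots**,
not pair values: within each contributing cell, plot indices are drawn with
replacement; every pairwise β of the replicate is then re-read and pooled
over locations, and the SE is the standard deviation of the replicate means
(default 1000 replicates, always seeded).  Resampling can duplicate a plot;
the self-pair of a non-empty plot contributes β = 0, of an empty plot is
undefined — both are consequences of the definitions, not special cases.  A
naive value-resampling scheme is available (`resample="values"`) for
comparison; it ignores the dependence and typically understates the SE.

## Multiplicative partitioning

Per location, `γ = ᾱ · β_w · β_b` with `β_w = ᾱ₂/ᾱ`, `β_b = γ/ᾱ₂`, where
`ᾱ₂` is the mean pooled richness of the location's habitats.  Components are
numbers-equivalents at diversity order q = 0 and are reported raw — no
null-model standardization — because the partition is used descriptively,
and raw mean plot richness is the natural first factor.  The identity is
exact by construction and asserted to 1e-9 in tests; an independent
cross-check against R `vegan::multipart` (global partition, Rényi scale 0)
runs in the test suite.  Log-scale shares `log ᾱ / log γ` etc. are emitted
for stacked-contribution plots; shares can exceed [0, 1] when ᾱ < 1 (very
species-poor locations), which is a property of the log decomposition, not
an error.

## Hill-number profiles for incidence data

For a group of `T` pooled plots, species i has incidence `Y_i ∈ 1..T`,
`U = Σ Y_i`, and `Q_k` counts species with incidence k.  The empirical
profile uses incidence shares `π_i = Y_i/U` (so Σπ = 1, the premise of the
Hill formula): `qD = (Σ π_i^q)^{1/(1−q)}`, with the Shannon limit at q = 1.

The asymptotic profile estimates the sampling-curve asymptote at each order
from the frequency counts (full formula in the `hill_profiles` module
docstring).  Anchors:

* q = 0: bias-corrected Chao2, `S_obs + ((T−1)/T)·Q₁(Q₁−1)/(2(Q₂+1))` — the
  `Q₂+1` denominator also covers the no-doubleton case;
* q = 2: the tail term vanishes identically and the expression collapses to
  the classical unbiased incidence Simpson estimator
  `(U/T)² / [Σ Y_i(Y_i−1)/(T(T−1))]`;
* q = 1: evaluated as the numerical two-sided limit of the same expression
  (±1e-5, averaged in log space), so the profile is continuous there.  The
  undetected-species parameter `A` is parameterized from the q = 0 anchor
  (`A = Q₁/(Q₁ + T·Q̂₀)`), making the whole profile consistent with the
  Chao2 correction.

With heavy undersampling (many singletons) the asymptotic values at higher
orders carry large variance and can exceed the q = 0 estimate; the monotone
non-increase in q is a property of true diversities and of the empirical
profile, and is only asserted for the latter.  Default grid: q = 0…3 in
steps of 0.25, endpoints inclusive.  `T < 2` makes the estimator undefined;
the profile then falls back to the empirical one with a warning.

## GLM candidate set, fitting, and AICc ranking

Responses and families: plot richness — negative binomial (NB2, dispersion
estimated by ML); endemic proportion — beta regression (logit mean link,
log-precision), with exact 0/1 squeezed by `(y(n−1)+0.5)/n`; pairwise β —
log-normal, i.e. Gaussian ML on `log y` with the Jacobian `−Σ log y` added
to the log-likelihood so AICc is comparable across candidates of the
response.  For β models the species-free lowest belt is excluded and the
habitat factor is replaced by the six-level transition factor.

The candidate set is deterministic and holds exactly 31 models: the 30
simplest hierarchical main-effects combinations of
{elevation, +elevation²} × {factor} × {MAT, +MAT²} × {MAP, +MAP²} (ordered
by term count, then lexicographically; the simplest is intercept-only),
plus one richer model per response carrying the reported best structure
with interactions; main effects required by its interactions are added so
every candidate satisfies the hierarchy rule.  Continuous predictors are
z-standardized internally (squares of z-scores for quadratics); this fixes
coefficient scale only and leaves likelihoods, AICc and pseudo-R²
invariant, which is asserted in tests.

`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`; `k` counts all estimated parameters
including dispersion/precision/σ.  Models that fail to converge or have
`n ≤ k+1` are excluded from ranking with a warning.  Pseudo-R² is
deviance-based, `1 − D_model/D_null` with `D = 2(ℓ_sat − ℓ)`; the saturated
term is per-observation maximal likelihood at the model's own dispersion —
for the beta family the maximizing mean is not `y` itself and is obtained by
solving `ψ(μφ) − ψ((1−μ)φ) = logit(y)` by bisection.  Within a ΔAICc < 2
band the model with fewest parameters is selected (parsimony convention).

## The synthetic landscape generator

Occurrence of species s in a plot at elevation e and habitat h is an
independent Bernoulli draw with

    p = clip( occupancy · κ · exp(−(e − c_s)²/(2·niche_width²))
              · habitat_affinity[group(s), h], 0, 1 )

Niche centers `c_s` are drawn from a Gaussian centered on `richness_peak`
(SD `richness_width`, truncated to the elevation span): the *density of
species ranges* produces the hump-shaped richness gradient, while any
species inside its range stays equally detectable — which keeps pairwise
dissimilarity realistic at species-poor belts.  `κ` calibrates the expected
per-plot richness at the peak (a Poisson-binomial mean, exposed exactly by
`expected_alpha`) to `richness_max`; habitat specialist groups with an
affinity multiplier matrix generate between-habitat turnover; endemism is a
per-species Bernoulli draw with probability given by a Gaussian curve of
the species' niche center (default peaking at 650 m).

Defaults describe a tropical-mountain herb survey: 264-species pool,
elevations 50–3500 m, peak richness 13 species/plot at 2500 m
(`richness_width` 1150 m), 80 m niche SD, occupancy 0.95, affinity 1 on the
diagonal / 0.45 off it.  Under these, realized landscapes show hump-shaped
α peaking around 2100–2500 m, a few species-free lowland plots,
within-habitat Sørensen dissimilarity around 0.45–0.6 and between-habitat
around 0.6–0.7, and γ peaking at mid-to-high elevations — the qualitative
and approximate quantitative structure of real elevation × forest-use
surveys.  What the generator does **not** emulate: spatial autocorrelation
within stands, species co-occurrence beyond shared responses, abundances,
and observer error; passing tests therefore demonstrate correctness of the
estimators under independent-Bernoulli sampling, not robustness to those
real-data features.

Reproducibility: the species pool derives deterministically from the config
seed; each plot draws from a child seed spawned from (seed, location,
habitat, plot), so partial regeneration is stable.  The pipeline derives
per-stage sub-seeds by stable hashing of the stage name.

## Problem sizes

Test and acceptance runs use the default 120-plot design with pools of
60–264 species, 1000 bootstrap replicates for reported SEs (10–50 for
smoke checks), 100 replicates for the richness-estimator recovery study and
20 for model recovery — sizes at which every Monte-Carlo check has
comfortable margins while the whole suite completes in well under a minute.

## Known limitations

* The asymptotic Hill estimator above order ~2 is variance-prone for small
  `T` with many singletons (see above); treat high-q asymptotic values at
  `T ≤ 15` as indicative.
* Beta regression can be numerically fragile under heavy collinearity
  (elevation and temperature are strongly correlated by nature); such fits
  are flagged and excluded from ranking rather than repaired.
* Bootstrap SEs assume the plot is the exchangeable unit; if plots within a
  stand were spatially autocorrelated the SEs would be optimistic.
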
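# Methods

`catpop` models Spain-style national community-cat (free-roaming *Felis
catus*) management in three stages: a stratified baseline estimate, a
scenario-specific reproduction model, and a stochastic metapopulation
projection under trap–neuter–return (TNR) sterilization policies. This note
documents the model, its assumptions, the defaults, and the design choices
made where the problem was genuinely open.

## Stratification and baseline extrapolation

Municipalities are classified on two independent axes:

* **habitat** — urban if human population > 20,000, rural otherwise (the
  boundary is rural);
* **reproductive potential** — a province-level class L/M/H/VH reflecting
  winter daylight and temperature, accepted as an input column (deriving it
  from climate data is out of scope).

This yields eight strata: UL, UM, UH, UVH, RL, RM, RH, RVH.

Separately, five municipality-size classes (<500, 500–5000, 5000–10000,
10000–50000, >50000 inhabitants) carry two census ratios estimated from the
sampled municipalities: community cats per inhabitant (defaults 0.59, 0.12,
0.04, 0.03, 0.01) and cats per colony (15.68, 15.05, 13.29, 14.14, 12.64).
The printed class labels are ambiguous at their shared boundaries; the
package uses right-open bins, so 5,000 falls in "5000–10000" and 50,000 in
">50000".

The ratio estimator is **pooled**: `sum(cats) / sum(inhabitants)` within a
class, rather than a mean of per-municipality ratios. Pooling weights
municipalities by size and is robust to tiny denominators; the synthetic
generator is used to validate recovery of the true ratios.

Extrapolation applies each census municipality's size-class ratio to its
human population, aggregates real-valued contributions by stratum, and
rounds **half-up only at the stratum aggregate** (per-municipality rounding
would bias small-municipality strata). Partition totals are sums of the
rounded stratum values, so the eight strata always add exactly to the
national total. With the packaged fixture census the baseline is 1,813,936
cats nationally — 485,769 urban, 1,328,167 rural (73.2% rural).

## Reproduction model

Annual reproductive output per unsterilized female is modelled in two
stages, then filtered by first-year mortality:

1. **Litter frequency.** Litters per year ~ Binomial(n = 3,
   p_modulated), with `p_modulated = p_base × RUR`, `p_base = 0.85` per
   fertile attempt. RUR (Reproductive Utilization Rate) is the fraction of
   fertile periods producing a pregnancy: 0.55 (L), 0.65 (M), 0.75 (H),
   0.85 (VH). Strata map to these levels with urban habitats bumped one
   level (UL→0.65, UM→0.75, UH and UVH→0.85), reflecting year-round urban
   food subsidies and prolonged estrus.
2. **Litter size.** Kittens per litter k ∈ {1..6} with
   `P(k) ∝ exp(−(k−μ)²/2σ²)`, normalized over the support; the Gaussian
   prefactor 1/(σ√2π) cancels under normalization and is omitted. Urban:
   μ = 3.75, σ = 1.2 (mean realized size 3.73). Rural: μ = 4.75, σ = 1.3
   (mean 4.53). Sizes outside 1–6 have probability zero by construction.

Expected viable offspring per female per year is
`3·p_modulated × E[litter size] × (1 − kitten mortality)` with 65% kitten
(<1 year) and 15% adult annual mortality, uniform across strata.

Printed probability tables are rounded half-up at 2 decimals (percent);
internal arithmetic keeps full precision. There is no within-year
seasonality: the model is strictly annual, with seasonality folded into RUR.

## Projection engine

Each stratum holds four cohorts (kitten/adult × sterilized/unsterilized),
advanced annually over a 25-year horizon in a fixed, configurable event
order: births → catastrophe draw → mortality → age-up → abandonment →
adoption → sterilization transfer → carrying capacity.

* **Births.** Breeding pool = 50% of unsterilized adults (an assumed even
  sex ratio; the data do not constrain it). Stochastic engine: total
  litters ~ Binomial(3F, p_mod), litter-size composition multinomial.
* **Mortality.** Binomial thinning at 65%/15%. Catastrophes (epizootics,
  poisoning) strike each stratum independently with 5% annual probability
  and multiply that year's rates by 1.30 (capped at 1). An additive
  reading (+30 points) is available as a flag; multiplicative is the
  default because mortality "increase" most naturally scales the rate.
* **Age structure.** Two stages only (kitten <1y, adult), matching the two
  mortality rates; no maximum age — a flat 15% adult hazard implies a
  geometric mean adult lifespan of ~6.7 years. The initial population
  starts all-adult, 20% sterilized by default (the status-quo coverage); a
  `stable` flag seeds a stationary kitten share instead as a sensitivity.
* **Flows.** A constant national abandonment inflow of 109,000 cats/year
  enters unsterilized (half kittens, half adults), allocated across strata
  proportionally to initial stratum populations. A constant national
  adoption harvest of 52,000 cats/year (which also absorbs the <1% welfare
  euthanasia/surgical losses) is removed proportionally to current cohort
  sizes, capped at availability. Both are integerized by deterministic
  largest-remainder allocation in both engines: they are planned management
  flows, not demographic noise.
* **Sterilization.** The annual TNR campaign is a *transfer* — individuals
  move from unsterilized to sterilized cohorts, never leave the
  population. The default policy semantics is *maintain*: transfer the
  minimum needed so the sterilized stock fraction meets the target each
  year. Because the transfer runs after the flow steps, immigrants are
  covered too. An *annual-rate* mode (target = fraction of the unsterilized
  pool treated per year, a campaign-effort reading) is exposed for
  sensitivity analysis; under it the coverage threshold for population
  decline lands in the 60–70% band commonly cited for TNR programmes.
* **Carrying capacity.** K = 2.5× initial stratum population (rural) or
  3× (urban — stronger human subsidies), configurable per stratum;
  applied to sterilized + unsterilized combined. Excess is removed
  proportionally (largest remainder), so the stratum lands exactly on K.
  Nationally the default ceiling is 4,777,725 cats.

**Engines.** The stochastic engine keeps integer counts and draws
binomial/multinomial variates; the expected-value engine propagates
real-valued means deterministically (catastrophes enter via the expected
rate multiplier) and is bit-reproducible. Where the dynamics are linear (no
capacity binding, no harvest caps) the two agree exactly in expectation,
which the suite verifies at 1000 iterations within 3 standard errors.
Monte-Carlo iterations are vectorized through one seeded generator
(`numpy` PCG64 via `SeedSequence(seed)`); runs are reproducible for a fixed
seed and iteration count, and every run manifest records the seed.

**Bookkeeping invariants**, asserted every simulated year: the integer
ledger `total(t+1) = total(t) + births + abandonments − deaths − adoptions −
capacity removals` holds exactly; sterilization never changes the total;
capacity never increases it; total ≤ K after every year.

## Built-in policy plans

`baseline20` (20% everywhere), `enhanced40` (40%), `ideal80` (80%), and
`pacf` — the differentiated plan: 50% in most strata, 60% in UVH and RH,
70% in RVH. The differentiated targets are configuration, not hard-coded
(the source strategy's stratum labels are ambiguous; the mapping
UVH→60%/RH→60%/RVH→70% follows their verbal descriptions, and alternatives
are expressible in a policy YAML).

## Synthetic data

`generate_sample` emulates the ~1128-municipality administrative sample:
sizes log-uniform within each class (class mix 109/477/186/278/78),
reported cat counts negative-binomial around `ratio × inhabitants`
(gamma–Poisson, shape 10 — moderate overdispersion typical of colony
census counts; no error model is published, so this is the package's
choice), colony counts from the cats-per-colony ratio with lognormal noise
(σ = 0.10). The round trip generate → estimate → extrapolate recovers the
true ratios within 10% per class at n = 1128 (verified on a fixed seed) and
tightens toward exactness as noise vanishes.

`generate_census` deterministically *inverse-solves* a target stratum
baseline: for each stratum it finds the total human population whose
ratio-extrapolation rounds exactly to the target, then splits it into
municipalities that stay inside one size class and on the correct side of
the urban threshold (rural strata: <500-inhabitant municipalities; urban:
10000–50000). The packaged fixture census (4,840 synthetic municipalities)
reproduces the default baseline table stratum-exactly. It is a test
artifact emulating the real national register's aggregates, not a claim
about real municipal data; in particular it does not reproduce real
per-region distributions, municipality counts, or the size-class mixture of
the real census, so baseline tests validate the bookkeeping, not the
underlying administrative data.

## Problem sizes and numerical choices

The default run is 8 strata × 25 years × 1000 iterations (< 1 s,
vectorized). The test suite and the acceptance script use 20–1000
iterations depending on the tolerance being exercised; projection checks
use 100–300 iterations, at which the national mean's Monte-Carlo error is
well under 1%. Half-up rounding is used wherever integers are formed from
targets; proportional integerization uses the largest-remainder rule with
deterministic (first-index) tie-breaking. A 1e-9 epsilon guards coverage
comparisons against floating-point artifacts (0.2 × 1000 = 200.0000…3).
Degenerate inputs — empty strata, zero carrying capacity, empty harvest
pools, total mortality — are all defined and tested.

## Known limitations

* The published study parameters under-determine the projection: the
  original analysis's age table, breeding-pool definition, and the
  sterilization status of immigrant cats are not published. With the
  printed rates taken at face value (Binomial(3, 0.85·RUR) litters,
  truncated-Gaussian litter sizes, 65%/15% mortality, 50% females), the
  implied growth is 1.1–1.7 viable recruits per unsterilized adult per
  year, so a maintained stock coverage below ~86–91% cannot produce
  population decline, and the constant flow balance (109,000 in / 52,000
  out) floors any declining trajectory near 0.2–0.4M cats. The engine
  reports what these rates actually imply rather than tuning hidden
  parameters to match published trajectories; the annual-rate policy mode
  documents how far the campaign-effort reading closes the gap.
* Flows are constant; no density dependence below K; no spatial movement
  between strata; no genetics; catastrophes are uncorrelated across strata.
* The reproductive-potential classification is an input; the package does
  not model climate.
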
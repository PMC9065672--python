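# Methods

## Scope and data situation

The package re-implements, end to end, an analysis of how actor groups
enable or block farmers' uptake of three sustainable-intensification
measures (small landscape elements `FoA1_3`, farm-level efficiency `FoA2`,
direct sales `FoA4`) in a peri-urban case-study region with 284 dairy and 71
fruit farms (27 arable farms in the region are excluded from all analyses).
None of the original micro-data (farm accounts, CAP payment records, parcel
maps, interview matrices) are public. Everything the pipeline consumes is
therefore synthetic, generated to match the published summary structure:
categorical farm marginals, actor priors, importance ranks, and baseline
node distributions, all frozen in `siactors.tables`.

Several printed distribution rows do not sum to 100% (fruit location
30/57/34; dairy size 26/58/17; the fruit consumer prior 28/37/38; subsidies
64/16/17; one regulations row). All categorical rows are renormalized on
load, preserving ratios, with a warning when the deviation exceeds rounding
noise.

## Synthetic farm population

`generate_farm_population` draws, per sector, the six farm/farmer
characteristics from the printed per-sector marginals. Two modes:

* **quota** (default): largest-remainder apportionment per attribute, so
  every marginal is met within 1/n at the configured population size; ties
  in remainders break by listed class order. Innovativeness is pinned at
  exactly `round(0.10·n)` intrinsically innovative farms per sector, the
  remainder split neutral/no in the printed proportions.
* **bernoulli**: independent per-farm draws; unbiased but noisy, for
  stochastic replication studies.

Attributes are assigned independently of one another, with two deliberate
exceptions: initial direct-sales status is allocated with a configurable
odds multiplier (default 2.0) toward close-to-village farms, reproducing the
reported spatial pattern; and coordinates are generated *conditional on* the
assigned location class. Each farm is scattered around one of four widely
separated village centers at a distance drawn from its class band (close
0.5–3, medium 8–14, remote 22–35 distance units). Because the bands are
separated by gaps wide relative to their spread, re-classifying the
distances to the nearest center with 3-class natural breaks
(`classify_locations`) recovers the assigned classes — the published
workflow's classification step is thus executable and self-consistent on the
synthetic geography. The real geography is not reproduced.

Farm size in hectares is drawn uniformly within per-sector class bounds
(dairy 5–25/25–60/60–150 ha, fruit 1–5/5–15/15–60 ha; configurable — the
source states no within-class distribution). The CAP identity `size_ha =
basic_payment / 260 €/ha` is exposed as `farm_size_from_payment`.

`jenks_breaks` is the exact Fisher dynamic program (O(k·n²)) minimizing
within-class sum of squared deviations; ties prefer the earlier cut, placing
tied values in the lower class.

## Influence network

Influence levels none/low/high/mandatory map to edge weights 0/1/2/3 —
an equal-step ordinal coding; the source gives the scale but no numbers.
"None" creates no edge. Indicators: weighted in/outdegree, and betweenness
as unnormalized counts of ordered-pair shortest paths through a node with
fractional credit among multiple shortest paths. Shortest paths are
hop-count (unweighted): the influence weights are ordinal strengths, not
distances, so treating them as path costs would be unjustified.

The empirical matrix is unavailable; `data/influence_matrix_synthetic.csv`
is a synthetic reconstruction consistent with the published qualitative
findings (farmers highest weighted indegree on every topic; for direct
sales, farmers also highest outdegree and betweenness; consumers moderate
throughout). Tests assert those orderings, never exact values.

## Belief-network engine

Small dense networks in linear probability space. `infer_marginal` runs
variable elimination with a min-degree ordering; correctness does not depend
on the ordering (factors are multiplied exactly), and the engine is tested
against `enumerate_joint`, a full-joint summation oracle, to 1e-9 on random
networks. Soft (virtual) evidence is supported on root nodes only, as prior
replacement — exactly what scenario runs need, since "neutral" group
attitudes are distributions rather than observed states. Evidence with zero
probability raises. CPT rows must sum to 1 within 1e-9. Networks serialize
to JSON with CPT rows row-major over parents in listed order.

## The SI model

### Structure

Per sector, 24 nodes: 7 actor roots (Retail, NGOs, Network, Labels,
Province, NL&EU, Consumers; Labels has no unsupportive state), 6
characteristic roots, Subsidies and Regulations (children of Province and
NL&EU), and per measure an advice, an intention, and an uptake node.
Intention parents are advice + Subsidies + Regulations (for `FoA1_3` and
`FoA2`) or advice + location (for `FoA4`), plus intrinsic attitude,
innovativeness, age, successor and size. The published figure's exact edge
set is not fully enumerable from the text; this assembly rule is the
documented reconstruction, and no further edges are guessed.

The printed baseline tables list Regulations per measure, with nearly
identical rows; the node count fixes a single Regulations node, so its
calibration target is the mean of the printed rows per sector.

### Actor ranking

The actor-importance table gives per-measure ranks, with "Farmers" mapped
onto the Network node and "Farmer organizations" onto NGOs (the two tables
in the source use different rosters; the mapping is configurable through the
roster objects). The printed ranking contains ties (e.g. Retail and Labels
share a rank for `FoA1_3` and `FoA2`); the rank-order elicitation needs a
strict order, so ties are broken deterministically by table row order:

* `FoA1_3`: Province, NL&EU, Retail, Labels, Network, Consumers
* `FoA2`: NL&EU, Retail, Labels, Network, NGOs
* `FoA4`: Network, Consumers, Retail, Province, Labels

### CPT generation

Full tables over up to eight parents cannot be elicited cell by cell; the
quantification is generated functionally:

* **Advice** (states positive/negative):
  `P(pos | states) = clamp(b_m(s₁) + Σ_{k≥2} sign(s_k)·δ·γ^(k−2), ε, 1−ε)`
  with sign(supportive)=+1, sign(neutral)=0, sign(unsupportive)=−1. The
  geometric decay γ encodes diminishing importance down the ranking. The
  baseline map `b_m` is per measure — each measure's top-ranked actor sets
  that measure's baseline — with a fixed supportive/unsupportive spread of
  ±0.25 around the neutral level. (A single baseline map shared across the
  three measures cannot reproduce the three printed advice marginals
  simultaneously for the fruit sector within 0.01; the per-measure baseline
  is the package's resolution and matches the per-measure phrasing of the
  elicitation protocol.)
* **Policy nodes**: a base distribution whose log-odds shift toward "high"
  by `policy_strength` (default 0.5) per supportive parent and away per
  unsupportive parent.
* **Intention**: additive log-odds over ordinal codes (+1/0/−1; successor
  and advice ±1) with nonnegative weights. Defaults: advice 1.0, intrinsic
  attitude 1.2 (stakeholders judged the farmer's own attitude the prime
  driver, so it outweighs advice), innovativeness 0.6, location (FoA4 only)
  0.5, age 0.4, successor 0.4, subsidies 0.4, regulations 0.4, size 0.3.
  The positive weights encode the reported directions: young > old,
  successor > none, innovative > not, larger > smaller, close > remote for
  direct sales only.
* **Uptake**: `P(yes|intention) = π₁` (positive) or `π₀` (negative) with
  `π₁ > π₀` per measure per sector; intention and uptake marginals differ in
  the printed baselines but no mechanism is given, so the two-parameter link
  is the minimal model.

Nonnegative weights, `δ > 0` and `b(s) ≥ b(n) ≥ b(u)` make the whole chain
monotone: making any actor more supportive can only raise advice, intention
and uptake. This is the property the scenario classes rest on.

### Calibration

`calibrate(sector)` fits, in order: the two policy base distributions
(iterative proportional fitting of the prior-averaged marginal), the
per-measure advice baseline level (bisection; the marginal is monotone in
the level), the per-measure intention intercept (bisection with inference in
the loop), and the per-measure `(π₁, π₀)` (closed form at a default gap of
0.5, clamped). Each stage is a deterministic 1-D solve, so the procedure is
reproducible with no randomness. If the staged result were ever worse than
the starting point in summed squared deviation, the starting parameters are
returned; targets already met return the initial parameters untouched. At
the printed targets the achieved maximum absolute deviation is ~1e-11 for
both sectors (criterion: 0.01, the print precision).

Parameter identifiability holds only at the level of the targeted
marginals: distinct (δ, γ, weights) can produce the same nine baselines.
Tests therefore check recovery of *marginals*, not of raw parameters.

## Scenarios

Group→attitude assignments use degenerate priors for supportive and
unsupportive; "neutral" leaves the baseline prior in place (Labels and
Consumers have non-uniform baselines, so neutrality must not overwrite
them). Labels, lacking an unsupportive state, is set to its least
supportive state (neutral) when its group is forced unsupportive. Percent
change is relative, `100·(p − p₀)/p₀`, against the calibrated model's own
baseline by default; the published input-adoption row (dairy 29/45/11,
fruit 14/33/9) is available via `baseline="observed"` since the source is
ambiguous about its reference (and about relative vs percentage-point
changes). Classes: all three deltas > 0 → `S_plus`; all < 0 → `S_minus`;
exactly zero everywhere → `none` (a sentinel outside the published
three-class scheme, needed for the null scenario); otherwise `T` — zeros
inside a mixed vector do not block `T`, matching published rows containing
0% entries.

The published percentage magnitudes depend on the unavailable supplementary
quantification and are deliberately not reproduced; what the package
validates instead is the sign structure (all-supportive is `S_plus` in both
sectors, all-unsupportive `S_minus` for dairy) and the bracketing
`uptake(all supportive) ≥ baseline ≥ uptake(all unsupportive)` for every
measure, sector and farm-characteristic combination.

`spatial_impact` conditions the network on each farm's location, size, age,
successor and innovativeness, computes uptake under the two extreme
scenarios, and writes the difference per farm (GeoJSON); inference is cached
per characteristic combination.

## Efficiency-measure scoring

The FoA2 proxy: for each of 12 measures, the threshold is the lower 10%
quantile of the country-level pool on the measure's favorable scale
(values negated for `lower_is_adoption` measures — the source does not state
per-measure directions, so each measure carries an orientation flag); a farm
on or beyond the threshold (≥, boundary counts as adoption) adopts; counts
are summed per farm and averaged per sector. The quantile uses linear
interpolation between order statistics (the common software default; none is
specified). The 12 default measures are a documented synthetic stand-in for
the restricted supplementary list.

A subtlety the tests respect: an *in-sample* empirical decile threshold
marks ~90% of the pool as adopters by construction, whatever the data.
Genuine recovery of a generating adoption prevalence is therefore validated
out-of-sample — thresholds from a large reference pool, scoring on a fresh
sample — with a quantile aligned to the generating mixture, and tolerances
propagate binomial noise from both samples. The real national averages (2.6
fruit / 4.3 dairy measures) derive from restricted data and are not
reproduction targets; only the procedure is validated, on synthetic tables.

## Problem sizes and numerical choices

Default runs use the case-study population (355 farms); scoring validation
uses pools of 1,000–10,000 synthetic farms, comfortable for exact
binomial-error analysis. Inference tolerances: CPT normalization 1e-9;
engine-vs-oracle agreement 1e-9; calibration tolerance 0.01 (print
precision). Clamping bound ε = 0.02. All randomness flows through
`numpy.random.default_rng` seeded from the relevant config; quota-mode
population generation is fully deterministic given the seed.

## Known limitations

* Farm characteristics are sampled independently (except the direct-sales
  location preference); real populations correlate age, size, succession
  and location. Passing tests show the pipeline reproduces *marginal*
  structure, not joint structure.
* The advice/intention CPT families are parametric reconstructions; the
  original cell-level quantification is unavailable, so scenario magnitudes
  are model-specific even though directions are robust.
* The influence matrix is synthetic; only qualitative orderings are
  meaningful.
* The synthetic geography is schematic (four village centers, uniform
  angular scatter); spatial results illustrate the mechanism, not the map.
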
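# Methods

This note documents the models implemented in `ballastflow`, the choices
made where the design was genuinely open, and what the test suite does and
does not establish.

## Per-trip introduction risk

The relative risk that a single voyage introduces a non-native species is

    P⁽ᵗ⁾ = (1 − exp(−λ·D)) · exp(−μ·Δ)

- `λ` (default 3.22 × 10⁻⁶ per metric ton) — species introduction potential
  per unit ballast discharge. The default is calibrated so that a 500,000-ton
  discharge on a zero-duration trip has risk 0.8.
- `μ` (default 0.02 per day) — daily mortality of organisms in the ballast
  tank; long voyages carry fewer survivors.
- `D` (metric tons) — expected ballast discharge of the voyage.
- `Δ` (days) — voyage duration, whole-day resolution from the arrival and
  departure dates (fractional days are accepted if the input provides them).

`P⁽ᵗ⁾` is a *relative* ranking metric, not a calibrated probability of
invasion; the pipeline deliberately makes no claim about absolute risk
magnitudes.

## Expected discharge: a hurdle model

Discharge behaviour is strongly type- and size-dependent, and most port
calls release nothing. The estimate is therefore a hurdle expectation

    D = Z_k · W_GWT

- `Z_k` — fraction of non-zero releases for vessel type `k` (9-category
  taxonomy), estimated by counting on the *unfiltered* record set: validity
  filtering removes zero-discharge records, so computing `Z_k` on valid
  records alone would trivially give 1.
- `W_GWT` — conditional (given a release happens) discharge volume,
  predicted from (vessel type, gross weight tonnage) by a regressor fitted
  to the valid records only, with a 70/30 train/test split and the held-out
  R² reported. The default backend is a 200-tree random-forest ensemble;
  anything exposing `fit`/`predict` can be plugged in. Predictions are
  clipped at zero from below; no upper clip is applied, because tank
  capacity is not known at prediction time.

Whether `W_GWT` targets the conditional mean or some other functional is an
open question in this model family; documenting `D` as "expected discharge
under a hurdle model" assumes the conditional-mean reading.

Voyage ship types arrive in a richer source taxonomy and are mapped to the
9 categories by an explicit `TypeMap`. A voyage whose mapped type is absent
from the discharge data falls back to a pooled (all-types) frequency and a
type-averaged volume prediction, with a logged warning — a general pipeline
must define this fallback even though a complete type map never triggers it.
The pipeline also routes types with fewer than two valid records to the
pooled fallback rather than aborting the fit.

## Aggregation

Trips on a pathway are assumed independent, so risks combine by the union
rule `P_{i→j} = 1 − Π_t (1 − P⁽ᵗ⁾)`, and a port's aggregated risk takes the
same product over its *distinct source ports* (the only reading of the
port-level formula under which the pathway risks are used coherently; the
index in some published statements of the formula is ambiguous). Complement
products are computed as sums of `log1p(−p)`, so risks down to ~10⁻³⁰⁰
survive aggregation rather than being flushed to zero. The independence
assumption is documented, not corrected for: repeated voyages of the same
ship on a route are positively correlated in reality.

## Pathway exclusions and environmental filtering

- **Round trips** (origin = destination) stay in trajectory sequences —
  they shape movement contexts — but never form a pathway: a self-loop is
  not a transfer between ports.
- **Ecoregion exclusion.** Pathways whose endpoints share an ecoregion, or
  lie in ecoregions declared adjacent, are removed: such transfers could
  plausibly occur by natural dispersal. The adjacency relation is an
  explicit input (made symmetric and reflexive); no operational definition
  of "neighboring" is guessed.
- **Arctic membership** is a per-port boolean in the port table. A loader
  hook (`arctic_flags_from_polygon`) derives the flags from a user-supplied
  boundary polygon, counting boundary ports as Arctic.
- **Tolerance groups.** Six groups cross thermal bounds for marine
  invertebrates (|Δt| ≤ 2.9 °C, ≤ 9.7 °C) with salinity bounds for
  freshwater-stenohaline, marine-stenohaline and euryhaline species
  (|Δs| ≤ 0.2, 2, 12 ppt). Filtering uses annual means only — no
  seasonality, temperature–salinity interaction, plasticity or adaptation.
  Retention is monotone in the tolerance partial order, which the tests
  verify as the nesting of the six filtered networks.

## Higher-order network extraction

Ship movements are path-dependent up to roughly fifth order, so the
dispersal network conditions ports on recent history. Extraction works in
four deterministic phases:

1. **Statistics.** For every context of length 0…(max_order − 1), tabulate
   the conditional next-port distribution over all trajectory transitions
   (self-transitions excluded as edges, retained in history).
2. **Acceptance.** A context extends an already-accepted parent iff its
   support reaches `min_support` and the Kullback–Leibler divergence (nats)
   of its next-port distribution from the accepted parent's exceeds
   `divergence_threshold / (order × support)`. The 1/support scaling keeps
   well-supported small deviations and discards noisy ones: under a purely
   first-order process, 2·support·KL is asymptotically chi-squared, so the
   acceptance event `KL > T/(order·support)` behaves like a chi-square test
   with critical value `2T/order`. The default `T = 25` puts the order-2
   false-positive rate near the 5% level for typical out-degrees (~10–15
   observed next ports). The divergence statistic always uses transition
   *counts* — the sample size that governs its distribution — in both
   weighting modes.
3. **Assignment.** Every transition contributes weight to exactly one rule:
   the accepted context with the longest suffix match to its history.
4. **Pruning.** A higher-order rule whose final weight falls below
   `min_support` hands its weight back to its parent rule instead of being
   dropped, so pruning never loses flow. First-order rules are always kept,
   leaving no dangling contexts.

Because each transition is counted exactly once, collapsing the higher-order
network (merging nodes by physical port, summing or probability-unioning
parallel edges) reproduces the first-order network exactly — the flow
conservation invariant the tests assert. Edges are wired to the
highest-order existing node whose context is a suffix of the source's
extended context (standard longest-suffix semantics). Two weighting modes:
`count` (weights are trip counts; `min_support` is an integer, default 1)
and `risk` (weights are union-aggregated per-trip risks; `min_support`
defaults to the conventional 10⁻³ non-trivial-pathway cut). No smoothing is
applied to unobserved next ports; divergence is computed over observed
support only, with an unobserved-in-parent next port counting as infinite
divergence.

The exact acceptance test used by the algorithm family this follows is not
fixed in the literature this model draws on; the measure and its scaling are
therefore config-exposed rather than asserted as the original's constants.

## Random walk, clustering, propagation

- **Ranking.** A walker follows outgoing edges with probability `damping`
  (default 0.85, the classic choice; the reset probability is a documented
  default, not an empirical claim) and otherwise resets uniformly over
  ports. On a higher-order network the reset mass enters at first-order
  nodes — the only context-free choice — and node probabilities are summed
  per physical port before ranking. Dangling-node mass is routed to the
  reset distribution. Power iteration stops when the L1 change falls below
  `tolerance` (default 10⁻¹⁰); non-convergence raises with the residual.
  Rank ties break lexicographically by port id so tables are reproducible.
- **Clustering.** The default backend is an in-package greedy agglomerative
  search minimizing a two-level map-equation description length (node visit
  rates from the damped walk; module exit flows without teleportation).
  igraph's Infomap — the same objective family — is available as
  `backend="infomap"` and doubles as an independent cross-check in the
  tests, alongside exhaustive-search verification on planted two-block
  instances. Denser within-cluster connectivity is the objective's
  direction, not a guarantee; isolated nodes get singleton clusters.
- **Propagation.** `propagate_steps` pushes unit mass from a start node
  through k applications of the row-normalized transition operator,
  reporting per-port reach, per-edge flows, flows above a report threshold,
  and the mass absorbed at dangling nodes (reported, never silently lost).

## Trends, projection, rewiring

Yearly metrics (voyage count, total DWT, DWT per voyage, pathway count,
recipient-port count, mean pathway risk, hub in-pathway count) are fitted by
OLS on year — a deliberately minimal functional form — with a two-sided
slope p-value. Projections extrapolate the line with both a 95% confidence
band on the mean and a 95% prediction interval, labelled, and carry an
`is_prediction: False` flag: they are trend extrapolations, not forecasts.
Study years run May 1 → April 30 and are labelled by the starting calendar
year.

Rewiring repeats: pick a pathway uniformly at random, keep its strength,
re-attach its target to a port drawn with probability proportional to its
*current* number of incoming pathways (recomputed after every accepted
move — the dynamic rich-get-richer mechanism), never equal to the pathway's
own source, until the distinct recipient count hits the target. Ports with
zero incoming pathways have zero attachment weight and can only lose
recipients. A draw that would duplicate an existing (source, target) pair is
rejected and redrawn by default ("forbid"), which conserves the pathway
count and the strength multiset exactly; a "merge" policy
(probability-union of strengths) is available. Under "forbid" the recipient
count cannot drop below the largest per-source out-degree; the pipeline
clamps a trend-derived default target to that floor, and an explicit
infeasible target raises. The default target is read off the fitted
recipient-count trend at the projection horizon unless overridden.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical features the analysis relies on:
heavy-tailed route frequencies (Zipf port attractiveness, exponent
`route_concentration`, default 1.0), vessel-type-dependent non-zero
discharge frequencies (defaults graded 0.20–0.75 by how routinely each type
ballasts), discharge volumes piecewise-linear in GWT (full slope to a
30,000-ton knee, 30% beyond — simple and recoverable by any reasonable
regressor) under multiplicative lognormal noise (default σ = 0.10), capped
at a capacity of half the GWT; positive integer trip durations (1–14 days);
geometric trajectory lengths (mean 20 voyages/ship/year — no length
distribution is available to copy, so this is a modelling default); and
planted second-order movement rules that override the first-order kernel
when their context matches. Every output is a pure function of the config;
a single seed drives independent sub-streams per generator (ports,
trajectories, ballast) so modules can be regenerated in isolation.

It does **not** reproduce real geography, port names (outside the
five-port worked example, whose coordinates are approximately real but
whose ecoregion/environment attributes are synthetic placeholders), traffic
volumes, seasonal structure, or fleet composition. Passing recovery tests
therefore demonstrates the estimators' correctness under the assumed
generative structure, not their performance on real shipping data.

Recovery tests that require every planted context to have support far above
`min_support` use a uniform route kernel (`route_concentration = 0`), since
under a heavy tail an arbitrary port pair can be arbitrarily rare. Scales
used by the acceptance suite: 10,000 records for discharge-frequency
recovery (2 binomial SE), ~1,000 valid records at 10% noise for the
regression (held-out R² ≥ 0.90), ~5,800 transitions over 10 ports for
higher-order rule recovery (3 SE) and the first-order null (≤ 5% of observed
order-2 contexts falsely accepted), and 1,000 replicates for the 95%
projection-band coverage check ([0.93, 0.97]); the band checked for
coverage of the true line is the mean-confidence band, which is the one
with exact nominal coverage of the mean.

## Numerical and interface choices

- Complement products in log space; probabilities stored as probabilities
  (percent rendering is formatting only).
- OLS via statsmodels; its QR solve agrees with the textbook centered
  closed form to ~10⁻¹⁰ relative, which is what the oracle tests assert.
- Record rejections (invalid rows, unknown ports, missing environments,
  invalid ballast records) carry machine-readable reason codes in a
  `RejectionLog`; nothing is silently dropped.
- CSV dialects tolerate extra columns and `#` provenance headers; a missing
  required column is a hard error naming the column. Networks export to
  GraphML and edge-list CSV; propagation traces also to GeoJSON (points per
  reached port per step) in place of map cartography, which is out of scope.
- Exported tables carry a provenance header (config hash, seed, stage).

## Known limitations

- Independence of trips within a pathway is assumed, not tested.
- Risks are relative; no absolute calibration, no species-specific biology,
  no biofouling pathway.
- Ecoregion adjacency, Arctic membership and environmental attributes are
  inputs; the package performs no geocoding or atlas retrieval.
- The greedy map-equation search is a local optimizer; on large networks it
  can stop short of Infomap's optimum (both backends must pass the planted
  partition tests).
- Linear trends over six observation years extrapolated 15 years are
  sensitive to the functional-form assumption; the projection output says
  so explicitly.
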
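# Methods

## The system being modelled

A regional subsidy scheme accommodates spring-staging geese on farmland:
fields are ranked by suitability, a fixed budget buys whole fields into
refuge status at per-hectare rates, and the outcome is audited with a
dropping-count survey comparing refuges against matched non-refuge
controls. The package implements each stage as a separate module and, in
place of the non-public cadastral and GIS inputs, a synthetic-landscape
generator that reproduces the statistical structure the analysis relies
on. Everything downstream of a `(config, seed)` pair is deterministic.

## Synthetic landscapes

Fields are non-overlapping axis-aligned rectangles jittered on a square
grid (real parcel shapes are irrelevant to the statistics in play, and
rectangles keep edge-distance geometry exact). Defaults emulate the
study region: 1008 fields, areas drawn from a lognormal moment-matched
to mean 3.80 ha / SD 3.14 ha and truncated by rejection to
0.20–14.41 ha, 26 % pasture, a 16 km extent. Non-pasture parcels are
stubble (30 %), new-sown cereal (20 %) or other/ineligible (50 %) — a
plausible spring crop mix in a cereal-dominated mosaic; only the pasture
fraction is an observed quantity. Roost 1 is a coastline along the
western edge of the extent; the remaining roosts (default 3) are
interior lake points. All field–roost distances are measured from the
field centroid (the representative point used consistently throughout;
"nearest edge" would be an equally defensible convention).

Historic goose use is a per-season binomial over a 4-season window with
success probability `0.8·exp(−d/4000 m)`, declining with roost distance
— enough to make the historic-use criterion informative and spatially
structured without modelling goose behaviour.

## Dropping deposition

Expected intensity at the centre of field *f* (droppings m⁻²):

```
λ(f) = base(f) · m(crop_f) · exp(−d_roost(f)/d0)
```

with `base` = 3.56 for refuge fields and 0.27 otherwise (the observed
season-accumulated refuge/non-refuge densities), crop multipliers
m(pasture)=1, m(stubble)=m(new-sown)=0.45, m(other)=0.05 (geese defecate
more while grazing grass than grain), and decay scale `d0 = 5000 m`.
The exponential form is a modelling choice; the data constrain only a
negative monotone relation. Within a field, intensity declines linearly
from the centre value to `edge_gradient` (default 0.5) times the centre
value at the boundary, via the relative edge depth
`t = d(p, boundary)/d(centre, boundary)` clipped to [0, 1]. Setting
`decay_scale=inf`, `edge_gradient=1` and unit crop multipliers yields a
flat surface, the degenerate case used to verify design unbiasedness.

Survey counts are Poisson with mean = intensity at the circle centre ×
circle area (a negative-binomial overdispersion hook exists but is off
by default; no noise model is observable from the published summaries).
Dropping persistence is treated as full-season accumulation — the
3–4-week visibility window is not decayed.

## Ranking and allocation

Criterion ranks use average ties so rank sums stay comparable; the
connectivity criterion is the summed area of other fields with centroids
within 1000 m (radius configurable) — monotone in local field
aggregation, which is all the downstream analysis needs. Rank-sum ties
break by smaller roost distance, then lexicographic field id: the
ordering must be a deterministic input to allocation.

Allocation is a greedy pass in effective-priority order. A candidate's
effective score is its rank sum minus `adjoin_bonus` once any neighbour
(boundary-to-boundary distance ≤ 20 m) has been selected; the
best-scoring candidate is selected iff its whole-field cost fits the
remaining budget, otherwise it is permanently skipped. Whole fields only
— partial subsidies do not occur. With `adjoin_bonus = 0` and uniform
costs this provably reduces to the top-k of the ranking, the limit used
in tests. The bonus mechanism is this package's operationalization of
the authorities' qualitative preference for adjoining refuges; nothing
quantitative about that preference is published. Farmer participation
(who actually applies) is deliberately not modelled.

Merged refuge units are connected components under the same 20 m
adjacency relation (STR-tree prefilter, `networkx` components; tests
check against an O(n²) transitive-closure oracle). Synthetic parcels
are sparser than real cadastral fields, so few adjacencies arise at
study scale under the defaults — the merging machinery is exercised on
dense hand-built grids in the test suite.

## Survey design

Circle 1 at the representative centre; circles 2 and 3 on the segment
from the nearest boundary point to the centre at ⅔ and ⅓ of the
edge-to-centre distance. "Nearest edge" is the nearest point of the
exterior ring to the centroid. A field whose centre is within one circle
radius of the boundary raises a protocol-infeasibility error naming the
field.

Controls are sampled without replacement from non-refuge fields whose
centroids lie within 2 km of any refuge polygon, with weights
`w_j = 1/(1 + |P_j − P̄_r|/P̄_r)` (P = perimeter, P̄_r = mean refuge
perimeter): bounded, symmetric, scale-free, equal to 1 for a perfect
match. The similarity weighting is undefined in any published form;
this is the package's choice.

## Evaluation

* Density comparisons: pooled-variance Student *t* by default (Welch
  behind `test="welch"`), two-sided, per crop stratum; no cross-crop
  comparisons (defecation rates differ by crop) and no multiple-testing
  correction. Identical constant groups return t = 0, p = 1; constant
  groups with different means raise a degeneracy error rather than
  return an infinite statistic.
* Spearman correlations via average ranks with the large-sample t
  approximation for p (n runs to hundreds; exact permutation would add
  nothing).
* Adjoined refuges are analysed as merged units: grouped area, mean of
  surveyed member densities, minimum member roost distance.
* `estimate_efficiency` carries areas in km² and densities in m⁻²;
  conversions are exact constants and rounding happens only in display.

## Replicate experiments (`refugia.scenarios`)

`correlation_replicate` runs landscape → ranking → allocation → survey
on a 260-field / 8 km landscape with a 620 000 NOK budget, scaled so the
allocation yields on the order of 78–95 merged units — the sample size
of the reference field campaign; at the full study scale the default
budget selects about twice as many fields. Every member is surveyed with
Poisson noise and the unit-level Spearman rho of density vs roost
distance is returned.

`recovery_replicate` runs the default 1008-field pipeline (90 refuge +
138 control surveys) and compares the survey-estimated captured share
with the same bookkeeping evaluated at the noise-free expected densities
of the same surveyed fields. That truth definition isolates what the
estimator can be held responsible for — design, count noise, averaging —
from the landscape-extrapolation step (applying the control-group
density to all non-refuge grassland) that is common to both values and
whose bias depends entirely on landscape geometry the generator cannot
claim to reproduce.

## Numerical and degenerate-input choices

* Per-stage seeds are `sha256(master_seed:stage_name) mod 2^31` — stages
  never share a stream, and reruns are byte-identical.
* Budget feasibility uses a 1e-9 slack on cost comparisons to absorb
  float accumulation; a budget below the cheapest eligible field returns
  an empty refuge set with a warning status, not an error.
* Fractile partition of n fields into k slices: sizes `⌈n/k⌉`/`⌊n/k⌋`
  with the remainder on the earliest (highest-priority) fractiles.
* Field-mean intensity uses a deterministic interior grid quadrature;
  it is only used for diagnostics, never in the survey pathway.

## What passing tests do and do not show

The generator reproduces the *marginal* structure the analysis assumes —
field-size distribution, pasture fraction, refuge/non-refuge intensity
contrast, negative density–distance dependence — not the actual spatial
configuration of any real region: parcel shapes, cadastral adjacency,
roost positions and farmer participation are all synthetic. Emergent
quantities that depend on that unavailable geometry (observed fractile
coverage of real subsidy years, the field t statistics, the −0.54
correlation magnitude, refuge size statistics) are therefore exercised
as sign, monotonicity and invariance properties rather than point
reproductions; the closed-form efficiency bookkeeping, which takes the
published summary inputs directly, is reproduced as printed.
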
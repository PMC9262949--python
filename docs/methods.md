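# Methods

This note documents the models, estimators, default parameters and design
choices behind `firewebs`, and what the synthetic-data tests do and do not
demonstrate about real survey data.

## Node model

A food-web node is one ontogenetic stage of an animal, one constituent part
of a plant, or one non-living resource class — not a species.  The registry
enforces: unique node ids (`<species_id>.<stage>`), taxonomy non-null down
to the identified rank, and a body size for every stage, observed or not.
Stages that are resource- and consumer-indistinguishable (e.g. parasitoid
egg + larva + pupa) are lumped into a single node; stages that do not occur
in the terrestrial habitat (e.g. aquatic larvae) are excluded, and a species
whose every stage is excluded is an error rather than a silent drop.
Aggregate producer/saprophyte groups (algae, moss, lichen, mycorrhizae,
saprophytic fungi and bacteria, nematodes) are first-class single nodes
without biomass.  Carcass size classes default to decade (×10) mass bins
from 1 mg to 100 kg — eight bins whose edges tile the span exactly; the
partition is configurable.

Volumetric body masses map measured length × width × depth onto an
idealized solid and multiply by a tissue density of 1.1 g/mL.  Shape
factors (volume = factor · l · w · d): ellipsoid π/6, cylinder π/4
(length × diameter × diameter), rectangular prism 1, hemisphere and
elliptic cone π/12.  The hemisphere/cone conventions are our own — sources
that name these shapes rarely state axis conventions — and are the halved
and one-third ellipsoid volumes on the same measured axes.

## Plant biomass (kg/ha)

*Trees.*  Above-ground biomass uses the national-scale DBH-only form
`AGB = exp(β₀ + β₁ ln DBH)` (DBH cm, AGB kg).  Tissue ratios
(foliage, coarse roots, stem bark, stem wood) use `exp(β₀ + β₁/DBH)`,
hardwood/softwood-specific; predicted full height is exp of a cubic in
ln DBH.  The four categories: intact alive = AGB·(1 + r_roots); intact dead
= AGB·(1 − r_foliage + r_roots); damaged trees scale each tissue biomass by
the proportion remaining — measured height / predicted full height, clipped
to [0, 1] — summed, minus foliage if dead.  A damaged tree measured taller
than its prediction is treated as intact.  Unidentified trees fall back to
Pinaceae coefficients (the dominant family in the system the pipeline
emulates).  `pipeline.default_allometry()` ships a documented two-group
(Pinaceae/Quercus) coefficient table; real analyses should substitute the
full species-group table for their system.

*Coarse woody debris.*  Pieces intersecting the transect line with
intersect diameter ≥ 12.5 cm and length ≥ 1 m are tallied.  Volume is the
equal-weight frustum `V = (π/8)(D_S² + D_L²) l / 10⁴` (diameters cm,
length m, V m³); when D_S = D_L this is exactly a cylinder, which the tests
assert term-for-term.  Volume density per piece is
`(π / 2L_t)(V / l_i) · f` with combined transect length L_t = 100 m and
area conversion f = 10⁴; mass density multiplies by 1000 kg/m³ × specific
gravity × decay correction.  The community specific gravity is an
abundance-weighted mean (0.372 × 0.947 + 0.566 × 0.053 = 0.382 for a
pine-dominated stand with a minor oak component).  Decay corrections per
class 1–5 default to {1.0, 1.0, 0.85, 0.55, 0.35} — a monotone,
literature-typical profile shipped as a required, overridable config table.
Whether the volume-density conversion is applied per piece and summed or to
pooled V/l is immaterial (it is linear); we apply it per piece.

*Understory plants.*  Box quadrats yield mass-to-volume ratios per species
and tissue type.  A species with ≥ 3 measurements uses its own mean;
sparser species pool upward — congeners first, then family, then the whole
table — and the pooling level is recorded on the output.  Ground-cover
transects give cover × height volumes per quadrat; biomass = pooled volume
/ sampled area × ratio, rescaled to kg/ha.  A taxon with no ratio even
after pooling is an error listing the taxon.

*Unidentifiable individuals.*  Plants recorded only at genus/family rank
are assigned species identities by bootstrap: each of `reps` (default 999)
replicates draws one unburned proxy site uniformly, then assigns identities
multinomially from that site's abundance distribution of the focal taxon;
the output is per-species mean counts with bootstrap SEs.

## Animal densities

All estimators are deterministic conversions; the hierarchical abundance
models some methods require (spatial capture–recapture, N-mixture,
Royle–Nichols, removal) are upstream of this package and enter as abundance
tables.  Invertebrate densities are ind/m², vertebrates ind/ha; every
output row carries a unit tag and mixing tags raises.  Conversion to the
common per-m² basis happens once, at the registry boundary, when biomass is
attached.

Default per-site sampling geometry (areas re-derivable from the protocol):
six 10-cm soil cores 0.0471 m²; three 5-m-diameter hard-substrate/sweep
cylinders 58.9 m²; twenty 1-m² ground-cover quadrats 20 m²; three 0.25-m²
box quadrats 0.75 m²; 90 × 90 m trapping/reptile grids 8,100 m²; tree and
shrub transect bands 1,500 and 500 m².  The bird point-count divisor is the
protocol's printed 15,708 m²; note this equals 2·π·50² rather than the
π·100² per station the radius suggests — we keep the printed value as the
default and expose it in config.

Method specifics: Berlese counts are scaled from the processed subsample to
the full box sample by mass (assuming arthropods are homogeneously
distributed within a plant sample), divided by box plant volume, and
multiplied by the transect plant-volume density.  Canopy-fog densities are
count / tarp area × habitat cover area, with treatment means over the 3 (or
6) fogged sites.  Black-light traps yield activity densities only; a
species caught nowhere else is paired with an ecological analog — deepest
shared taxonomy, then smallest |Δ log body mass|, then lexicographic id —
that was caught at the same sites in black lights *and* an absolute-density
method, and receives analog density × mean count ratio.  A node with no
eligible analog keeps its place in the web without biomass.  Pooled
unidentifiable larvae (ant/moth/beetle bins) are partitioned among adults
of the bin's rank that lack an observed larval stage, proportionally to
adult relative abundance; the split conserves the pooled total to 1e-9
relative, and partitioned larval nodes are thereafter treated as observed.
Group-modeled vertebrates (e.g. chipmunks, snakes) are split by each
species' share of captured individuals.  Annual home ranges are converted
to seasonal by × 0.67; literature means are sample-size weighted.
Never-caught species × treatment combinations can be fixed to exact zero
with `fixed_zero` provenance.

When two methods yield densities for the same node, the method with the
greater ability to detect it (larger mean density) is kept.

## Link engine

Membership in encounter groups is a deterministic predicate over node
class, habitat tags, diel tags, taxonomy, guild and a soft-bodied flag; a
stage may belong to several groups.  The default definitions materialize
the fifteen metazoan groups (flying / nocturnal flying / diurnal flying /
non-flying invertebrates; ground-dwelling, with and without spider eggs;
soft-bodied ground; on-plants, with and without spider eggs; soft-bodied
on-plants; on-trees; reptiles; birds; small mammals; large mammals) plus
producer-part, non-living and saprophyte groups.

Compatibility clauses, applied in order: taxon blacklist, diet whitelist
(any matching taxon rank, or any whitelisted plant-part/non-living type —
part records generalize, so "eats seeds" reaches every seed node unless a
rule narrows it), then the body-size-ratio window.  Windows are inclusive
on both ends by default (ranges stated without strictness; inclusivity is
the weaker assumption) and are config-overridable per rule; the ratio basis
is body length by default, mass per rule.  A part-whitelisted plant or
non-living resource is not size-screened — size windows model prey capture.
A missing size measurement raises rather than silently failing the pair.
Unweaned mammal juveniles link only to their species' adult node.

Rules apply in sorted rule-id order with first-matching-rule provenance, so
the link set and its provenance are independent of registry and rule file
ordering.  Widening a window or adding a rule can only add links.  The
shipped rule skeleton encodes what is derivable from the documented guild
descriptions (17 spider family guilds with a web-builder fallback for
unidentified spiders, the 20–200 % web-builder and 25–75 % salticid
windows, herbivore part generalization, nectar rules, nursing, size-windowed
insectivory for birds/bats/reptiles); the full diet whitelists of a real
system are user-supplied data.

## Web assembly and trophic levels

A treatment's web contains nodes observed with positive density there,
inferred (unobserved) stages, and non-living nodes; edges restrict to
present nodes.  Pruning removes feeding nodes with no surviving resources
until a fixed point.  The fixed point is unique: prunability is monotone in
set inclusion, so the iteration is a closure operator — the suite verifies
this exhaustively over all removal orders on all digraphs with ≤ 4 nodes
and on randomized webs of up to 8.

Shortest trophic level is 1 + the fewest consumer→resource hops to any
basal node (out-degree 0).  Prey-averaged level solves the dense linear
system TLᵢ = 1 + mean over resources of TLⱼ with cannibalistic self-loops
dropped; cycles are fine as long as every node reaches a basal node (the
system is then nonsingular).  Short-weighted trophic level is the
arithmetic mean of the two, always lying between them.  Connectance uses
the directed denominator S² (all ordered pairs, self-links included), not
S(S−1)/2.  Exports: edge-list CSV and GraphML with biomass/trophic-level/
guild attributes; inferred nodes get no dummy biomass (visualization
conventions are the caller's business).

## Diversity validation

Hill numbers: q = 0 richness, q = 1 exp(Shannon), general q
`(Σ pᵢ^q)^(1/(1−q))`; non-increasing in q, equal to k for k equally
abundant species.  Sample coverage uses the singleton/doubleton estimator;
coverage is clamped to [0, 1].  Grouped validation pools methods with
overlapping species records, tallies species (stages pooled), and reports
individuals, observed richness, coverage, a percentile-bootstrap CI
(200 reps, seeded; the analytic variance is deliberately not exposed) and
Hill numbers per group × treatment.  Rarefaction/extrapolation curves are
out of scope; only the analytic estimators and bootstrap are provided.

## Synthetic campaigns and what the tests show

The generator emulates the campaign design: three treatments × 9 sites,
producers decomposed into five parts, invertebrates into egg/larva/adult
(archetypes spanning soil, ground, understory, plant-surface, nocturnal and
diurnal aerial, and bark habitats, with spider, beetle, hemipteran, moth
and fly guilds), vertebrates into juvenile/adult (small mammal, bird, bat,
reptile, large mammal).  True densities are log-normal per coarse group —
defaults ln 0.4/m² producers (σ 0.6), ln 8/m² invertebrates (σ 0.8, soil
fauna × 150), ln 3/ha vertebrates (σ 0.7) — with multiplicative treatment
effects (high severity halves producers: 1 / 0.8 / 0.5; invertebrates
1 / 0.75 / 0.5; vertebrates 1 / 0.85 / 0.6).  Counts are Poisson with mean
density × sampled area × detection scaling (default 1), keeping analytic
expectations exact; 20 % of animal larval stages are generated unobserved
to exercise the inferred-stage and larval-partitioning paths; half the
nocturnal aerial species are black-light-only to exercise the analog path.
Canopy ground truth is defined per m² of ground, with tarp intensity =
ground density × site area / fogged habitat cover, so all invertebrate
estimators share one basis.  All randomness flows from one `SeedSequence`;
per-table child generators are spawned in a fixed documented order, so any
single table regenerates stably.

Parameter-recovery checks compare treatment-mean estimates to truth via
z = (estimate − truth)/SE with SE from the 9 replicate sites.  Row-level
z's are approximately t with 8 d.f. (sd ≈ 1.15) — and only 2 d.f. for
fogging's 3 sites — so the acceptance check is per-estimator: the mean z of
each method must sit within 3 aggregate-SEs (1.15/√n) of zero.  The
acceptance script pools three replicate campaigns for this measurement.

What passing does *not* show about real data: the generator has no spatial
autocorrelation, no overdispersion (a negative-binomial option is the
obvious extension), no detection heterogeneity among species, no seasonal
turnover, and its rule file is complete and correct by construction — on
real campaigns the dominant uncertainties (model-based vertebrate
abundances, home-range transfer, diet-record completeness) enter through
inputs this package treats as given.

## Numerical choices and limitations

- Dense linear solve for prey-averaged levels: fine to a few thousand
  nodes; webs far larger would want a sparse solver.
- Ties in black-light analog selection resolve by node id so runs are
  reproducible; the choice among equally good analogs is otherwise
  arbitrary.
- Proportions in group partitioning must sum to 1 within 1e-6; partitioning
  outputs conserve totals to ≤ 1e-9 relative.
- CSV round-trips write floats with `%.17g` and read with round-trip
  precision, so registries survive serialization bit-exactly.
- The pipeline's synthetic stage sizes (8 producers, 18 invertebrates,
  8 vertebrates) are a desk-scale default chosen to exercise every code
  path; they are config fields, not constants.
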
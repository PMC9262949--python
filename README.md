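# firewebs

Quantitative food-web assembly from multi-method ecological field surveys.

Post-fire landscapes are a natural experiment in community reorganization:
the same forest, sampled across unburned, low-to-moderate and high
burn-severity treatments, supports different producers, invertebrates and
vertebrates at different biomass densities — and therefore different food
webs.  `firewebs` is a pipeline for researchers who have (or want to
prototype against) that kind of campaign: per-site survey tables from many
complementary methods (vegetation transects, box quadrats, line-intercept
dead-wood tallies, soil cores, sweep nets, canopy fogging, black-light
traps, trapping grids, point counts, camera/acoustic model outputs) and who
want per-treatment, biomass-annotated, rule-traceable food webs out the
other end.

## What it computes

**Node list.** Species are decomposed into the units that actually interact:
ontogenetic stages for animals (egg, larva/juvenile, adult), constituent
parts for plants (leaf, stem, root, seed, flower), plus non-living resources
(woody and leaf detritus, carcasses in logarithmic size classes, dung,
honeydew).  Every node carries a body size; body masses can be estimated
volumetrically (idealized solids × 1.1 g/mL tissue density).

**Biomass densities.** Per node and treatment, biomass density = mean
individual body mass × numeric density.  Numeric densities come from
method-specific estimators:

- trees: DBH allometry `AGB = exp(β₀ + β₁ ln DBH)` with tissue-type ratios
  `exp(β₀ + β₁/DBH)`, predicted full heights, and four health/damage
  categories (intact/damaged × alive/dead);
- coarse woody debris: line-intercept frustum volumes
  `V = (π/8)(D_S² + D_L²)·l / 10⁴`, converted to m³/ha via
  `(π/2L_t)(V/l_i)·f` and to kg/ha via `· 1000 · SpG · D`;
- understory plants: cover × height volumes × mass-to-volume ratios with
  taxonomic pooling (species → genus → family → all) for sparse taxa;
- invertebrates: counts / sampled area, Berlese subsample scaling, canopy-fog
  tarp scaling, black-light analog ratios for species never caught by an
  absolute method, pooled-larvae partitioning by adult relative abundance;
- vertebrates: model-output abundances divided by grid area or literature
  home range (annual ranges × 0.67 for a seasonal estimate), with
  proportional partitioning for species groups modeled jointly.

**Links.** Directed consumer → resource links are assigned by a two-stage
rule engine: *encounter* filters (named resource groups defined over
habitat, diel activity, taxonomy and palatability — flying invertebrates,
ground-dwelling invertebrates excluding spider eggs, invertebrates on
plants, birds, small mammals, ...) followed by *compatibility* filters
(body-size-ratio windows such as the web-building spider's 20–200 %
body-length prey window, diet whitelists/blacklists, part-type
generalization — a seed record extends to every seed in the system).  Rules
are data (YAML), every link records which rule and clauses admitted it, and
the whole assignment is order-independent and reproducible.

**Webs and metrics.** Per treatment: nodes present (observed with density,
plus inferred stages) are pruned to a unique fixed point (a feeding node
with no surviving resources is removed, iteratively); metrics include
S, L, potential links S², connectance L/S², and per-node short-weighted
trophic level — the mean of the shortest-path level (1 + fewest
consumer→resource hops to a basal node) and the prey-averaged level
(TLᵢ = 1 + mean TL of i's resources, solved as a linear system).

**Validation.** Hill numbers (q = 0, 1, 2) and singleton/doubleton sample
coverage `Ĉ = 1 − (f₁/n)·[(n−1)f₁ / ((n−1)f₁ + 2f₂)]` per taxonomic group ×
treatment, with percentile-bootstrap confidence intervals.

A first-class synthetic-data module generates a whole campaign (27 sites,
9 per treatment, log-normal densities, Poisson counts, known ground truth)
so every estimator can be tested for parameter recovery without any field
data.

## Worked example

```bash
firewebs run --out demo/ --seed 1
```

runs simulate → biomass → density → registry → links → assemble → validate
and writes 33 artifacts plus a manifest of SHA-256 digests (a rerun with the
same seed is bit-identical).  `demo/web_metrics.json` then contains, for the
unburned web:

```json
{"treatment": "unburned", "S": 120, "L": 767, "potential_links": 14400,
 "connectance": 0.0533, "mean_swtl": 1.742, "max_swtl": 4.0,
 "total_biomass": 105.18}
```

S = 120 nodes survived pruning, 767 of the 14,400 possible directed links
passed both filters (connectance 5.3 %), the mean short-weighted trophic
level is 1.74 (most biomass sits near the producer base) and the longest
chains reach level 4 (e.g. plant → herbivore → spider → bird).  Total
biomass falls from ≈105 g/m² unburned to ≈53 g/m² at high severity,
reflecting the generator's treatment effects.  The same library calls are
available in Python:

```python
from firewebs.pipeline import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(out_dir="demo", seed=1))
```

Each stage can be rerun separately (`firewebs links --out demo/`), consuming
the previous stage's CSV/YAML outputs unchanged.

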
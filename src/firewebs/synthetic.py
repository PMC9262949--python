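"""Synthetic survey-campaign generator with known ground truth.

Emulates the statistical structure of a multi-method burn-severity field
campaign: three treatments (unburned, low-to-moderate, high severity)
with nine replicate sites each, a community of producers decomposed into
parts, invertebrates and vertebrates decomposed into ontogenetic stages,
non-living resources, log-normal true densities with multiplicative
treatment effects, and per-method count tables drawn Poisson with mean
density x sampled area x detection scaling.

Everything is deterministic under the configured seed: child generators
are spawned from one ``SeedSequence`` in a fixed order, so regenerating a
single table is stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import links as link_mod
from .animal_density import DEFAULT_GEOMETRIES
from .registry import (
    NodeRegistry,
    NonlivingBinConfig,
    TaxonStage,
    Taxonomy,
    add_nonliving_nodes,
    node_id_for,
    volumetric_mass,
)

TREATMENTS = ("unburned", "low_moderate", "high")

#: effective trapping area of one black-light night (m^2); internal to the
#: generator — the emitted black-light tables report counts only
BLACKLIGHT_EFFECTIVE_AREA_M2 = 600.0

FOGGING_TARP_AREA_M2 = 4.5  # two 2.25 m^2 tarps
SITE_AREA_M2 = 40_000.0  # 200 x 200 m site


@dataclass(frozen=True)
class SimConfig:
    n_sites_per_treatment: int = 9
    treatments: tuple[str, ...] = TREATMENTS
    n_producers: int = 8
    n_invertebrates: int = 18
    n_vertebrates: int = 8
    #: log-scale density distributions per coarse group
    log_density_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "producers": math.log(0.4),      # individuals / m^2
            "invertebrates": math.log(8.0),  # individuals / m^2
            "vertebrates": math.log(3.0),    # individuals / ha
        }
    )
    log_density_sd: Mapping[str, float] = field(
        default_factory=lambda: {"producers": 0.6, "invertebrates": 0.8, "vertebrates": 0.7}
    )
    #: multiplicative treatment effects (high severity halves producers)
    treatment_effect: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "producers": {"unburned": 1.0, "low_moderate": 0.8, "high": 0.5},
            "invertebrates": {"unburned": 1.0, "low_moderate": 0.75, "high": 0.5},
            "vertebrates": {"unburned": 1.0, "low_moderate": 0.85, "high": 0.6},
        }
    )
    detection_scaling: Mapping[str, float] = field(default_factory=dict)
    unobserved_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.treatments) != TREATMENTS:
            raise ValueError(f"treatments must be exactly {TREATMENTS}")
        if min(self.n_producers, self.n_invertebrates, self.n_vertebrates) < 0:
            raise ValueError("richness values must be >= 0")
        if self.n_sites_per_treatment < 1:
            raise ValueError("need at least one site per treatment")
        for method, det in self.detection_scaling.items():
            if not 0 < det <= 1:
                raise ValueError(f"{method}: detection scaling must be in (0, 1]")
        if not 0 <= self.unobserved_fraction <= 1:
            raise ValueError("unobserved fraction must be in [0, 1]")

    def detection(self, method: str) -> float:
        return self.detection_scaling.get(method, 1.0)

    def sites(self) -> dict[str, str]:
        """site id -> treatment, e.g. U1..U9, M1..M9, H1..H9."""
        prefix = {"unburned": "U", "low_moderate": "M", "high": "H"}
        return {
            f"{prefix[t]}{i + 1}": t
            for t in self.treatments
            for i in range(self.n_sites_per_treatment)
        }


@dataclass
class GroundTruth:
    """True per-node densities and body masses behind the synthetic surveys."""

    density: dict[str, dict[str, float]]  # node_id -> treatment -> density
    unit: dict[str, str]  # node_id -> "ind/m2" | "ind/ha"
    body_mass_g: dict[str, float]
    blacklight_only: frozenset = frozenset()
    home_range_ha: dict[str, float] = field(default_factory=dict)
    mass_to_volume: dict[str, float] = field(default_factory=dict)  # producer kg/m^3


# ---------------------------------------------------------------- community

# archetype cycle for invertebrates: (order, family, guild, habitat tags,
# diel, adult length mm, soft-bodied, larva habitat)
_INVERT_ARCHETYPES = (
    ("Collembola", "Isotomidae", "detritivore", ("soil",), (), 2.0, True, ("soil",)),
    ("Araneae", "Lycosidae", "hunting_spider_ground", ("ground",), ("nocturnal",), 8.0, False, ("ground",)),
    ("Coleoptera", "Carabidae", "predatory_beetle", ("ground",), ("nocturnal",), 10.0, False, ("ground",)),
    ("Hemiptera", "Miridae", "herbivore_hemiptera", ("understory",), ("diurnal",), 5.0, True, ("understory",)),
    ("Araneae", "Araneidae", "web_building_spider", ("plant-surface",), ("diurnal", "nocturnal"), 6.0, False, ("plant-surface",)),
    ("Araneae", "Salticidae", "salticid_spider", ("plant-surface",), ("diurnal",), 6.0, False, ("plant-surface",)),
    ("Diptera", "Muscidae", "detritivore", ("aerial",), ("diurnal",), 6.0, True, ("ground",)),
    ("Lepidoptera", "Noctuidae", "lepidoptera", ("aerial",), ("nocturnal",), 15.0, True, ("understory",)),
    ("Coleoptera", "Curculionidae", "herbivorous_beetle", ("tree/bark",), ("diurnal",), 6.0, False, ("tree/bark",)),
)

_VERT_ARCHETYPES = (
    # (class, order, guild, length mm, mass g, density multiplier, basis)
    ("Mammalia", "Rodentia", "small_mammal", 90.0, 20.0, 1.0, "grid"),
    ("Aves", "Passeriformes", "insectivorous_bird", 150.0, 30.0, 1.0, "bird"),
    ("Mammalia", "Chiroptera", "bat", 80.0, 15.0, 0.5, "home_range"),
    ("Reptilia", "Squamata", "reptile", 120.0, 40.0, 0.5, "grid"),
    ("Mammalia", "Carnivora", "large_mammal", 1500.0, 50_000.0, 0.01, "home_range"),
)

_PRODUCER_FAMILIES = ("Pinaceae", "Rosaceae", "Asteraceae", "Poaceae", "Fagaceae",
                      "Ericaceae", "Rhamnaceae", "Fabaceae")

PRODUCER_PARTS = ("leaf", "stem", "root", "seed", "flower")


def _length_to_mass(length_mm: float) -> float:
    # slender-ellipsoid body: width = depth = length / 3
    return volumetric_mass(length_mm, length_mm / 3.0, length_mm / 3.0, "ellipsoid")


def gen_community(config: SimConfig) -> tuple[NodeRegistry, GroundTruth]:
    """Generate the node registry and its ground-truth densities."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    registry = NodeRegistry()
    truth = GroundTruth(density={}, unit={}, body_mass_g={})
    blacklight_only: set[str] = set()

    def treatment_densities(group: str, multiplier: float = 1.0) -> dict[str, float]:
        base = float(
            rng.lognormal(config.log_density_mean[group], config.log_density_sd[group])
        ) * multiplier
        return {t: base * config.treatment_effect[group][t] for t in config.treatments}

    # -- producers: one node per part, density shared across a species' parts
    for i in range(config.n_producers):
        sp = f"P{i + 1:02d}"
        family = _PRODUCER_FAMILIES[i % len(_PRODUCER_FAMILIES)]
        tax = Taxonomy(kingdom="Plantae", family=family, genus=f"{family[:-4]}us",
                       species=sp)
        dens = treatment_densities("producers")
        truth.mass_to_volume[sp] = float(rng.lognormal(math.log(30.0), 0.3))
        for part in PRODUCER_PARTS:
            nid = node_id_for(sp, part)
            registry.add(
                TaxonStage(
                    node_id=nid, species_id=sp, stage=part,
                    node_class="producer_part", taxonomy=tax,
                    habitat=frozenset({"understory"}), observed=True,
                    body_mass_g=float(rng.lognormal(math.log(5.0), 0.5)),
                )
            )
            truth.density[nid] = dict(dens)
            truth.unit[nid] = "ind/m2"
            truth.body_mass_g[nid] = registry[nid].body_mass_g

    # -- invertebrates: egg / larva-or-juvenile / adult stages
    for i in range(config.n_invertebrates):
        sp = f"I{i + 1:02d}"
        order, family, guild, habitat, diel, length, soft, larva_habitat = (
            _INVERT_ARCHETYPES[i % len(_INVERT_ARCHETYPES)]
        )
        tax = Taxonomy(kingdom="Animalia", phylum="Arthropoda",
                       class_="Arachnida" if order == "Araneae" else "Insecta",
                       order=order, family=family, genus=f"{family[:-3]}a",
                       species=sp)
        adult_len = length * float(rng.lognormal(0.0, 0.2))
        juvenile_label = "juvenile" if order in ("Araneae", "Collembola") else "larva"
        dens = treatment_densities(
            "invertebrates", 150.0 if "soil" in habitat else 1.0
        )
        larva_observed = (
            juvenile_label == "juvenile" or rng.random() >= config.unobserved_fraction
        )
        nocturnal_aerial = "aerial" in habitat and "nocturnal" in diel
        in_blacklight_only = nocturnal_aerial and i % 2 == 1

        for stage, slen, shabitat, observed in (
            ("egg", adult_len * 0.08, larva_habitat, False),
            (juvenile_label, adult_len * 0.6, larva_habitat, larva_observed),
            ("adult", adult_len, habitat, True),
        ):
            nid = node_id_for(sp, stage)
            registry.add(
                TaxonStage(
                    node_id=nid, species_id=sp, stage=stage,
                    node_class="consumer_stage", taxonomy=tax,
                    habitat=frozenset(shabitat),
                    diel=frozenset(diel) if stage == "adult" else frozenset({"diurnal", "nocturnal"} & set(diel) or {"diurnal"}),
                    guild=guild, soft_bodied=soft or stage != "adult",
                    observed=observed,
                    body_length_mm=slen, body_mass_g=_length_to_mass(slen),
                )
            )
            truth.body_mass_g[nid] = registry[nid].body_mass_g
            truth.unit[nid] = "ind/m2"
            if observed:
                stage_factor = 1.0 if stage == "adult" else 0.5
                truth.density[nid] = {t: d * stage_factor for t, d in dens.items()}
                if stage == "adult" and in_blacklight_only:
                    blacklight_only.add(nid)

    # -- vertebrates: juvenile / adult stages, density per hectare
    for i in range(config.n_vertebrates):
        sp = f"V{i + 1:02d}"
        class_, order, guild, length, mass, mult, basis = (
            _VERT_ARCHETYPES[i % len(_VERT_ARCHETYPES)]
        )
        tax = Taxonomy(kingdom="Animalia", phylum="Chordata", class_=class_,
                       order=order, genus=f"{order[:5]}us", species=sp)
        habitat = {
            "small_mammal": {"ground"}, "insectivorous_bird": {"aerial", "tree/bark"},
            "bat": {"aerial"}, "reptile": {"ground"}, "large_mammal": {"ground"},
        }[guild]
        diel = {"bat": {"nocturnal"}}.get(guild, {"diurnal"})
        dens = treatment_densities("vertebrates", mult)
        if basis == "home_range":
            truth.home_range_ha[sp] = float(
                rng.lognormal(math.log(300.0 if guild == "large_mammal" else 100.0), 0.3)
            )
        for stage, slen, smass, observed in (
            ("juvenile", length * 0.5, mass * 0.25, False),
            ("adult", length, mass, True),
        ):
            nid = node_id_for(sp, stage)
            registry.add(
                TaxonStage(
                    node_id=nid, species_id=sp, stage=stage,
                    node_class="consumer_stage", taxonomy=tax,
                    habitat=frozenset(habitat), diel=frozenset(diel),
                    guild=guild, observed=observed,
                    body_length_mm=slen, body_mass_g=smass,
                )
            )
            truth.body_mass_g[nid] = smass
            truth.unit[nid] = "ind/ha"
            if observed:
                truth.density[nid] = dict(dens)

    if len(registry):
        add_nonliving_nodes(registry, NonlivingBinConfig())
    truth.blacklight_only = frozenset(blacklight_only)
    return registry, truth


# ------------------------------------------------------------------ surveys


@dataclass
class SurveyBundle:
    """Per-method survey tables plus shared context tables."""

    tables: dict[str, pd.DataFrame]
    site_treatments: dict[str, str]
    habitat_cover: pd.DataFrame  # site, habitat_type, cover_m2


def _nodes_by(registry: NodeRegistry, *, habitat: str | None = None,
              diel: str | None = None) -> list[TaxonStage]:
    out = []
    for n in registry:
        if n.node_class != "consumer_stage" or not n.observed:
            continue
        if n.guild in ("small_mammal", "insectivorous_bird", "bat", "reptile",
                       "large_mammal"):
            continue
        if habitat is not None and habitat not in n.habitat:
            continue
        if diel is not None and diel not in n.diel:
            continue
        out.append(n)
    return sorted(out, key=lambda n: n.node_id)


def gen_surveys(registry: NodeRegistry, truth: GroundTruth, config: SimConfig) -> SurveyBundle:
    """Draw the per-method survey tables from the ground truth."""
    if len(registry) == 0:
        raise ValueError("registry is empty")
    sites = config.sites()
    seq = np.random.SeedSequence(config.seed)
    # child 0 is gen_community's; methods use a fixed spawn order after it
    children = seq.spawn(16)
    method_rngs = {
        name: np.random.default_rng(children[i + 1])
        for i, name in enumerate(
            ("vegetation_transect", "soil_cores", "hard_substrate", "sweep_net",
             "berlese", "fogging", "blacklight", "vertebrate_abundance",
             "tree_transect", "cwd_transect", "ground_cover", "box_quadrat",
             "larval_bins")
        )
    }
    tables: dict[str, pd.DataFrame] = {}
    pf = config.treatment_effect["producers"]

    def poisson_counts(nodes, area_m2, method, rng):
        det = config.detection(method)
        if area_m2 <= 0:
            raise ValueError(f"{method}: sampled area must be positive")
        rows = []
        for site, treatment in sites.items():
            for node in nodes:
                d = truth.density.get(node.node_id, {}).get(treatment, 0.0)
                rows.append(
                    {"site": site, "treatment": treatment, "node_id": node.node_id,
                     "count": int(rng.poisson(d * area_m2 * det)),
                     "sampled_area_m2": area_m2}
                )
        return pd.DataFrame(rows, columns=["site", "treatment", "node_id", "count",
                                           "sampled_area_m2"])

    # ---- producers on shrub/vegetation transects (counts over 500 m^2)
    veg_area = DEFAULT_GEOMETRIES["shrub_transect"].sampled_area_m2
    producer_leads = [
        registry[node_id_for(sp, "leaf")]
        for sp in registry.species_ids()
        if node_id_for(sp, "leaf") in registry
        and registry[node_id_for(sp, "leaf")].node_class == "producer_part"
    ]
    tables["vegetation_transect"] = poisson_counts(
        producer_leads, veg_area, "vegetation_transect", method_rngs["vegetation_transect"]
    )

    # ---- area-count invertebrate methods
    tables["soil_cores"] = poisson_counts(
        _nodes_by(registry, habitat="soil"),
        DEFAULT_GEOMETRIES["soil_cores"].sampled_area_m2,
        "soil_cores", method_rngs["soil_cores"],
    )
    tables["hard_substrate"] = poisson_counts(
        _nodes_by(registry, habitat="ground"),
        DEFAULT_GEOMETRIES["hard_substrate"].sampled_area_m2,
        "hard_substrate", method_rngs["hard_substrate"],
    )
    sweep_nodes = {n.node_id: n for n in _nodes_by(registry, habitat="plant-surface")}
    for n in _nodes_by(registry, habitat="aerial"):
        # nocturnal aerial species regularly caught only in black lights are
        # excluded; their diurnal/analog peers appear in the sweep table
        if n.node_id not in truth.blacklight_only:
            sweep_nodes[n.node_id] = n
    tables["sweep_net"] = poisson_counts(
        sorted(sweep_nodes.values(), key=lambda n: n.node_id),
        DEFAULT_GEOMETRIES["sweep_net"].sampled_area_m2,
        "sweep_net", method_rngs["sweep_net"],
    )

    # ---- Berlese extractions from box-quadrat plant material
    rng = method_rngs["berlese"]
    det = config.detection("berlese")
    box_volume_m3, subsample_kg = 0.05, 1.0
    rows = []
    for site, treatment in sites.items():
        plant_volume_density = 0.05 * pf[treatment]  # m^3 plant per m^2 ground
        box_mass_kg = 30.0 * box_volume_m3  # bulk mass-to-volume 30 kg/m^3
        for node in _nodes_by(registry, habitat="understory"):
            d = truth.density.get(node.node_id, {}).get(treatment, 0.0)
            per_m3 = d / plant_volume_density if plant_volume_density else 0.0
            lam = per_m3 * box_volume_m3 * (subsample_kg / box_mass_kg) * det
            rows.append(
                {"site": site, "treatment": treatment, "node_id": node.node_id,
                 "count": int(rng.poisson(lam)),
                 "subsample_mass_kg": subsample_kg, "box_mass_kg": box_mass_kg,
                 "box_volume_m3": box_volume_m3,
                 "transect_volume_density": plant_volume_density}
            )
    tables["berlese"] = pd.DataFrame(rows)

    # ---- canopy fogging: three sites per treatment, tarp counts
    rng = method_rngs["fogging"]
    det = config.detection("fogging")
    fog_sites = [s for t in config.treatments
                 for s in list(k for k, v in sites.items() if v == t)[:3]]
    cover_rows, rows = [], []
    for site in fog_sites:
        treatment = sites[site]
        habitat_type = "dead_tree" if treatment == "high" else "live_tree"
        cover_m2 = 1200.0 * pf[treatment]
        cover_rows.append({"site": site, "habitat_type": habitat_type,
                           "cover_m2": cover_m2})
        for node in _nodes_by(registry, habitat="tree/bark"):
            # truth densities are per m^2 of ground; the density seen on a
            # tarp is the site total concentrated onto the fogged habitat
            d_ground = truth.density.get(node.node_id, {}).get(treatment, 0.0)
            d_habitat = d_ground * SITE_AREA_M2 / cover_m2
            rows.append(
                {"site": site, "treatment": treatment, "node_id": node.node_id,
                 "count": int(rng.poisson(d_habitat * FOGGING_TARP_AREA_M2 * det)),
                 "tarp_area_m2": FOGGING_TARP_AREA_M2, "habitat_type": habitat_type}
            )
    tables["fogging"] = pd.DataFrame(rows)
    habitat_cover = pd.DataFrame(cover_rows, columns=["site", "habitat_type", "cover_m2"])

    # ---- black lights: activity counts only (no area column by design)
    rng = method_rngs["blacklight"]
    det = config.detection("blacklight")
    rows = []
    for site, treatment in sites.items():
        for node in _nodes_by(registry, habitat="aerial", diel="nocturnal"):
            d = truth.density.get(node.node_id, {}).get(treatment, 0.0)
            rows.append(
                {"site": site, "treatment": treatment, "node_id": node.node_id,
                 "count": int(rng.poisson(d * BLACKLIGHT_EFFECTIVE_AREA_M2 * det))}
            )
    tables["blacklight"] = pd.DataFrame(rows, columns=["site", "treatment", "node_id", "count"])

    # ---- vertebrate model-output abundances
    rng = method_rngs["vertebrate_abundance"]
    rows = []
    for site, treatment in sites.items():
        for node in sorted(registry, key=lambda n: n.node_id):
            if node.node_class != "consumer_stage" or not node.observed:
                continue
            if node.guild not in ("small_mammal", "insectivorous_bird", "bat",
                                  "reptile", "large_mammal"):
                continue
            d_ha = truth.density[node.node_id][treatment]
            if node.guild in ("bat", "large_mammal"):
                hr = truth.home_range_ha[node.species_id]
                lam, basis, area, hr_out = d_ha * hr, "home_range", None, hr
            else:
                area = (DEFAULT_GEOMETRIES["bird_point_count"].sampled_area_m2
                        if node.guild == "insectivorous_bird"
                        else DEFAULT_GEOMETRIES["small_mammal_grid"].sampled_area_m2)
                lam, basis, hr_out = d_ha * area / 1e4, "area", None
            rows.append(
                {"site": site, "treatment": treatment, "node_id": node.node_id,
                 "species_id": node.species_id,
                 "abundance": float(rng.poisson(lam)), "basis": basis,
                 "area_m2": area, "home_range_ha": hr_out}
            )
    tables["vertebrate_abundance"] = pd.DataFrame(rows)

    # ---- plant-biomass raw tables (trees, CWD, ground cover, box quadrats)
    rng = method_rngs["tree_transect"]
    tree_area = DEFAULT_GEOMETRIES["tree_transect"].sampled_area_m2
    dead_frac = {"unburned": 0.05, "low_moderate": 0.35, "high": 0.85}
    rows = []
    for site, treatment in sites.items():
        n_trees = int(rng.poisson(0.04 * pf[treatment] * tree_area))
        for _ in range(n_trees):
            dbh = 15.0 + float(rng.lognormal(math.log(15.0), 0.5))
            dead = rng.random() < dead_frac[treatment]
            damaged = rng.random() < (0.5 if treatment == "high" else 0.1)
            rows.append(
                {"site": site, "treatment": treatment,
                 "species_group": "Pinaceae" if rng.random() < 0.95 else "Quercus",
                 "dbh_cm": dbh,
                 "health": "dead" if dead else ("unhealthy" if rng.random() < 0.2 else "healthy"),
                 "damaged": damaged,
                 "measured_height_m": float(rng.uniform(2.0, 15.0)) if damaged else None}
            )
    tables["tree_transect"] = pd.DataFrame(
        rows, columns=["site", "treatment", "species_group", "dbh_cm", "health",
                       "damaged", "measured_height_m"])

    rng = method_rngs["cwd_transect"]
    rows = []
    cwd_rate = {"unburned": 2.0, "low_moderate": 4.0, "high": 6.0}
    for site, treatment in sites.items():
        for _ in range(int(rng.poisson(cwd_rate[treatment]))):
            d_small = float(rng.uniform(12.5, 35.0))
            rows.append(
                {"site": site, "treatment": treatment,
                 "small_diameter_cm": d_small,
                 "large_diameter_cm": d_small + float(rng.uniform(0.0, 12.0)),
                 "length_m": float(rng.uniform(1.0, 8.0)),
                 "decay_class": int(rng.integers(1, 6))}
            )
    tables["cwd_transect"] = pd.DataFrame(
        rows, columns=["site", "treatment", "small_diameter_cm", "large_diameter_cm",
                       "length_m", "decay_class"])

    rng = method_rngs["ground_cover"]
    rows = []
    producer_species = sorted(truth.mass_to_volume)
    for site, treatment in sites.items():
        for sp in producer_species:
            rows.append(
                {"site": site, "treatment": treatment, "species_id": sp,
                 "tissue_type": "leaf",
                 "cover_fraction": float(rng.uniform(0.0, 0.3)) * pf[treatment],
                 "height_m": float(rng.uniform(0.1, 0.6)),
                 "quadrat_area_m2": DEFAULT_GEOMETRIES["ground_cover"].sampled_area_m2}
            )
    tables["ground_cover"] = pd.DataFrame(rows)

    rng = method_rngs["box_quadrat"]
    rows = []
    for sp in producer_species:
        node = registry[node_id_for(sp, "leaf")]
        ratio = truth.mass_to_volume[sp]
        n_samples = int(rng.integers(1, 5))  # some species sparse -> pooling
        for k in range(n_samples):
            volume = float(rng.uniform(0.005, 0.05))
            rows.append(
                {"site": f"U{k % config.n_sites_per_treatment + 1}",
                 "species_id": sp,
                 "genus": node.taxonomy.genus, "family": node.taxonomy.family,
                 "tissue_type": "leaf",
                 "mass_kg": ratio * volume * float(rng.lognormal(0.0, 0.1)),
                 "volume_m3": volume}
            )
    tables["box_quadrat"] = pd.DataFrame(
        rows, columns=["site", "species_id", "genus", "family", "tissue_type",
                       "mass_kg", "volume_m3"])

    # ---- pooled larval bins for partitioning (unidentifiable larvae)
    rows = []
    for treatment in config.treatments:
        pooled = 0.0
        for node in registry:
            if (node.stage == "larva" and not node.observed
                    and node.taxonomy.order == "Lepidoptera"):
                adult = registry.get(node_id_for(node.species_id, "adult"))
                if adult is not None and adult.node_id in truth.density:
                    pooled += truth.density[adult.node_id][treatment] * 0.5
        rows.append({"treatment": treatment, "taxon_bin": "Lepidoptera",
                     "pooled_density": pooled, "unit": "ind/m2"})
    tables["larval_bins"] = pd.DataFrame(rows)

    return SurveyBundle(tables=tables, site_treatments=sites, habitat_cover=habitat_cover)


def gen_rules(registry: NodeRegistry, config: SimConfig) -> link_mod.RuleFile:
    """Emit a rule file covering every consumer guild present in the registry.

    Starts from the package's text-derivable guild skeleton and keeps only
    rules whose consumer selector matches at least one node, adding the
    herbivory, detritivory and predation rules the synthetic archetypes
    need.  Always includes the web-spider size window when spiders are
    present.
    """
    extra = (
        link_mod.TrophicRule(
            "hemiptera_herbivore",
            link_mod.ConsumerSelector(guild="herbivore_hemiptera"),
            ("producer_parts",),
            diet_part_whitelist=("leaf", "stem"),
        ),
        link_mod.TrophicRule(
            "predatory_beetle",
            link_mod.ConsumerSelector(guild="predatory_beetle"),
            ("ground_invertebrates_excl_spider_eggs",
             "soft_bodied_ground_invertebrates"),
            link_mod.SizeWindow(0.05, 1.0),
        ),
        link_mod.TrophicRule(
            "reptile_insectivore",
            link_mod.ConsumerSelector(guild="reptile", stages=("adult", "juvenile")),
            ("ground_invertebrates",),
            link_mod.SizeWindow(0.01, 0.5),
        ),
        link_mod.TrophicRule(
            "large_mammal_browse",
            link_mod.ConsumerSelector(guild="large_mammal", stages=("adult",)),
            ("producer_parts",),
            diet_part_whitelist=("leaf", "stem"),
        ),
        link_mod.TrophicRule(
            "moth_larva_folivory",
            link_mod.ConsumerSelector(
                stages=("larva",), ranks=(("order", "Lepidoptera"),)
            ),
            ("producer_parts",),
            diet_part_whitelist=("leaf",),
        ),
        link_mod.TrophicRule(
            "moth_adult_nectar",
            link_mod.ConsumerSelector(
                stages=("adult",), ranks=(("order", "Lepidoptera"),)
            ),
            ("producer_parts",),
            diet_part_whitelist=("flower",),
        ),
    )
    candidates = {r.rule_id: r for r in link_mod.default_guild_rules().rules}
    for rule in extra:
        candidates[rule.rule_id] = rule
    kept = tuple(
        rule for _, rule in sorted(candidates.items())
        if any(rule.consumer.matches(n) for n in registry)
    )
    rule_file = link_mod.RuleFile(rules=kept)
    rule_file.validate()
    return rule_file
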
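"""Node registry: ontogenetic stages, plant parts and non-living resources.

A food-web *node* is not a species.  Animals are decomposed into ontogenetic
stages (egg, larva/juvenile, adult), plants into constituent parts (leaf,
stem, root, seed, flower/nectar), and non-living resources (detritus,
carcasses, dung, honeydew) are first-class nodes, optionally partitioned
into logarithmic size classes.  Every node — observed in the field or
inferred from life history — carries a body-size estimate; only observed
nodes carry biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

TISSUE_DENSITY_G_PER_ML = 1.1  # soft-tissue density used for volumetric masses

RANKS = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")

NODE_CLASSES = ("producer_part", "consumer_stage", "nonliving")

HABITAT_TAGS = frozenset(
    {"soil", "ground", "understory", "plant-surface", "tree/bark", "aerial"}
)
DIEL_TAGS = frozenset({"diurnal", "nocturnal"})

#: stages that do not feed and therefore are never pruned for lack of resources
NON_FEEDING_STAGES = frozenset({"egg", "pupa", "egg_larva_pupa_lumped"})

PLANT_PARTS = ("leaf", "stem", "root", "seed", "flower")


@dataclass(frozen=True)
class Taxonomy:
    """Linnaean ranks, nullable below the identified rank."""

    kingdom: str | None = None
    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def as_tuple(self) -> tuple[str | None, ...]:
        return tuple(getattr(self, r) for r in RANKS)

    def shared_rank_depth(self, other: "Taxonomy") -> int:
        """Number of leading ranks on which both are non-null and equal."""
        depth = 0
        for a, b in zip(self.as_tuple(), other.as_tuple()):
            if a is None or b is None or a != b:
                break
            depth += 1
        return depth

    def rank(self, name: str) -> str | None:
        return getattr(self, "class_" if name == "class" else name)


@dataclass(frozen=True)
class TaxonStage:
    """One node: an ontogenetic stage, a plant part, or a non-living resource."""

    node_id: str
    species_id: str
    stage: str
    node_class: str
    taxonomy: Taxonomy = field(default_factory=Taxonomy)
    observed: bool = True
    habitat: frozenset = frozenset()
    diel: frozenset = frozenset()
    guild: str | None = None
    soft_bodied: bool = False
    body_length_mm: float | None = None
    body_mass_g: float | None = None
    mass_se: float | None = None
    mass_n: int | None = None
    mass_method: str | None = None  # weighed | volumetric | literature

    def __post_init__(self) -> None:
        if self.node_class not in NODE_CLASSES:
            raise ValueError(f"unknown node class {self.node_class!r}")
        unknown = set(self.habitat) - HABITAT_TAGS
        if unknown:
            raise ValueError(f"unknown habitat tags {sorted(unknown)}")
        if set(self.diel) - DIEL_TAGS:
            raise ValueError(f"unknown diel tags {sorted(set(self.diel) - DIEL_TAGS)}")

    @property
    def feeding(self) -> bool:
        """Whether this node consumes resources (drives web pruning)."""
        return self.node_class == "consumer_stage" and self.stage not in NON_FEEDING_STAGES


def node_id_for(species_id: str, stage: str) -> str:
    """Stable node-id scheme ``<species_id>.<stage_label>``."""
    return f"{species_id}.{stage}"


class NodeRegistry:
    """An ordered, id-unique collection of :class:`TaxonStage` nodes."""

    def __init__(self, nodes: Iterable[TaxonStage] = ()) -> None:
        self._nodes: dict[str, TaxonStage] = {}
        for node in nodes:
            self.add(node)

    def add(self, node: TaxonStage) -> None:
        if node.node_id in self._nodes:
            raise ValueError(f"duplicate node id {node.node_id!r}")
        self._nodes[node.node_id] = node

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[TaxonStage]:
        return iter(self._nodes.values())

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __getitem__(self, node_id: str) -> TaxonStage:
        return self._nodes[node_id]

    def get(self, node_id: str) -> TaxonStage | None:
        return self._nodes.get(node_id)

    def ids(self) -> list[str]:
        return list(self._nodes)

    def replace_node(self, node: TaxonStage) -> None:
        if node.node_id not in self._nodes:
            raise KeyError(node.node_id)
        self._nodes[node.node_id] = node

    def species_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for node in self:
            seen.setdefault(node.species_id)
        return list(seen)

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in self:
            row = {
                "node_id": n.node_id,
                "species_id": n.species_id,
                "stage": n.stage,
                "node_class": n.node_class,
                "observed": n.observed,
                "habitat": ";".join(sorted(n.habitat)),
                "diel": ";".join(sorted(n.diel)),
                "guild": n.guild,
                "soft_bodied": n.soft_bodied,
                "body_length_mm": n.body_length_mm,
                "body_mass_g": n.body_mass_g,
                "mass_se": n.mass_se,
                "mass_n": n.mass_n,
                "mass_method": n.mass_method,
            }
            for rank, value in zip(RANKS, n.taxonomy.as_tuple()):
                row[rank] = value
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NodeRegistry":
        def _tags(raw) -> frozenset:
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
                return frozenset()
            return frozenset(str(raw).split(";"))

        def _opt(raw):
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                return None
            return raw

        nodes = []
        for _, r in frame.iterrows():
            tax = Taxonomy(**{rank: _opt(r.get(rank)) for rank in RANKS})
            mass_n = _opt(r.get("mass_n"))
            nodes.append(
                TaxonStage(
                    node_id=r["node_id"],
                    species_id=r["species_id"],
                    stage=r["stage"],
                    node_class=r["node_class"],
                    taxonomy=tax,
                    observed=bool(r["observed"]),
                    habitat=_tags(r.get("habitat")),
                    diel=_tags(r.get("diel")),
                    guild=_opt(r.get("guild")),
                    soft_bodied=bool(r.get("soft_bodied", False)),
                    body_length_mm=_opt(r.get("body_length_mm")),
                    body_mass_g=_opt(r.get("body_mass_g")),
                    mass_se=_opt(r.get("mass_se")),
                    mass_n=int(mass_n) if mass_n is not None else None,
                    mass_method=_opt(r.get("mass_method")),
                )
            )
        return cls(nodes)

    def to_csv(self, path) -> None:
        # %.17g keeps the round-trip bit-exact for float64 attributes
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "NodeRegistry":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


# ------------------------------------------------------------------ stage nodes


@dataclass(frozen=True)
class StageTemplate:
    """Which stages a species gets, with per-stage tag overrides.

    ``lump`` names groups of stages that are resource- and
    consumer-indistinguishable and should be emitted as a single node
    (e.g. parasitoid eggs+larvae+pupae).  ``exclude`` removes stages that
    do not occur in the terrestrial habitat (e.g. aquatic larvae).
    """

    stages: tuple[str, ...]
    lump: tuple[tuple[str, ...], ...] = ()
    exclude: tuple[str, ...] = ()


@dataclass(frozen=True)
class SpeciesSpec:
    """Input record for :func:`build_stage_nodes`."""

    species_id: str
    taxonomy: Taxonomy
    node_class: str  # producer_part -> parts; consumer_stage -> stages
    template: StageTemplate
    habitat: frozenset = frozenset()
    diel: frozenset = frozenset()
    guild: str | None = None
    soft_bodied: bool = False
    observed_stages: frozenset = frozenset()
    body_length_mm: Mapping[str, float] = field(default_factory=dict)
    body_mass_g: Mapping[str, float] = field(default_factory=dict)


def build_stage_nodes(species: Iterable[SpeciesSpec]) -> NodeRegistry:
    """Decompose species into stage/part nodes, applying lumping and exclusion.

    Raises ``ValueError`` if exclusion removes every stage of a species.
    """
    registry = NodeRegistry()
    for spec in species:
        labels = [s for s in spec.template.stages if s not in spec.template.exclude]
        if not labels:
            raise ValueError(
                f"species {spec.species_id!r} has no stages left after exclusion"
            )
        lumped: list[str] = []
        consumed: set[str] = set()
        for group in spec.template.lump:
            members = [s for s in group if s in labels]
            if len(members) > 1:
                consumed.update(members)
        for label in labels:
            if label in consumed:
                continue
            lumped.append(label)
        for group in spec.template.lump:
            members = [s for s in group if s in labels]
            if len(members) > 1:
                lumped.append("_".join(members) + "_lumped")
        for label in lumped:
            source = label.removesuffix("_lumped").split("_")[0] if label.endswith("_lumped") else label
            registry.add(
                TaxonStage(
                    node_id=node_id_for(spec.species_id, label),
                    species_id=spec.species_id,
                    stage=label,
                    node_class=spec.node_class,
                    taxonomy=spec.taxonomy,
                    observed=source in spec.observed_stages,
                    habitat=spec.habitat,
                    diel=spec.diel,
                    guild=spec.guild,
                    soft_bodied=spec.soft_bodied,
                    body_length_mm=spec.body_length_mm.get(source),
                    body_mass_g=spec.body_mass_g.get(source),
                )
            )
    return registry


# ------------------------------------------------------------- volumetric mass

_SHAPE_FACTORS = {
    # volume = factor * length * width * depth, dimensions in the same unit
    "ellipsoid": math.pi / 6.0,
    "cylinder": math.pi / 4.0,  # length x diameter x diameter
    "hemisphere": math.pi / 12.0,  # half-ellipsoid on the measured axes
    "rectangular prism": 1.0,
    "cone": math.pi / 12.0,  # elliptic cone: (1/3) * pi * (w/2)(d/2) * l
}


def volumetric_mass(length_mm: float, width_mm: float, depth_mm: float, shape: str) -> float:
    """Body mass (g) from linear dimensions via an idealized solid.

    The measured length x width x depth are mapped onto the named solid and
    the volume multiplied by a tissue density of 1.1 g/mL.
    """
    if shape not in _SHAPE_FACTORS:
        raise ValueError(f"unknown shape {shape!r}; choose from {sorted(_SHAPE_FACTORS)}")
    if min(length_mm, width_mm, depth_mm) < 0:
        raise ValueError("dimensions must be non-negative")
    volume_mm3 = _SHAPE_FACTORS[shape] * length_mm * width_mm * depth_mm
    volume_ml = volume_mm3 / 1000.0  # 1 mL = 1 cm^3 = 1000 mm^3
    return volume_ml * TISSUE_DENSITY_G_PER_ML


# ------------------------------------------------------------ non-living nodes


@dataclass(frozen=True)
class NonlivingBinConfig:
    """Log-bin layout for carcass and detritus size classes.

    Carcass bins are decade (x10) mass classes spanning
    ``carcass_min_g`` .. ``carcass_max_g``; detritus types each get one node
    per declared size class label.
    """

    carcass_min_g: float = 1e-3
    carcass_max_g: float = 1e5
    carcass_base: float = 10.0
    detritus_classes: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "woody_detritus": ("fine", "coarse"),
            "leaf_detritus": ("litter",),
        }
    )


def carcass_bins(config: NonlivingBinConfig) -> list[tuple[float, float]]:
    """Logarithmic carcass mass bins ``[lo, hi)`` covering the configured span."""
    if config.carcass_max_g <= config.carcass_min_g:
        raise ValueError("carcass bin span is empty")
    n = round(math.log(config.carcass_max_g / config.carcass_min_g, config.carcass_base))
    edges = [config.carcass_min_g * config.carcass_base**i for i in range(n + 1)]
    bins = list(zip(edges[:-1], edges[1:]))
    for (lo1, hi1), (lo2, _) in zip(bins, bins[1:]):
        if not math.isclose(hi1, lo2):
            raise ValueError("carcass bins overlap or leave gaps")
    return bins


def add_nonliving_nodes(
    registry: NodeRegistry, config: NonlivingBinConfig | None = None
) -> NodeRegistry:
    """Append detritus, carcass, dung and honeydew nodes; idempotent."""
    config = config or NonlivingBinConfig()

    def _maybe_add(node: TaxonStage) -> None:
        if node.node_id not in registry:
            registry.add(node)

    for dtype, classes in config.detritus_classes.items():
        for size_class in classes:
            _maybe_add(
                TaxonStage(
                    node_id=node_id_for(dtype, size_class),
                    species_id=dtype,
                    stage=size_class,
                    node_class="nonliving",
                    habitat=frozenset({"ground"}),
                )
            )
    for lo, hi in carcass_bins(config):
        label = f"carcass_{lo:.0e}_{hi:.0e}g"
        # representative mass: geometric mid-point of the bin
        _maybe_add(
            TaxonStage(
                node_id=label,
                species_id="carcass",
                stage=label.removeprefix("carcass_"),
                node_class="nonliving",
                habitat=frozenset({"ground"}),
                body_mass_g=math.sqrt(lo * hi),
            )
        )
    for single in ("dung", "honeydew"):
        _maybe_add(
            TaxonStage(
                node_id=node_id_for(single, "bulk"),
                species_id=single,
                stage="bulk",
                node_class="nonliving",
                habitat=frozenset({"ground", "plant-surface"}) if single == "honeydew" else frozenset({"ground"}),
            )
        )
    return registry


# -------------------------------------------------------------- biomass attach


def attach_biomass(
    registry: NodeRegistry,
    densities: pd.DataFrame,
    masses: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-node, per-treatment biomass density = body mass x numeric density.

    ``densities`` needs columns node_id, treatment, density (individuals per
    m^2 or per ha — the product keeps the density's area basis), plus an
    optional ``unit`` column carried through.  Masses default to the
    registry's ``body_mass_g``.  Unobserved (inferred) nodes never receive
    biomass; a density row with no matching node raises listing the orphans.
    """
    orphans = sorted(set(densities["node_id"]) - set(registry.ids()))
    if orphans:
        raise ValueError(f"density rows without registry nodes: {orphans}")
    rows = []
    for _, r in densities.iterrows():
        node = registry[r["node_id"]]
        if not node.observed:
            continue
        mass = masses.get(node.node_id) if masses else node.body_mass_g
        if mass is None:
            continue
        biomass = mass * float(r["density"])
        unit = r.get("unit", "ind/m2")
        rows.append(
            {
                "node_id": node.node_id,
                "treatment": r["treatment"],
                "density": float(r["density"]),
                "body_mass_g": mass,
                "biomass_density": biomass,
                "unit": f"g_per_{str(unit).split('/')[-1]}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["node_id", "treatment", "density", "body_mass_g", "biomass_density", "unit"],
    )


def with_aggregate_producer_nodes(registry: NodeRegistry) -> NodeRegistry:
    """Add the single-node aggregate groups (no biomass, first-class nodes)."""
    for name in ("algae", "moss", "lichen", "mycorrhizae", "saprophytic_fungi",
                 "saprophytic_bacteria", "nematodes"):
        nid = node_id_for(name, "aggregate")
        if nid not in registry:
            registry.add(
                TaxonStage(
                    node_id=nid,
                    species_id=name,
                    stage="aggregate",
                    node_class="producer_part" if name in ("algae", "moss", "lichen") else "nonliving",
                    habitat=frozenset({"ground", "soil"}),
                    observed=True,
                )
            )
    return registry
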
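"""Rule-based trophic-link assignment.

A candidate consumer-resource pair becomes a link only if it passes two
filters in sequence:

* an **encounter filter** — can the consumer physically/behaviorally meet
  the resource?  Resources are partitioned into named encounter groups
  (flying invertebrates, ground-dwelling invertebrates, invertebrates on
  plants, reptiles, birds, small/large mammals, producer parts,
  non-living resources, saprophytes, ...) and each consumer guild is
  exposed only to the groups its foraging mode reaches; and
* a **compatibility filter** — is an encountered resource consumable?
  Body-size-ratio windows (e.g. web-building spiders take prey 20-200% of
  their own body length), diet whitelists/blacklists of taxa or plant
  parts, and palatability exclusions.

Rules are data (YAML), not code: researchers can adjust any filter and
rerun assignment without touching the engine.  Edges are stored
consumer -> resource; energy flows the opposite way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import yaml

from .registry import NodeRegistry, TaxonStage, node_id_for

VERTEBRATE_CLASSES = frozenset({"Aves", "Mammalia", "Reptilia", "Amphibia"})


def is_invertebrate(node: TaxonStage) -> bool:
    return (
        node.node_class == "consumer_stage"
        and node.taxonomy.class_ not in VERTEBRATE_CLASSES
    )


# ------------------------------------------------------------ encounter side


@dataclass(frozen=True)
class GroupDef:
    """Declarative membership predicate for one encounter group."""

    name: str
    node_classes: tuple[str, ...] = ("consumer_stage",)
    invertebrate: bool | None = None
    any_habitat: tuple[str, ...] = ()
    exclude_habitat: tuple[str, ...] = ()
    any_diel: tuple[str, ...] = ()
    soft_bodied: bool | None = None
    ranks: tuple[tuple[str, str], ...] = ()
    guilds: tuple[str, ...] = ()
    exclude_rank_stage: tuple[tuple[str, str, str], ...] = ()  # (rank, value, stage)

    def matches(self, node: TaxonStage) -> bool:
        if node.node_class not in self.node_classes:
            return False
        if self.invertebrate is not None and is_invertebrate(node) != self.invertebrate:
            return False
        if self.any_habitat and not set(self.any_habitat) & node.habitat:
            return False
        if set(self.exclude_habitat) & node.habitat:
            return False
        if self.any_diel and not set(self.any_diel) & node.diel:
            return False
        if self.soft_bodied is not None and node.soft_bodied != self.soft_bodied:
            return False
        for rank, value in self.ranks:
            if node.taxonomy.rank(rank) != value:
                return False
        if self.guilds and node.guild not in self.guilds:
            return False
        for rank, value, stage in self.exclude_rank_stage:
            if node.taxonomy.rank(rank) == value and node.stage == stage:
                return False
        return True


SPIDER_EGG_EXCLUSION = (("order", "Araneae", "egg"),)


def default_group_definitions() -> tuple[GroupDef, ...]:
    """The fifteen metazoan encounter groups plus basal-resource groups."""
    inv = dict(invertebrate=True)
    return (
        GroupDef("flying_invertebrates", any_habitat=("aerial",), **inv),
        GroupDef("nocturnal_flying_invertebrates", any_habitat=("aerial",),
                 any_diel=("nocturnal",), **inv),
        GroupDef("diurnal_flying_invertebrates", any_habitat=("aerial",),
                 any_diel=("diurnal",), **inv),
        GroupDef("nonflying_invertebrates", exclude_habitat=("aerial",), **inv),
        GroupDef("ground_invertebrates", any_habitat=("ground", "soil"), **inv),
        GroupDef("ground_invertebrates_excl_spider_eggs",
                 any_habitat=("ground", "soil"),
                 exclude_rank_stage=SPIDER_EGG_EXCLUSION, **inv),
        GroupDef("soft_bodied_ground_invertebrates", any_habitat=("ground", "soil"),
                 soft_bodied=True, **inv),
        GroupDef("invertebrates_on_plants",
                 any_habitat=("understory", "plant-surface"), **inv),
        GroupDef("invertebrates_on_plants_excl_spider_eggs",
                 any_habitat=("understory", "plant-surface"),
                 exclude_rank_stage=SPIDER_EGG_EXCLUSION, **inv),
        GroupDef("soft_bodied_invertebrates_on_plants",
                 any_habitat=("understory", "plant-surface"), soft_bodied=True, **inv),
        GroupDef("invertebrates_on_trees", any_habitat=("tree/bark",), **inv),
        GroupDef("reptiles", ranks=(("class", "Reptilia"),)),
        GroupDef("birds", ranks=(("class", "Aves"),)),
        GroupDef("small_mammals", guilds=("small_mammal",)),
        GroupDef("large_mammals", guilds=("large_mammal",)),
        GroupDef("producer_parts", node_classes=("producer_part",)),
        GroupDef("nonliving_resources", node_classes=("nonliving",)),
        GroupDef("saprophytes", node_classes=("consumer_stage", "producer_part",
                                              "nonliving"), guilds=("saprophyte",)),
    )


def build_encounter_groups(
    registry: NodeRegistry, definitions: Iterable[GroupDef] | None = None
) -> dict[str, list[str]]:
    """Materialize encounter groups as explicit, sorted member-id lists."""
    definitions = tuple(definitions) if definitions is not None else default_group_definitions()
    groups: dict[str, list[str]] = {}
    for gdef in definitions:
        if gdef.name in groups:
            raise ValueError(f"duplicate encounter group {gdef.name!r}")
        groups[gdef.name] = sorted(n.node_id for n in registry if gdef.matches(n))
    return groups


# ---------------------------------------------------------- compatibility side


@dataclass(frozen=True)
class SizeWindow:
    """Resource/consumer body-size-ratio window; inclusive by default."""

    min_ratio: float
    max_ratio: float
    basis: str = "length"  # length | mass
    min_inclusive: bool = True
    max_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.min_ratio > self.max_ratio:
            raise ValueError("min ratio exceeds max ratio")
        if self.basis not in ("length", "mass"):
            raise ValueError(f"unknown size basis {self.basis!r}")


def size_compatible(consumer: TaxonStage, resource: TaxonStage, window: SizeWindow) -> bool:
    """True iff resource/consumer size ratio lies inside the window.

    A missing measurement on either node raises — silent exclusion would
    hide data errors.
    """
    attr = "body_length_mm" if window.basis == "length" else "body_mass_g"
    c, r = getattr(consumer, attr), getattr(resource, attr)
    if c is None or r is None or c <= 0:
        raise ValueError(
            f"missing {window.basis} measurement for "
            f"{consumer.node_id if c in (None, 0) else resource.node_id}"
        )
    ratio = r / c
    lo_ok = ratio >= window.min_ratio if window.min_inclusive else ratio > window.min_ratio
    hi_ok = ratio <= window.max_ratio if window.max_inclusive else ratio < window.max_ratio
    return lo_ok and hi_ok


@dataclass(frozen=True)
class ConsumerSelector:
    """Phylogeny x ontogeny guild selector (e.g. web-building spider adults)."""

    guild: str | None = None
    stages: tuple[str, ...] = ()
    ranks: tuple[tuple[str, str], ...] = ()

    def matches(self, node: TaxonStage) -> bool:
        if node.node_class != "consumer_stage":
            return False
        if self.guild is not None and node.guild != self.guild:
            return False
        if self.stages and node.stage not in self.stages:
            return False
        for rank, value in self.ranks:
            if node.taxonomy.rank(rank) != value:
                return False
        return True


@dataclass(frozen=True)
class TrophicRule:
    rule_id: str
    consumer: ConsumerSelector
    encounter_groups: tuple[str, ...] = ()
    size_window: SizeWindow | None = None
    #: resource passes if it matches ANY whitelisted (rank, value) or part label
    diet_rank_whitelist: tuple[tuple[str, str], ...] = ()
    diet_part_whitelist: tuple[str, ...] = ()
    #: resource excluded if it matches ANY blacklisted (rank, value)
    diet_rank_blacklist: tuple[tuple[str, str], ...] = ()
    nursing: bool = False

    def compatible(self, consumer: TaxonStage, resource: TaxonStage) -> tuple[bool, list[str]]:
        """Apply the compatibility clauses; returns (passed, trace clauses)."""
        trace: list[str] = []
        part_hit = False
        for rank, value in self.diet_rank_blacklist:
            if resource.taxonomy.rank(rank) == value:
                return False, trace
        if self.diet_rank_whitelist or self.diet_part_whitelist:
            rank_hit = any(
                resource.taxonomy.rank(rank) == value
                for rank, value in self.diet_rank_whitelist
            )
            part_hit = (
                resource.node_class in ("producer_part", "nonliving")
                and resource.stage in self.diet_part_whitelist
            )
            if not (rank_hit or part_hit):
                return False, trace
            trace.append("diet_whitelist")
        # size windows constrain prey capture; a plant part or non-living
        # resource admitted through the part whitelist is not size-screened
        if self.size_window is not None and not part_hit:
            if not size_compatible(consumer, resource, self.size_window):
                return False, trace
            trace.append(f"size_window[{self.size_window.min_ratio},{self.size_window.max_ratio}]")
        return True, trace


@dataclass(frozen=True)
class LinkRecord:
    consumer_id: str
    resource_id: str
    rule_id: str
    trace: tuple[str, ...]


@dataclass
class RuleFile:
    """Parsed rule file: encounter-group definitions plus trophic rules."""

    groups: tuple[GroupDef, ...] = field(default_factory=default_group_definitions)
    rules: tuple[TrophicRule, ...] = ()

    def validate(self) -> None:
        names = {g.name for g in self.groups}
        for rule in self.rules:
            missing = set(rule.encounter_groups) - names
            if missing:
                raise ValueError(
                    f"rule {rule.rule_id!r} references undefined groups {sorted(missing)}"
                )


# --------------------------------------------------------------- assignment


def assign_links(
    registry: NodeRegistry,
    groups: Mapping[str, Sequence[str]],
    rules: Iterable[TrophicRule],
) -> list[LinkRecord]:
    """All consumer-resource pairs passing encounter then compatibility.

    Pairs are deduplicated with first-matching-rule provenance, rules
    applied in sorted rule-id order so the output is independent of
    registry and rule ordering.  Unweaned (nursing) mammal rules link each
    juvenile to its species' adult node and nothing else.
    """
    links: dict[tuple[str, str], LinkRecord] = {}
    for rule in sorted(rules, key=lambda r: r.rule_id):
        missing = set(rule.encounter_groups) - set(groups)
        if missing:
            raise KeyError(f"rule {rule.rule_id!r}: unknown encounter groups {sorted(missing)}")
        consumers = [n for n in registry if rule.consumer.matches(n)]
        if rule.nursing:
            for consumer in consumers:
                mother_id = node_id_for(consumer.species_id, "adult")
                if mother_id in registry:
                    key = (consumer.node_id, mother_id)
                    links.setdefault(
                        key,
                        LinkRecord(consumer.node_id, mother_id, rule.rule_id, ("nursing",)),
                    )
            continue
        resource_ids = sorted(
            {rid for gname in rule.encounter_groups for rid in groups[gname]}
        )
        for consumer in consumers:
            for rid in resource_ids:
                key = (consumer.node_id, rid)
                if key in links:
                    continue
                resource = registry[rid]
                passed, clauses = rule.compatible(consumer, resource)
                if passed:
                    group_hit = next(
                        g for g in sorted(rule.encounter_groups) if rid in set(groups[g])
                    )
                    links[key] = LinkRecord(
                        consumer.node_id, rid, rule.rule_id,
                        (f"encounter:{group_hit}", *clauses) or ("encounter",),
                    )
    return sorted(links.values(), key=lambda l: (l.consumer_id, l.resource_id))


# -------------------------------------------------------------- default rules

#: spider families partitioned into hunting-mode guilds; unidentified
#: families default to web-building
SPIDER_FAMILY_GUILDS: dict[str, str] = {
    "Araneidae": "web_building_spider",
    "Theridiidae": "web_building_spider",
    "Linyphiidae": "web_building_spider",
    "Tetragnathidae": "web_building_spider",
    "Agelenidae": "web_building_spider",
    "Dictynidae": "web_building_spider",
    "Amaurobiidae": "web_building_spider",
    "Pholcidae": "web_building_spider",
    "Salticidae": "salticid_spider",
    "Oxyopidae": "hunting_spider_plants",
    "Thomisidae": "hunting_spider_plants",
    "Philodromidae": "hunting_spider_plants",
    "Anyphaenidae": "hunting_spider_plants",
    "Clubionidae": "hunting_spider_ground",
    "Corinnidae": "hunting_spider_ground",
    "Gnaphosidae": "hunting_spider_ground",
    "Lycosidae": "hunting_spider_ground",
}

WEB_BUILDER_FALLBACK_GUILD = "web_building_spider"


def spider_guild(family: str | None) -> str:
    """Family -> hunting guild; unidentified spiders assumed web-building."""
    if family is None:
        return WEB_BUILDER_FALLBACK_GUILD
    return SPIDER_FAMILY_GUILDS.get(family, WEB_BUILDER_FALLBACK_GUILD)


def default_guild_rules() -> RuleFile:
    """Rule skeleton derivable from the documented guild descriptions.

    Encodes: web-building spiders taking flying insects at 20-200% of
    their body length, salticids at 25-75%, hunting spiders on ground or
    plant prey, insectivorous birds and bats with size windows,
    herbivore part-type generalization (a fruit/seed/leaf record extends
    to all parts of that type), granivorous small mammals, nectar-feeding
    adult lepidoptera (non-feeding adult moths simply receive no rule),
    microlepidoptera treated like gelechiid caterpillars, and the nursing
    rule linking unweaned mammals to their mothers.
    """
    r = [
        TrophicRule(
            "spider_web_adult",
            ConsumerSelector(guild="web_building_spider", stages=("adult", "juvenile")),
            ("flying_invertebrates",),
            SizeWindow(0.2, 2.0),
        ),
        TrophicRule(
            "spider_salticid_adult",
            ConsumerSelector(guild="salticid_spider", stages=("adult", "juvenile")),
            ("invertebrates_on_plants_excl_spider_eggs", "diurnal_flying_invertebrates"),
            SizeWindow(0.25, 0.75),
        ),
        TrophicRule(
            "spider_hunting_ground",
            ConsumerSelector(guild="hunting_spider_ground", stages=("adult", "juvenile")),
            ("ground_invertebrates_excl_spider_eggs",),
            SizeWindow(0.2, 1.0),
        ),
        TrophicRule(
            "spider_hunting_plants",
            ConsumerSelector(guild="hunting_spider_plants", stages=("adult", "juvenile")),
            ("invertebrates_on_plants_excl_spider_eggs",),
            SizeWindow(0.2, 1.0),
        ),
        TrophicRule(
            "caterpillar_folivory",
            ConsumerSelector(guild="lepidoptera_larva", stages=("larva",)),
            ("producer_parts",),
            diet_part_whitelist=("leaf", "stem"),
        ),
        TrophicRule(
            "adult_lepidoptera_nectar",
            ConsumerSelector(guild="lepidoptera_adult", stages=("adult",)),
            ("producer_parts",),
            diet_part_whitelist=("flower",),
        ),
        TrophicRule(
            "herbivorous_beetle",
            ConsumerSelector(guild="herbivorous_beetle"),
            ("producer_parts",),
            diet_part_whitelist=("leaf", "stem", "root", "flower"),
        ),
        TrophicRule(
            "granivore_small_mammal",
            ConsumerSelector(guild="small_mammal", stages=("adult",)),
            ("producer_parts", "ground_invertebrates"),
            SizeWindow(0.0, 0.5),
            diet_part_whitelist=("seed",),
            diet_rank_whitelist=(("phylum", "Arthropoda"),),
        ),
        TrophicRule(
            "insectivorous_bird",
            ConsumerSelector(guild="insectivorous_bird", stages=("adult",)),
            ("invertebrates_on_plants", "flying_invertebrates"),
            SizeWindow(0.01, 0.5),
        ),
        TrophicRule(
            "aerial_hawking_bat",
            ConsumerSelector(guild="bat", stages=("adult",)),
            ("nocturnal_flying_invertebrates",),
            SizeWindow(0.01, 0.4),
        ),
        TrophicRule(
            "detritivore",
            ConsumerSelector(guild="detritivore"),
            ("nonliving_resources",),
        ),
        TrophicRule(
            "nursing_mammals",
            ConsumerSelector(stages=("juvenile",), ranks=(("class", "Mammalia"),)),
            nursing=True,
        ),
    ]
    rf = RuleFile(rules=tuple(r))
    rf.validate()
    return rf


# ----------------------------------------------------------------- YAML I/O


def _window_to_dict(w: SizeWindow | None):
    if w is None:
        return None
    return {
        "basis": w.basis,
        "min": w.min_ratio,
        "max": w.max_ratio,
        "inclusive": [w.min_inclusive, w.max_inclusive],
    }


def rules_to_yaml(rule_file: RuleFile) -> str:
    doc = {
        "groups": [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(g).items()}
            for g in rule_file.groups
        ],
        "rules": [
            {
                "id": r.rule_id,
                "consumer": {
                    "guild": r.consumer.guild,
                    "stages": list(r.consumer.stages),
                    "ranks": [list(x) for x in r.consumer.ranks],
                },
                "encounter": list(r.encounter_groups),
                "size_window": _window_to_dict(r.size_window),
                "diet_rank_whitelist": [list(x) for x in r.diet_rank_whitelist],
                "diet_part_whitelist": list(r.diet_part_whitelist),
                "diet_rank_blacklist": [list(x) for x in r.diet_rank_blacklist],
                "nursing": r.nursing,
            }
            for r in rule_file.rules
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def rules_from_yaml(text: str) -> RuleFile:
    doc = yaml.safe_load(text) or {}

    def _tt(pairs):  # list-of-lists -> tuple-of-tuples
        return tuple(tuple(p) for p in (pairs or ()))

    groups = tuple(
        GroupDef(
            name=g["name"],
            node_classes=tuple(g.get("node_classes") or ("consumer_stage",)),
            invertebrate=g.get("invertebrate"),
            any_habitat=tuple(g.get("any_habitat") or ()),
            exclude_habitat=tuple(g.get("exclude_habitat") or ()),
            any_diel=tuple(g.get("any_diel") or ()),
            soft_bodied=g.get("soft_bodied"),
            ranks=_tt(g.get("ranks")),
            guilds=tuple(g.get("guilds") or ()),
            exclude_rank_stage=_tt(g.get("exclude_rank_stage")),
        )
        for g in doc.get("groups", [])
    ) or default_group_definitions()
    rules = []
    for r in doc.get("rules", []):
        w = r.get("size_window")
        window = None
        if w is not None:
            inc = w.get("inclusive", [True, True])
            window = SizeWindow(w["min"], w["max"], w.get("basis", "length"), inc[0], inc[1])
        cons = r.get("consumer", {})
        rules.append(
            TrophicRule(
                rule_id=r["id"],
                consumer=ConsumerSelector(
                    guild=cons.get("guild"),
                    stages=tuple(cons.get("stages") or ()),
                    ranks=_tt(cons.get("ranks")),
                ),
                encounter_groups=tuple(r.get("encounter") or ()),
                size_window=window,
                diet_rank_whitelist=_tt(r.get("diet_rank_whitelist")),
                diet_part_whitelist=tuple(r.get("diet_part_whitelist") or ()),
                diet_rank_blacklist=_tt(r.get("diet_rank_blacklist")),
                nursing=bool(r.get("nursing", False)),
            )
        )
    rf = RuleFile(groups=groups, rules=tuple(rules))
    rf.validate()
    return rf
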
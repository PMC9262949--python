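"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by the most direct route
available (double loops, BFS, fixed-point iteration) so they stay
independent of the library code paths they check.
"""

from __future__ import annotations


import networkx as nx
import numpy as np
import pytest

from firewebs.links import (
    ConsumerSelector,
    GroupDef,
    RuleFile,
    SizeWindow,
    TrophicRule,
)
from firewebs.registry import NodeRegistry, TaxonStage, Taxonomy
from firewebs.synthetic import SimConfig, gen_community, gen_rules, gen_surveys


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def community(sim_config):
    return gen_community(sim_config)


@pytest.fixture(scope="session")
def surveys(sim_config, community):
    registry, truth = community
    return gen_surveys(registry, truth, sim_config)


@pytest.fixture(scope="session")
def rule_file(sim_config, community) -> RuleFile:
    registry, _ = community
    return gen_rules(registry, sim_config)


# ------------------------------------------------- random registries + rules

_HABITATS = ("soil", "ground", "understory", "plant-surface", "tree/bark", "aerial")


def random_registry(rng: np.random.Generator, n_nodes: int) -> NodeRegistry:
    """A random mixed registry of consumers, producer parts and non-living nodes."""
    registry = NodeRegistry()
    for i in range(n_nodes):
        kind = rng.choice(["consumer_stage", "producer_part", "nonliving"], p=[0.6, 0.25, 0.15])
        habitat = frozenset(
            rng.choice(_HABITATS, size=rng.integers(1, 3), replace=False).tolist()
        )
        diel = frozenset(
            rng.choice(["diurnal", "nocturnal"], size=rng.integers(1, 3), replace=False).tolist()
        )
        stage = (
            rng.choice(["egg", "larva", "adult", "juvenile"])
            if kind == "consumer_stage"
            else (rng.choice(["leaf", "stem", "seed", "flower"]) if kind == "producer_part" else "bulk")
        )
        registry.add(
            TaxonStage(
                node_id=f"n{i:03d}.{stage}",
                species_id=f"n{i:03d}",
                stage=str(stage),
                node_class=str(kind),
                taxonomy=Taxonomy(
                    kingdom="Animalia" if kind == "consumer_stage" else "Plantae",
                    order=str(rng.choice(["Araneae", "Coleoptera", "Lepidoptera"])),
                ),
                habitat=habitat,
                diel=diel,
                guild=str(rng.choice(["g1", "g2", "g3"])),
                soft_bodied=bool(rng.random() < 0.4),
                body_length_mm=float(rng.lognormal(1.5, 0.8)),
                body_mass_g=float(rng.lognormal(-2.0, 1.0)),
            )
        )
    return registry


def random_rules(rng: np.random.Generator, groups: tuple[GroupDef, ...]) -> list[TrophicRule]:
    rules = []
    names = [g.name for g in groups]
    for i in range(rng.integers(1, 5)):
        lo = float(rng.uniform(0.0, 1.0))
        window = (
            SizeWindow(lo, lo + float(rng.uniform(0.1, 2.0)))
            if rng.random() < 0.7
            else None
        )
        rules.append(
            TrophicRule(
                rule_id=f"r{i}",
                consumer=ConsumerSelector(
                    guild=str(rng.choice(["g1", "g2", "g3"])) if rng.random() < 0.7 else None,
                    stages=("adult", "larva") if rng.random() < 0.4 else (),
                ),
                encounter_groups=tuple(
                    rng.choice(names, size=rng.integers(1, 3), replace=False).tolist()
                ),
                size_window=window,
                diet_part_whitelist=("leaf", "seed") if rng.random() < 0.3 else (),
            )
        )
    return rules


def random_group_defs(rng: np.random.Generator) -> tuple[GroupDef, ...]:
    defs = []
    for i in range(rng.integers(2, 5)):
        defs.append(
            GroupDef(
                name=f"grp{i}",
                node_classes=("consumer_stage",)
                if rng.random() < 0.6
                else ("consumer_stage", "producer_part", "nonliving"),
                any_habitat=tuple(
                    rng.choice(_HABITATS, size=rng.integers(0, 3), replace=False).tolist()
                ),
                any_diel=("nocturnal",) if rng.random() < 0.3 else (),
                soft_bodied=bool(rng.random() < 0.5) if rng.random() < 0.3 else None,
            )
        )
    return tuple(defs)


def oracle_links(registry, group_defs, rules):
    """Brute-force all-pairs link assignment, re-deriving every predicate.

    Walks all S^2 pairs and all rules (sorted by id) with plain attribute
    checks; first matching rule wins.  Independent of assign_links'
    group-materialization and dedup logic.
    """
    pairs = set()
    nodes = list(registry)
    defs = {g.name: g for g in group_defs}
    for rule in sorted(rules, key=lambda r: r.rule_id):
        for consumer in nodes:
            if consumer.node_class != "consumer_stage":
                continue
            if rule.consumer.guild is not None and consumer.guild != rule.consumer.guild:
                continue
            if rule.consumer.stages and consumer.stage not in rule.consumer.stages:
                continue
            if any(consumer.taxonomy.rank(k) != v for k, v in rule.consumer.ranks):
                continue
            if rule.nursing:
                mid = f"{consumer.species_id}.adult"
                if mid in registry:
                    pairs.add((consumer.node_id, mid))
                continue
            for resource in nodes:
                in_group = False
                for gname in rule.encounter_groups:
                    g = defs[gname]
                    ok = resource.node_class in g.node_classes
                    if ok and g.invertebrate is not None:
                        is_inv = (
                            resource.node_class == "consumer_stage"
                            and resource.taxonomy.class_
                            not in ("Aves", "Mammalia", "Reptilia", "Amphibia")
                        )
                        ok = is_inv == g.invertebrate
                    if ok and g.any_habitat:
                        ok = bool(set(g.any_habitat) & resource.habitat)
                    if ok and g.exclude_habitat:
                        ok = not (set(g.exclude_habitat) & resource.habitat)
                    if ok and g.any_diel:
                        ok = bool(set(g.any_diel) & resource.diel)
                    if ok and g.soft_bodied is not None:
                        ok = resource.soft_bodied == g.soft_bodied
                    if ok:
                        ok = all(resource.taxonomy.rank(k) == v for k, v in g.ranks)
                    if ok and g.guilds:
                        ok = resource.guild in g.guilds
                    if ok:
                        for rank, value, stage in g.exclude_rank_stage:
                            if resource.taxonomy.rank(rank) == value and resource.stage == stage:
                                ok = False
                    if ok:
                        in_group = True
                        break
                if not in_group:
                    continue
                # compatibility, re-derived
                if any(resource.taxonomy.rank(k) == v for k, v in rule.diet_rank_blacklist):
                    continue
                part_hit = False
                if rule.diet_rank_whitelist or rule.diet_part_whitelist:
                    rank_hit = any(
                        resource.taxonomy.rank(k) == v for k, v in rule.diet_rank_whitelist
                    )
                    part_hit = (
                        resource.node_class in ("producer_part", "nonliving")
                        and resource.stage in rule.diet_part_whitelist
                    )
                    if not (rank_hit or part_hit):
                        continue
                if rule.size_window is not None and not part_hit:
                    w = rule.size_window
                    c = consumer.body_length_mm if w.basis == "length" else consumer.body_mass_g
                    r = resource.body_length_mm if w.basis == "length" else resource.body_mass_g
                    ratio = r / c
                    lo = ratio >= w.min_ratio if w.min_inclusive else ratio > w.min_ratio
                    hi = ratio <= w.max_ratio if w.max_inclusive else ratio < w.max_ratio
                    if not (lo and hi):
                        continue
                pairs.add((consumer.node_id, resource.node_id))
    return pairs


# ------------------------------------------------------ trophic-level oracles


def bfs_shortest_tl(graph: nx.DiGraph) -> dict[str, float]:
    """Plain BFS per node down consumer->resource edges to any basal node."""
    basal = {n for n in graph.nodes if graph.out_degree(n) == 0}
    levels = {}
    for start in graph.nodes:
        frontier, depth, seen = {start}, 0, {start}
        while frontier:
            if frontier & basal:
                levels[start] = 1.0 + depth
                break
            nxt = {s for f in frontier for s in graph.successors(f)} - seen
            seen |= nxt
            frontier, depth = nxt, depth + 1
    return levels


def iterative_prey_averaged_tl(graph: nx.DiGraph, tol: float = 1e-12) -> dict[str, float]:
    """Fixed-point relaxation of TL_i = 1 + mean TL of resources (basal = 1)."""
    tl = {n: 1.0 for n in graph.nodes}
    for _ in range(100_000):
        delta = 0.0
        for n in graph.nodes:
            resources = [r for r in graph.successors(n) if r != n]
            new = 1.0 + (sum(tl[r] for r in resources) / len(resources) if resources else 0.0)
            delta = max(delta, abs(new - tl[n]))
            tl[n] = new
        if delta < tol:
            break
    return tl


def random_web_graph(rng: np.random.Generator, n_nodes: int, p: float = 0.3) -> nx.DiGraph:
    """Random digraph where every feeding node keeps a path to a basal node."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    for i in range(1, n_nodes):
        # guarantee support: each node consumes at least one lower-index node
        g.add_edge(i, int(rng.integers(0, i)))
        for j in range(n_nodes):
            if j != i and rng.random() < p and not (j > i and rng.random() < 0.5):
                if j < i:
                    g.add_edge(i, j)
    return g
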
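"""Per-treatment food-web assembly, trophic levels and network metrics.

A web for one burn-severity treatment contains the nodes observed with a
density there plus inferred (unobserved) stages, restricted by an
iterative pruning rule: a feeding node with no surviving resources is
removed, repeatedly, until a fixed point.  The fixed point is unique —
pruning is a monotone closure — which the test suite checks exhaustively
on small webs.

Trophic height is the short-weighted trophic level: the arithmetic mean of
the shortest-path level (1 + fewest consumer->resource hops to any basal
node) and the prey-averaged level (TL_i = 1 + mean TL of i's resources,
solved as a linear system with cannibalistic self-loops dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .links import LinkRecord
from .registry import NodeRegistry, TaxonStage


@dataclass
class FoodWeb:
    treatment: str
    graph: nx.DiGraph  # edges consumer -> resource
    biomass: dict[str, float] = field(default_factory=dict)  # per-node biomass density

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def node(self, node_id: str) -> TaxonStage:
        return self.graph.nodes[node_id]["stage"]


def _is_feeding(node: TaxonStage) -> bool:
    return node.feeding


def prune_unsupported(
    graph: nx.DiGraph,
    registry: NodeRegistry,
    order: Sequence[str] | None = None,
) -> nx.DiGraph:
    """Iteratively remove feeding nodes with no resources until a fixed point.

    ``order`` only affects the sequence of removals, never the result; it
    exists so tests can verify order-independence.
    """
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        candidates = [
            n for n in (order if order is not None else sorted(g.nodes))
            if n in g and _is_feeding(registry[n]) and g.out_degree(n) == 0
        ]
        for n in candidates:
            if n in g and _is_feeding(registry[n]) and g.out_degree(n) == 0:
                g.remove_node(n)
                changed = True
    return g


def assemble_web(
    registry: NodeRegistry,
    links: Iterable[LinkRecord],
    densities: pd.DataFrame,
    treatment: str,
    biomass: pd.DataFrame | None = None,
) -> FoodWeb:
    """Build the web for one treatment and prune unsupported consumers.

    Present nodes = nodes with a (positive) density in the treatment plus
    inferred (unobserved) stages; edges restricted to present nodes; then
    feeding nodes with no surviving resources are removed iteratively.
    """
    present = set(
        densities.loc[
            (densities["treatment"] == treatment) & (densities["density"] > 0),
            "node_id",
        ]
    )
    present |= {n.node_id for n in registry if not n.observed}
    present |= {n.node_id for n in registry if n.node_class == "nonliving"}
    present &= set(registry.ids())

    g = nx.DiGraph()
    for nid in sorted(present):
        g.add_node(nid, stage=registry[nid])
    for link in links:
        if link.consumer_id in present and link.resource_id in present:
            g.add_edge(link.consumer_id, link.resource_id, rule_id=link.rule_id)

    g = prune_unsupported(g, registry)
    if g.number_of_nodes() == 0:
        raise ValueError(f"web for treatment {treatment!r} is empty after pruning")

    biomass_map: dict[str, float] = {}
    if biomass is not None:
        sub = biomass[biomass["treatment"] == treatment]
        biomass_map = {
            r["node_id"]: float(r["biomass_density"])
            for _, r in sub.iterrows()
            if r["node_id"] in g
        }
    return FoodWeb(treatment=treatment, graph=g, biomass=biomass_map)


# ----------------------------------------------------------------- metrics


def potential_links(web: FoodWeb) -> int:
    """Number of possible consumer-resource interactions: S^2."""
    return web.n_nodes**2


def connectance(web: FoodWeb) -> float:
    """Realized fraction of potential links: L / S^2."""
    if web.n_nodes == 0:
        raise ValueError("connectance undefined for an empty web")
    return web.n_links / potential_links(web)


def basal_nodes(web: FoodWeb) -> list[str]:
    """Nodes that consume nothing (producer parts, non-living, non-feeding stages)."""
    return sorted(n for n in web.graph.nodes if web.graph.out_degree(n) == 0)


def shortest_trophic_level(web: FoodWeb) -> dict[str, float]:
    """1 + fewest consumer->resource hops to any basal node; basal = 1."""
    basal = set(basal_nodes(web))
    if not basal:
        raise ValueError("web has no basal nodes")
    # BFS from all basal nodes over reversed edges finds, for every
    # consumer, the shortest resource-chain down to a basal node
    reverse = web.graph.reverse(copy=False)
    dist = nx.multi_source_dijkstra_path_length(reverse, basal, weight=lambda *_: 1)
    levels = {}
    for n in web.graph.nodes:
        if n not in dist:
            raise ValueError(f"feeding node {n!r} has no path to a basal node")
        levels[n] = 1.0 + dist[n]
    return levels


def prey_averaged_trophic_level(web: FoodWeb) -> dict[str, float]:
    """Solve TL_i = 1 + mean(TL of i's resources); basal nodes have TL 1.

    Cannibalistic self-loops are dropped from the averaging; remaining
    cycles are handled by the dense linear solve, which is well posed
    whenever every node has a resource path to a basal node.
    """
    nodes = sorted(web.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.eye(n)
    for node in nodes:
        resources = [r for r in web.graph.successors(node) if r != node]
        if resources:
            share = 1.0 / len(resources)
            for r in resources:
                a[index[node], index[r]] -= share
    try:
        tl = np.linalg.solve(a, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError("prey-averaged trophic levels are not identifiable "
                         "(singular system after cycle handling)") from exc
    return {node: float(tl[index[node]]) for node in nodes}


def short_weighted_trophic_level(web: FoodWeb) -> dict[str, float]:
    """Arithmetic mean of the shortest and prey-averaged trophic levels."""
    shortest = shortest_trophic_level(web)
    prey_avg = prey_averaged_trophic_level(web)
    return {n: 0.5 * (shortest[n] + prey_avg[n]) for n in shortest}


def web_summary(web: FoodWeb) -> dict:
    swtl = short_weighted_trophic_level(web)
    return {
        "treatment": web.treatment,
        "S": web.n_nodes,
        "L": web.n_links,
        "potential_links": potential_links(web),
        "connectance": connectance(web),
        "mean_swtl": float(np.mean(list(swtl.values()))),
        "max_swtl": float(max(swtl.values())),
        "total_biomass": float(sum(web.biomass.values())),
    }


# ------------------------------------------------------------------- export


def export_web(web: FoodWeb, edge_csv_path, graphml_path=None) -> None:
    """Write the web as an edge-list CSV and (optionally) annotated GraphML.

    Inferred nodes carry no biomass attribute unless ``dummy`` plotting
    values are injected upstream.
    """
    rows = [
        {"consumer_id": c, "resource_id": r, "rule_id": d.get("rule_id", "")}
        for c, r, d in web.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["consumer_id", "resource_id", "rule_id"]).sort_values(
        ["consumer_id", "resource_id"]
    ).to_csv(edge_csv_path, index=False)

    if graphml_path is not None:
        g = nx.DiGraph()
        swtl = short_weighted_trophic_level(web)
        shortest = shortest_trophic_level(web)
        for nid in web.graph.nodes:
            stage = web.node(nid)
            attrs = {
                "species_id": stage.species_id,
                "stage": stage.stage,
                "node_class": stage.node_class,
                "guild": stage.guild or "",
                "swtl": swtl[nid],
                "shortest_tl": shortest[nid],
            }
            if nid in web.biomass:
                attrs["biomass_density"] = web.biomass[nid]
            g.add_node(nid, **attrs)
        for c, r, d in web.graph.edges(data=True):
            g.add_edge(c, r, rule_id=d.get("rule_id", ""))
        nx.write_graphml(g, graphml_path)


def import_web(edge_csv_path, registry: NodeRegistry, treatment: str = "") -> FoodWeb:
    """Rebuild a web from an exported edge list (round-trip inverse)."""
    edges = pd.read_csv(edge_csv_path)
    g = nx.DiGraph()
    node_ids = sorted(set(edges["consumer_id"]) | set(edges["resource_id"]))
    for nid in node_ids:
        g.add_node(nid, stage=registry[nid])
    for _, r in edges.iterrows():
        rule = r.get("rule_id", "")
        g.add_edge(r["consumer_id"], r["resource_id"],
                   rule_id="" if pd.isna(rule) else rule)
    return FoodWeb(treatment=treatment, graph=g)
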
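"""Visualization-ready graph JSON for super-networks and gene–pathway maps.

The renderer is deliberately out of scope: this module emits a plain JSON
document ``{"nodes": [...], "edges": [...]}`` with everything a generic
network viewer needs — coordinates from one of three layouts, node sizes
proportional to the number of first neighbors, and *semantic* color
classes rather than RGB values so the renderer owns the palette.

Color classes:

* role classes of a super-network (``reaction``, ``reactant``,
  ``product``, ``modifier``, ``reactant-and-product``) — the circular
  layout places these on five concentric rings, reactions innermost;
* fold-change classes (``up`` for fold change > 1, ``down`` for < 1,
  ``constant`` at exactly 1, ``no-info`` when the gene is absent from the
  input list), the conventional mapping being up=green, down=red;
* ``pathway`` for the outer ring of the gene–pathway bipartite map.

Metabolic reactions are reified as nodes (substrate → reaction →
product, modifier → reaction edges); signaling relations are plain edges
labelled with their subtypes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .annotation import AnnotationStore, GeneList
from .enrichment import EnrichmentResult
from .netmodel import (
    ROLE_BOTH,
    ROLE_MODIFIER,
    ROLE_PRODUCT,
    ROLE_REACTANT,
    SuperNetwork,
)

logger = logging.getLogger(__name__)

LAYOUTS = ("circular", "random", "force_directed")

CLASS_REACTION = "reaction"
CLASS_PATHWAY = "pathway"
CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_CONSTANT = "constant"
CLASS_NO_INFO = "no-info"

_ROLE_TO_CLASS = {
    ROLE_REACTANT: "reactant",
    ROLE_PRODUCT: "product",
    ROLE_MODIFIER: "modifier",
    ROLE_BOTH: "reactant-and-product",
}

# ring order of the circular layout, innermost first
_RING_ORDER = (
    CLASS_REACTION,
    "reactant",
    "product",
    "modifier",
    "reactant-and-product",
)


@dataclass(frozen=True)
class VisNode:
    id: str
    label: str
    x: float
    y: float
    size: float
    color: str
    fold_change: float | None = None


@dataclass
class VisGraph:
    nodes: list[VisNode] = field(default_factory=list)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def node_ids(self) -> set[str]:
        return {n.id for n in self.nodes}

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "id": n.id,
                    "label": n.label,
                    "x": round(n.x, 6),
                    "y": round(n.y, 6),
                    "size": n.size,
                    "color": n.color,
                    **(
                        {"fold_change": n.fold_change}
                        if n.fold_change is not None
                        else {}
                    ),
                }
                for n in self.nodes
            ],
            "edges": [
                {"source": s, "target": t, **({"label": lbl} if lbl else {})}
                for s, t, lbl in self.edges
            ],
        }


def write_graph_json(graph: VisGraph, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(graph.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def _skeleton(net: SuperNetwork) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Nodes (id, label, class) and edges of the drawable graph."""
    nodes: list[tuple[str, str, str]] = []
    edges: list[tuple[str, str, str]] = []
    for sp in net.sorted_species():
        nodes.append((sp.global_id, sp.display_name, _ROLE_TO_CLASS[sp.role_class]))
    for idx, inter in enumerate(net.interactions, start=1):
        if inter.kind == "metabolic":
            rid = f"rxn:{idx:05d}"
            label = "+".join(inter.reaction_ids) or rid
            nodes.append((rid, label, CLASS_REACTION))
            for s in inter.substrates:
                edges.append((s, rid, ""))
            for p in inter.products:
                edges.append((rid, p, ""))
            for m in inter.modifiers:
                edges.append((m, rid, ""))
        else:
            label = "+".join(inter.subtypes) or "+".join(inter.relation_types)
            for s in inter.substrates:
                for t in inter.products:
                    edges.append((s, t, label))
    return nodes, edges


def _neighbor_counts(
    nodes: list[tuple[str, str, str]], edges: list[tuple[str, str, str]]
) -> dict[str, int]:
    nb: dict[str, set[str]] = {nid: set() for nid, _, _ in nodes}
    for s, t, _ in edges:
        if s != t:
            nb[s].add(t)
            nb[t].add(s)
    return {nid: len(v) for nid, v in nb.items()}


def _node_size(degree: int) -> float:
    return 1.0 + float(degree)


def layout(net: SuperNetwork, algorithm: str = "circular", seed: int = 0) -> VisGraph:
    """Build the drawable graph of ``net`` with coordinates per algorithm.

    ``circular`` places the five role classes on five concentric rings
    (reactions innermost), members of a ring equally spaced by angle;
    ``random`` scatters nodes uniformly; ``force_directed`` runs a seeded
    Fruchterman–Reingold layout for a fixed 200 iterations. All layouts
    are deterministic given the seed.
    """
    if algorithm not in LAYOUTS:
        raise ValueError(f"unknown layout {algorithm!r}; choose from {LAYOUTS}")
    skeleton_nodes, edges = _skeleton(net)
    if not skeleton_nodes:
        return VisGraph()
    degrees = _neighbor_counts(skeleton_nodes, edges)
    coords = _coordinates(skeleton_nodes, edges, algorithm, seed)
    nodes = [
        VisNode(
            id=nid,
            label=label,
            x=coords[nid][0],
            y=coords[nid][1],
            size=_node_size(degrees[nid]),
            color=cls,
            fold_change=(
                net.species[nid].fold_change if nid in net.species else None
            ),
        )
        for nid, label, cls in skeleton_nodes
    ]
    return VisGraph(nodes=nodes, edges=edges)


def ring_radius(color_class: str) -> float:
    """Radius of the concentric ring assigned to a role class."""
    try:
        return float(_RING_ORDER.index(color_class) + 1)
    except ValueError:
        return float(len(_RING_ORDER) + 1)


def _coordinates(
    skeleton_nodes: list[tuple[str, str, str]],
    edges: list[tuple[str, str, str]],
    algorithm: str,
    seed: int,
) -> dict[str, tuple[float, float]]:
    if algorithm == "circular":
        coords: dict[str, tuple[float, float]] = {}
        by_ring: dict[str, list[str]] = {}
        for nid, _, cls in sorted(skeleton_nodes):
            by_ring.setdefault(cls, []).append(nid)
        for cls, ids in by_ring.items():
            r = ring_radius(cls)
            for i, nid in enumerate(ids):
                theta = 2 * math.pi * i / len(ids)
                coords[nid] = (r * math.cos(theta), r * math.sin(theta))
        return coords
    if algorithm == "random":
        rng = np.random.default_rng(seed)
        return {
            nid: (float(x), float(y))
            for (nid, _, _), (x, y) in zip(
                skeleton_nodes, rng.uniform(-1, 1, size=(len(skeleton_nodes), 2))
            )
        }
    g = nx.Graph()
    g.add_nodes_from(nid for nid, _, _ in skeleton_nodes)
    g.add_edges_from((s, t) for s, t, _ in edges if s != t)
    pos = nx.spring_layout(g, iterations=200, seed=seed)
    return {nid: (float(x), float(y)) for nid, (x, y) in pos.items()}


def fold_change_class(fc: float | None) -> str:
    """Map a natural-scale fold change to its semantic color class."""
    if fc is None:
        return CLASS_NO_INFO
    if fc > 1:
        return CLASS_UP
    if fc < 1:
        return CLASS_DOWN
    return CLASS_CONSTANT


def color_by_fold_change(
    graph: VisGraph,
    genes: GeneList,
    up_color: str = CLASS_UP,
    down_color: str = CLASS_DOWN,
) -> VisGraph:
    """Recolor species nodes by the fold-change rule.

    Reaction and pathway nodes keep their class; every other node is
    recolored: fold change > 1 → ``up_color``, < 1 → ``down_color``,
    exactly 1 → ``constant``, gene absent from the list → ``no-info``.
    """
    fcs = genes.fold_changes
    listed = set(genes.ids)
    new_nodes = []
    for n in graph.nodes:
        if n.color in (CLASS_REACTION, CLASS_PATHWAY):
            new_nodes.append(n)
            continue
        if n.id in fcs:
            cls = fold_change_class(fcs[n.id])
            cls = {CLASS_UP: up_color, CLASS_DOWN: down_color}.get(cls, cls)
            new_nodes.append(replace(n, color=cls, fold_change=fcs[n.id]))
        elif n.id in listed:
            # listed without a fold-change value: no expression information
            new_nodes.append(replace(n, color=CLASS_NO_INFO))
        else:
            new_nodes.append(replace(n, color=CLASS_NO_INFO))
    return VisGraph(nodes=new_nodes, edges=list(graph.edges))


def gene_pathway_map(
    genes: GeneList,
    enriched: list[EnrichmentResult],
    store: AnnotationStore,
) -> VisGraph:
    """Bipartite circular map of input genes vs enriched pathways.

    Inner ring: input genes that belong to at least one enriched pathway,
    colored by the fold-change rule. Outer ring: the enriched pathways.
    One edge per (gene, pathway) membership, so the edge count is
    Σ_p |genes(p) ∩ input|.
    """
    if not enriched:
        raise ValueError("gene_pathway_map requires a nonempty enriched list")
    fcs = genes.fold_changes
    pathway_ids = [r.pathway_id for r in enriched]
    memberships: list[tuple[str, str]] = []
    inner: list[str] = []
    for g, _ in genes.entries:
        hit = [
            p for p in pathway_ids if g in store.pathway_to_genes.get(p, frozenset())
        ]
        if hit:
            inner.append(g)
            memberships.extend((g, p) for p in hit)
    if not inner:
        logger.warning("gene_pathway_map: no input gene maps to any enriched pathway")
        return VisGraph()

    degree: dict[str, int] = {}
    for g, p in memberships:
        degree[g] = degree.get(g, 0) + 1
        degree[p] = degree.get(p, 0) + 1

    nodes: list[VisNode] = []
    for i, g in enumerate(inner):
        theta = 2 * math.pi * i / len(inner)
        nodes.append(
            VisNode(
                id=g,
                label=g,
                x=math.cos(theta),
                y=math.sin(theta),
                size=_node_size(degree[g]),
                color=fold_change_class(fcs.get(g)),
                fold_change=fcs.get(g),
            )
        )
    for i, p in enumerate(pathway_ids):
        theta = 2 * math.pi * i / len(pathway_ids)
        nodes.append(
            VisNode(
                id=p,
                label=p,
                x=2.0 * math.cos(theta),
                y=2.0 * math.sin(theta),
                size=_node_size(degree.get(p, 0)),
                color=CLASS_PATHWAY,
            )
        )
    return VisGraph(nodes=nodes, edges=[(g, p, "") for g, p in memberships])
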
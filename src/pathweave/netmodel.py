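"""Merging parsed pathways into non-redundant super-networks.

Many enriched pathway maps share species (the same compound or gene
appears in several maps) and sometimes whole interactions. The merge
collapses a list of parsed pathway graphs into a single network of one
*kind* — metabolic (reactions with catalyzing genes as modifiers) or
signaling (typed pairwise relations) — in which every global identifier
appears as exactly one species and duplicate interactions are collapsed,
with the set of contributing pathways retained as provenance.

Interaction identity ("redundancy"):

* metabolic — two reactions are duplicates iff they have the same
  substrate set, product set, and modifier set. Reversible reactions are
  canonicalized (sides swapped into lexicographic order) so a reversible
  A→B and a reversible B→A collapse.
* signaling — two relations are duplicates iff they share source, target
  and subtype set; the relation types of collapsed duplicates are unioned
  so the merge is independent of input order.

Entries linking to other maps (``path:`` ids) are navigational, not
molecular species, and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .annotation import GeneList
from .kgml import GROUP_PLACEHOLDER_PREFIX, PathwayGraph

logger = logging.getLogger(__name__)

ROLE_REACTANT = "reactant-only"
ROLE_PRODUCT = "product-only"
ROLE_BOTH = "reactant-and-product"
ROLE_MODIFIER = "modifier"


def _is_map_id(global_id: str) -> bool:
    return global_id.startswith("path:")


@dataclass(frozen=True)
class Species:
    """One unique molecular entity of the merged network."""

    global_id: str
    display_name: str
    role_class: str
    fold_change: float | None = None


@dataclass(frozen=True)
class Interaction:
    """One deduplicated interaction of a super-network.

    For metabolic networks ``substrates``/``products``/``modifiers`` hold
    the participant species; for signaling networks substrates=(source,),
    products=(target,) and ``subtypes`` holds the interaction labels.
    All tuples are sorted so equality is structural.
    """

    kind: str  # metabolic | signaling
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    modifiers: tuple[str, ...] = ()
    reversible: bool = False
    relation_types: tuple[str, ...] = ()
    subtypes: tuple[str, ...] = ()
    reaction_ids: tuple[str, ...] = ()
    provenance: tuple[str, ...] = ()

    @property
    def key(self) -> tuple:
        """Identity key under which duplicates collapse."""
        if self.kind == "metabolic":
            return ("M", self.substrates, self.products, self.modifiers)
        return ("S", self.substrates, self.products, self.subtypes)

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(
            dict.fromkeys(self.substrates + self.products + self.modifiers)
        )


@dataclass
class SuperNetwork:
    """A merged, non-redundant network of one kind."""

    kind: str
    species: dict[str, Species] = field(default_factory=dict)
    interactions: list[Interaction] = field(default_factory=list)

    @property
    def provenance(self) -> dict[tuple, frozenset[str]]:
        return {i.key: frozenset(i.provenance) for i in self.interactions}

    def sorted_species(self) -> list[Species]:
        return [self.species[g] for g in sorted(self.species)]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SuperNetwork):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.species == other.species
            and self.interactions == other.interactions
        )


def _canonical_metabolic(
    substrates: tuple[str, ...],
    products: tuple[str, ...],
    reversible: bool,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Sort each side; for reversible reactions order the sides themselves
    lexicographically so direction does not affect identity."""
    s, p = tuple(sorted(set(substrates))), tuple(sorted(set(products)))
    if reversible and p < s:
        s, p = p, s
    return s, p


def merge(graphs: list[PathwayGraph], kind: str) -> SuperNetwork:
    """Merge the ``kind`` side of every input graph into one SuperNetwork.

    Graphs must be parsed and group-expanded. A mixed graph contributes its
    reactions to a metabolic merge and its relations to a signaling merge.
    Output ordering is deterministic (species by id, interactions by key)
    and independent of the order of ``graphs``.
    """
    if kind not in ("metabolic", "signaling"):
        raise ValueError(f"unknown network kind {kind!r}")
    merged: dict[tuple, Interaction] = {}
    for graph in graphs:
        if kind == "metabolic":
            for rxn in graph.reactions:
                subs, prods = _canonical_metabolic(
                    rxn.substrates, rxn.products, rxn.reversible
                )
                subs = tuple(s for s in subs if not _is_map_id(s))
                prods = tuple(p for p in prods if not _is_map_id(p))
                if not subs or not prods:
                    logger.warning(
                        "%s: reaction %s lost all substrates or products "
                        "(map links excluded), dropped",
                        graph.pathway_id, rxn.reaction_id,
                    )
                    continue
                cand = Interaction(
                    kind="metabolic",
                    substrates=subs,
                    products=prods,
                    modifiers=tuple(
                        sorted(set(m for m in rxn.modifiers if not _is_map_id(m)))
                    ),
                    reversible=rxn.reversible,
                    reaction_ids=(rxn.reaction_id,),
                    provenance=(graph.pathway_id,),
                )
                _absorb(merged, cand)
        else:
            for rel in graph.relations:
                if rel.source.startswith(GROUP_PLACEHOLDER_PREFIX) or (
                    rel.target.startswith(GROUP_PLACEHOLDER_PREFIX)
                ):
                    logger.warning(
                        "%s: unexpanded group relation dropped (run "
                        "expand_groups first)", graph.pathway_id,
                    )
                    continue
                if _is_map_id(rel.source) or _is_map_id(rel.target):
                    continue  # links to other maps are navigational
                cand = Interaction(
                    kind="signaling",
                    substrates=(rel.source,),
                    products=(rel.target,),
                    relation_types=(rel.relation_type,),
                    subtypes=tuple(sorted(set(rel.subtypes))),
                    provenance=(graph.pathway_id,),
                )
                _absorb(merged, cand)

    interactions = [merged[k] for k in sorted(merged)]
    net = SuperNetwork(kind=kind, interactions=interactions)
    net.species = _build_species(interactions)
    return net


def _absorb(merged: dict[tuple, Interaction], cand: Interaction) -> None:
    old = merged.get(cand.key)
    if old is None:
        merged[cand.key] = cand
        return
    merged[cand.key] = replace(
        old,
        reversible=old.reversible or cand.reversible,
        relation_types=tuple(sorted(set(old.relation_types + cand.relation_types))),
        reaction_ids=tuple(sorted(set(old.reaction_ids + cand.reaction_ids))),
        provenance=tuple(sorted(set(old.provenance + cand.provenance))),
    )


def _build_species(interactions: list[Interaction]) -> dict[str, Species]:
    as_sub: set[str] = set()
    as_prod: set[str] = set()
    as_mod: set[str] = set()
    for i in interactions:
        as_sub.update(i.substrates)
        as_prod.update(i.products)
        as_mod.update(i.modifiers)
        if i.reversible:  # both sides of a reversible reaction play both roles
            as_sub.update(i.products)
            as_prod.update(i.substrates)
    species: dict[str, Species] = {}
    for gid in sorted(as_sub | as_prod | as_mod):
        if gid in as_sub and gid in as_prod:
            role = ROLE_BOTH
        elif gid in as_sub:
            role = ROLE_REACTANT
        elif gid in as_prod:
            role = ROLE_PRODUCT
        else:
            role = ROLE_MODIFIER
        species[gid] = Species(global_id=gid, display_name=gid, role_class=role)
    return species


def annotate_fold_changes(net: SuperNetwork, genes: GeneList) -> SuperNetwork:
    """Attach input fold changes to matching species (returns a new network).

    Species whose global id matches an input gene id carry its fold change;
    everything else keeps fold_change=None. Unmatched input genes are
    counted in a log message only.
    """
    fcs = genes.fold_changes
    new_species = {
        gid: (replace(sp, fold_change=fcs[gid]) if gid in fcs else sp)
        for gid, sp in net.species.items()
    }
    unmatched = sum(1 for g in fcs if g not in net.species)
    if unmatched:
        logger.info(
            "annotate_fold_changes: %d gene(s) with fold changes absent from "
            "the %s network", unmatched, net.kind,
        )
    return SuperNetwork(
        kind=net.kind, species=new_species, interactions=list(net.interactions)
    )


def degree_map(net: SuperNetwork) -> dict[str, int]:
    """Number of distinct first neighbors per species.

    All participants of one metabolic reaction (substrates, products and
    modifiers) are mutually adjacent; a signaling relation makes its source
    and target adjacent. Self-adjacency is not counted.
    """
    neighbors: dict[str, set[str]] = {gid: set() for gid in net.species}
    for i in net.interactions:
        parts = i.participants
        for a in parts:
            for b in parts:
                if a != b:
                    neighbors[a].add(b)
    return {gid: len(nb) for gid, nb in neighbors.items()}
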
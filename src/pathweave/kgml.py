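"""KGML (KEGG Markup Language) parsing into typed pathway graphs.

A KGML document describes one pathway map as a list of *entries* (genes,
compounds, glycans, drugs, enzymes, orthologs, links to other maps, and
*groups* denoting complexes), a list of *reactions* (metabolic
conversions between compounds, catalyzed by gene products) and a list of
*relations* (signaling interactions between entries, typed as ECrel,
PPrel, GErel, PCrel or maplink with subtypes such as phosphorylation or
activation).

Parsing is tolerant: optional attributes may be absent, and references to
nonexistent entries are dropped with a logged warning rather than
aborting. Graphics/coordinate elements are ignored — visualization uses
computed layouts downstream. Entries naming several genes (multi-gene
boxes) fan out: a relation endpoint naming k genes yields k relations and
a catalyst entry naming k genes yields k reaction modifiers, because
merged-network nodes must be single biological entities.

Group entries are kept opaque at parse time (their relation endpoints get
the placeholder id ``grp:<local_id>``) and are flattened by
:func:`expand_groups` into one relation per member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from lxml import etree

from .errors import KGMLParseError

logger = logging.getLogger(__name__)

RELATION_TYPES = ("ECrel", "PPrel", "GErel", "PCrel", "maplink")

_CATEGORY_BY_KGML_TYPE = {
    "gene": "gene",
    "compound": "compound",
    "glycan": "glycan",
    "drug": "drug",
    "enzyme": "enzyme",
    "ortholog": "ortholog",
    "map": "map",
    "group": "group",
}

_NAME_PREFIX_CATEGORY = {"gl": "glycan", "dr": "drug", "ec": "enzyme"}

GROUP_PLACEHOLDER_PREFIX = "grp:"


@dataclass(frozen=True)
class Entry:
    """One KGML entry: a pathway-scoped node with global identifiers."""

    local_id: str
    names: tuple[str, ...]
    category: str  # gene|compound|glycan|drug|enzyme|map|group|ortholog|other
    members: tuple[str, ...] = ()  # local ids; nonempty only for groups


@dataclass(frozen=True)
class MetabolicReaction:
    """A metabolic conversion; catalyzing genes are stored as modifiers."""

    reaction_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    modifiers: tuple[str, ...]
    reversible: bool


@dataclass(frozen=True)
class SignalRelation:
    """A signaling interaction between two single entities."""

    source: str
    target: str
    relation_type: str
    subtypes: tuple[str, ...]


@dataclass
class PathwayGraph:
    """Typed in-memory form of one parsed KGML pathway."""

    pathway_id: str
    title: str
    organism: str
    entries: list[Entry] = field(default_factory=list)
    reactions: list[MetabolicReaction] = field(default_factory=list)
    relations: list[SignalRelation] = field(default_factory=list)

    @property
    def kind(self) -> str:
        """metabolic / signaling / mixed, by structural content."""
        if self.reactions and not self.relations:
            return "metabolic"
        if self.relations and not self.reactions:
            return "signaling"
        return "mixed"

    def entry_by_id(self) -> dict[str, Entry]:
        return {e.local_id: e for e in self.entries}


def _entry_category(kgml_type: str, names: tuple[str, ...]) -> str:
    cat = _CATEGORY_BY_KGML_TYPE.get(kgml_type, "other")
    if cat == "compound" and names:
        prefix = names[0].split(":", 1)[0].lower() if ":" in names[0] else ""
        cat = _NAME_PREFIX_CATEGORY.get(prefix, cat)
    return cat


def _endpoint_ids(entry: Entry) -> tuple[str, ...]:
    """Global ids a relation endpoint expands to (groups stay opaque)."""
    if entry.category == "group":
        return (GROUP_PLACEHOLDER_PREFIX + entry.local_id,)
    return entry.names


def parse_kgml(source: str | bytes | Path) -> PathwayGraph:
    """Parse a KGML document from a path, XML string, or bytes.

    Raises :class:`KGMLParseError` on malformed XML or when the root
    ``pathway`` element lacks its ``name`` or ``org`` attribute.
    """
    try:
        if isinstance(source, Path) or (
            isinstance(source, str) and "<" not in source
        ):
            tree = etree.parse(str(source))
            root = tree.getroot()
        else:
            if isinstance(source, str):
                source = source.encode("utf-8")
            root = etree.fromstring(source)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise KGMLParseError(f"cannot parse KGML: {exc}") from exc

    if root.tag != "pathway":
        raise KGMLParseError(f"root element is <{root.tag}>, expected <pathway>")
    name = root.get("name")
    org = root.get("org")
    if not name or not org:
        raise KGMLParseError("pathway element must carry 'name' and 'org' attributes")
    pathway_id = name[5:] if name.startswith("path:") else name
    graph = PathwayGraph(
        pathway_id=pathway_id, title=root.get("title", ""), organism=org
    )

    # --- entries -----------------------------------------------------------
    for el in root.findall("entry"):
        local_id = el.get("id")
        if local_id is None:
            logger.warning("%s: entry without id skipped", pathway_id)
            continue
        names = tuple(
            tok for tok in (el.get("name") or "").split() if tok != "undefined"
        )
        members = tuple(
            c.get("id") for c in el.findall("component") if c.get("id") is not None
        )
        category = _entry_category(el.get("type", "other"), names)
        if category != "group" and not names:
            logger.warning(
                "%s: entry %s has no usable name, skipped", pathway_id, local_id
            )
            continue
        graph.entries.append(
            Entry(local_id=local_id, names=names, category=category, members=members)
        )
    by_id = graph.entry_by_id()
    # drop dangling group member references
    fixed_entries = []
    for e in graph.entries:
        if e.members:
            kept = tuple(m for m in e.members if m in by_id)
            if len(kept) != len(e.members):
                logger.warning(
                    "%s: group %s references missing members", graph.pathway_id,
                    e.local_id,
                )
            e = replace(e, members=kept)
        fixed_entries.append(e)
    graph.entries = fixed_entries
    by_id = graph.entry_by_id()

    # genes/enzymes catalyzing each reaction, from the entry 'reaction' attr
    catalysts: dict[str, list[str]] = {}
    for el in root.findall("entry"):
        if el.get("type") in ("gene", "enzyme", "ortholog") and el.get("reaction"):
            entry = by_id.get(el.get("id", ""))
            if entry is None:
                continue
            for rxn_name in el.get("reaction", "").split():
                catalysts.setdefault(rxn_name, []).extend(entry.names)

    # --- reactions ---------------------------------------------------------
    for el in root.findall("reaction"):
        rxn_name = (el.get("name") or "").split()
        reaction_id = rxn_name[0] if rxn_name else f"rn:unnamed_{el.get('id', '?')}"
        reversible = el.get("type") == "reversible"

        def _participants(tag: str) -> tuple[str, ...]:
            out: list[str] = []
            for child in el.findall(tag):
                ref = by_id.get(child.get("id", ""))
                if ref is not None and ref.names:
                    out.extend(ref.names)
                elif child.get("name"):
                    out.append(child.get("name"))
                else:
                    logger.warning(
                        "%s: reaction %s %s reference unresolved, dropped",
                        graph.pathway_id, reaction_id, tag,
                    )
            return tuple(dict.fromkeys(out))

        substrates = _participants("substrate")
        products = _participants("product")
        if not substrates or not products:
            logger.warning(
                "%s: reaction %s lacks substrates or products, dropped",
                graph.pathway_id, reaction_id,
            )
            continue
        modifiers = tuple(
            dict.fromkeys(
                m
                for tok in rxn_name
                for m in catalysts.get(tok, [])
            )
        )
        graph.reactions.append(
            MetabolicReaction(
                reaction_id=reaction_id,
                substrates=substrates,
                products=products,
                modifiers=modifiers,
                reversible=reversible,
            )
        )

    # --- relations ---------------------------------------------------------
    for el in root.findall("relation"):
        e1, e2 = by_id.get(el.get("entry1", "")), by_id.get(el.get("entry2", ""))
        if e1 is None or e2 is None:
            logger.warning(
                "%s: relation %s->%s references a missing entry, dropped",
                graph.pathway_id, el.get("entry1"), el.get("entry2"),
            )
            continue
        rel_type = el.get("type", "PPrel")
        if rel_type not in RELATION_TYPES:
            logger.warning(
                "%s: unknown relation type %r kept verbatim", graph.pathway_id,
                rel_type,
            )
        subtypes = tuple(
            s.get("name") for s in el.findall("subtype") if s.get("name")
        )
        for src in _endpoint_ids(e1):
            for tgt in _endpoint_ids(e2):
                graph.relations.append(
                    SignalRelation(
                        source=src, target=tgt, relation_type=rel_type,
                        subtypes=subtypes,
                    )
                )
    return graph


def classify_pathway(graph: PathwayGraph) -> str | None:
    """Route a parsed pathway: 'metabolic' if it has any reaction, else
    'signaling' if it has any relation, else None (with a warning).

    Mixed graphs classify as metabolic here but contribute their relations
    to the signaling merge as well — the merge routes each side separately.
    """
    if graph.reactions:
        return "metabolic"
    if graph.relations:
        return "signaling"
    logger.warning(
        "%s: pathway has neither reactions nor relations; excluded from merging",
        graph.pathway_id,
    )
    return None


def _resolve_group(
    local_id: str, by_id: dict[str, Entry], seen: frozenset[str]
) -> tuple[str, ...]:
    """Recursively flatten a group entry to the global ids of its members."""
    if local_id in seen:  # cycle guard
        logger.warning("group %s participates in a cycle, truncated", local_id)
        return ()
    entry = by_id.get(local_id)
    if entry is None:
        return ()
    if entry.category != "group":
        return entry.names
    out: list[str] = []
    for m in entry.members:
        out.extend(_resolve_group(m, by_id, seen | {local_id}))
    return tuple(dict.fromkeys(out))


def expand_groups(graph: PathwayGraph) -> PathwayGraph:
    """Replace group (complex) relation endpoints by one relation per member.

    Nested groups flatten recursively; empty groups are dropped with a
    warning, as are relations left without a resolvable endpoint. Group
    entries are removed from the result. Idempotent.
    """
    by_id = graph.entry_by_id()
    group_ids = {e.local_id for e in graph.entries if e.category == "group"}
    if not group_ids:
        return graph

    def _expand_endpoint(gid: str) -> tuple[str, ...]:
        if gid.startswith(GROUP_PLACEHOLDER_PREFIX):
            members = _resolve_group(
                gid[len(GROUP_PLACEHOLDER_PREFIX):], by_id, frozenset()
            )
            if not members:
                logger.warning(
                    "%s: empty group %s dropped", graph.pathway_id, gid
                )
            return members
        return (gid,)

    new_relations: list[SignalRelation] = []
    for rel in graph.relations:
        for src in _expand_endpoint(rel.source):
            for tgt in _expand_endpoint(rel.target):
                new_relations.append(replace(rel, source=src, target=tgt))
    return PathwayGraph(
        pathway_id=graph.pathway_id,
        title=graph.title,
        organism=graph.organism,
        entries=[e for e in graph.entries if e.category != "group"],
        reactions=list(graph.reactions),
        relations=new_relations,
    )


# --- serialization (round-trip support and fixture output) -----------------

_CATEGORY_TO_KGML_TYPE = {
    "gene": "gene",
    "compound": "compound",
    "glycan": "compound",  # glycans re-detected from the gl: name prefix
    "drug": "compound",
    "enzyme": "enzyme",
    "ortholog": "ortholog",
    "map": "map",
    "group": "group",
    "other": "other",
}


def write_kgml(graph: PathwayGraph, path: str | Path | None = None) -> bytes:
    """Serialize a :class:`PathwayGraph` back to KGML.

    Parsing the output yields a graph equal to the input (round-trip
    identity), provided relation endpoints are single global ids present
    in some entry — which is what :func:`parse_kgml` produces.
    """
    root = etree.Element(
        "pathway",
        name=f"path:{graph.pathway_id}",
        org=graph.organism,
        title=graph.title,
    )
    name_to_local: dict[str, str] = {}
    for e in graph.entries:
        for nm in e.names:
            name_to_local.setdefault(nm, e.local_id)
        name_to_local.setdefault(GROUP_PLACEHOLDER_PREFIX + e.local_id, e.local_id)

    # reactions catalyzed per gene entry (KGML links them via the entry attr)
    entry_reactions: dict[str, list[str]] = {}
    for rxn in graph.reactions:
        for mod in rxn.modifiers:
            local = name_to_local.get(mod)
            if local is not None:
                entry_reactions.setdefault(local, []).append(rxn.reaction_id)

    for e in graph.entries:
        attrs = {"id": e.local_id, "type": _CATEGORY_TO_KGML_TYPE[e.category]}
        if e.names:
            attrs["name"] = " ".join(e.names)
        if e.local_id in entry_reactions:
            attrs["reaction"] = " ".join(dict.fromkeys(entry_reactions[e.local_id]))
        el = etree.SubElement(root, "entry", **attrs)
        for m in e.members:
            etree.SubElement(el, "component", id=m)

    for i, rxn in enumerate(graph.reactions, start=1):
        el = etree.SubElement(
            root,
            "reaction",
            id=str(1000 + i),
            name=rxn.reaction_id,
            type="reversible" if rxn.reversible else "irreversible",
        )
        for s in rxn.substrates:
            etree.SubElement(
                el, "substrate", id=name_to_local.get(s, "0"), name=s
            )
        for p in rxn.products:
            etree.SubElement(el, "product", id=name_to_local.get(p, "0"), name=p)

    for rel in graph.relations:
        src = name_to_local.get(rel.source)
        tgt = name_to_local.get(rel.target)
        if src is None or tgt is None:
            raise KGMLParseError(
                f"{graph.pathway_id}: relation endpoint {rel.source!r} or "
                f"{rel.target!r} is not named by any entry; cannot serialize"
            )
        el = etree.SubElement(
            root, "relation", entry1=src, entry2=tgt, type=rel.relation_type
        )
        for st in rel.subtypes:
            etree.SubElement(el, "subtype", name=st, value="")

    data = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    if path is not None:
        Path(path).write_bytes(data)
    return data
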
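"""SBML Level 3 Version 1 serialization of super-networks.

One SBML model per network, with a single default compartment. Every
species appears exactly once. Metabolic interactions become reactions
with listed reactants, products and modifier species references (the
catalyzing genes); signaling interactions become two-participant
reactions whose *name* encodes the interaction subtype list (multiple
subtypes joined deterministically with "+"). Stoichiometry is fixed at 1
throughout: the output targets visualization and topology analysis, not
mass-balanced simulation.

Identifiers are sanitized into SBML SId tokens (``cpd:C00031`` →
``cpd_C00031``); the original identifier is kept as the species ``name``
attribute so the mapping is invertible. Fold changes, provenance and
relation types ride along in a package annotation namespace, keeping the
documents consumable by generic SBML tools while making
``read_sbml(write_sbml(net))`` the identity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .errors import SBMLError
from .netmodel import Interaction, SuperNetwork, _build_species

logger = logging.getLogger(__name__)

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
ANN_NS = "urn:x-pathweave:network"
_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_COMPARTMENT_ID = "default"


def sanitize_sid(raw: str) -> str:
    """Map an identifier to an SBML SId token (':' and other non-word
    characters become '_'; a leading digit gets an 'x' prefix)."""
    sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not sid or not re.match(r"[A-Za-z_]", sid[0]):
        sid = "x" + sid
    return sid


@dataclass
class ValidationReport:
    """Outcome of writing + validating one SBML document."""

    path: str
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _q(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _qa(tag: str) -> str:
    return f"{{{ANN_NS}}}{tag}"


def write_sbml(net: SuperNetwork, path: str | Path) -> ValidationReport:
    """Serialize ``net`` to SBML L3V1 at ``path``.

    The document is validated structurally before writing; it is written
    even when validation reports errors (the report carries them).
    """
    path = Path(path)
    nsmap = {None: SBML_NS, "pw": ANN_NS}
    root = etree.Element(_q("sbml"), nsmap=nsmap, level="3", version="1")
    model = etree.SubElement(
        root, _q("model"), id=f"{net.kind}_supernetwork", name=f"{net.kind} super-network"
    )
    comps = etree.SubElement(model, _q("listOfCompartments"))
    etree.SubElement(
        comps, _q("compartment"), id=_COMPARTMENT_ID, constant="true",
        spatialDimensions="3",
    )

    species_list = etree.SubElement(model, _q("listOfSpecies"))
    for sp in net.sorted_species():
        el = etree.SubElement(
            species_list,
            _q("species"),
            id=sanitize_sid(sp.global_id),
            name=sp.global_id,
            compartment=_COMPARTMENT_ID,
            hasOnlySubstanceUnits="false",
            boundaryCondition="false",
            constant="false",
        )
        if sp.fold_change is not None or sp.display_name != sp.global_id:
            ann = etree.SubElement(el, _q("annotation"))
            attrs = {}
            if sp.fold_change is not None:
                attrs["foldChange"] = repr(sp.fold_change)
            if sp.display_name != sp.global_id:
                attrs["displayName"] = sp.display_name
            etree.SubElement(ann, _qa("species"), **attrs)

    reactions_list = etree.SubElement(model, _q("listOfReactions"))
    for i, inter in enumerate(net.interactions, start=1):
        attrs = {
            "id": f"R{i:05d}",
            "reversible": "true" if inter.reversible else "false",
            "fast": "false",
        }
        if inter.kind == "signaling":
            attrs["name"] = "+".join(inter.subtypes) if inter.subtypes else (
                "+".join(inter.relation_types)
            )
        elif inter.reaction_ids:
            attrs["name"] = "+".join(inter.reaction_ids)
        el = etree.SubElement(reactions_list, _q("reaction"), **attrs)
        ann = etree.SubElement(el, _q("annotation"))
        etree.SubElement(
            ann,
            _qa("interaction"),
            kind=inter.kind,
            relationTypes=" ".join(inter.relation_types),
            subtypes=";".join(inter.subtypes),
            reactionIds=" ".join(inter.reaction_ids),
            provenance=" ".join(inter.provenance),
        )
        if inter.substrates:
            lst = etree.SubElement(el, _q("listOfReactants"))
            for s in inter.substrates:
                etree.SubElement(
                    lst, _q("speciesReference"), species=sanitize_sid(s),
                    stoichiometry="1", constant="true",
                )
        if inter.products:
            lst = etree.SubElement(el, _q("listOfProducts"))
            for p in inter.products:
                etree.SubElement(
                    lst, _q("speciesReference"), species=sanitize_sid(p),
                    stoichiometry="1", constant="true",
                )
        if inter.modifiers:
            lst = etree.SubElement(el, _q("listOfModifiers"))
            for m in inter.modifiers:
                etree.SubElement(
                    lst, _q("modifierSpeciesReference"), species=sanitize_sid(m)
                )

    errors = validate_sbml(root)
    data = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    path.write_bytes(data)
    if errors:
        logger.error("SBML validation: %d error(s) in %s", len(errors), path)
    return ValidationReport(path=str(path), errors=errors)


def validate_sbml(doc: etree._Element | str | Path) -> list[str]:
    """Structural consistency check of an SBML L3V1 core document.

    Verifies the namespace/level/version, that all SIds are valid tokens
    and globally unique, that species reference an existing compartment,
    and that every species reference resolves. Returns a list of error
    strings (empty when consistent).
    """
    if not isinstance(doc, etree._Element):
        try:
            doc = etree.parse(str(doc)).getroot()
        except (etree.XMLSyntaxError, OSError) as exc:
            return [f"cannot parse document: {exc}"]
    errors: list[str] = []
    if doc.tag != _q("sbml"):
        errors.append(f"root element is {doc.tag}, expected SBML L3V1 <sbml>")
        return errors
    if doc.get("level") != "3" or doc.get("version") != "1":
        errors.append("document does not declare level=3 version=1")
    model = doc.find(_q("model"))
    if model is None:
        errors.append("missing <model> element")
        return errors

    sids: list[str] = []
    if model.get("id"):
        sids.append(model.get("id"))
    compartments = {
        c.get("id") for c in model.iter(_q("compartment")) if c.get("id")
    }
    sids.extend(compartments)
    species_ids: set[str] = set()
    for sp in model.iter(_q("species")):
        sid = sp.get("id")
        if sid is None:
            errors.append("species without id")
            continue
        sids.append(sid)
        species_ids.add(sid)
        if sp.get("compartment") not in compartments:
            errors.append(f"species {sid}: unknown compartment")
        for req in ("hasOnlySubstanceUnits", "boundaryCondition", "constant"):
            if sp.get(req) is None:
                errors.append(f"species {sid}: missing required attribute {req}")
    for rxn in model.iter(_q("reaction")):
        rid = rxn.get("id")
        if rid is None:
            errors.append("reaction without id")
            continue
        sids.append(rid)
        if rxn.get("reversible") is None:
            errors.append(f"reaction {rid}: missing required attribute reversible")
        for ref in rxn.iter(_q("speciesReference"), _q("modifierSpeciesReference")):
            target = ref.get("species")
            if target not in species_ids:
                errors.append(f"reaction {rid}: unresolved species reference {target!r}")
            if ref.tag == _q("speciesReference"):
                st = ref.get("stoichiometry")
                if st is not None:
                    try:
                        float(st)
                    except ValueError:
                        errors.append(f"reaction {rid}: bad stoichiometry {st!r}")

    for sid in sids:
        if not _SID_RE.match(sid):
            errors.append(f"invalid SId token {sid!r}")
    seen: set[str] = set()
    for sid in sids:
        if sid in seen:
            errors.append(f"duplicate SId {sid!r}")
        seen.add(sid)
    return errors


def read_sbml(path: str | Path) -> SuperNetwork:
    """Read an SBML document written by :func:`write_sbml` back into a
    :class:`SuperNetwork` (roles are recomputed from the interactions)."""
    path = Path(path)
    try:
        root = etree.parse(str(path)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLError(f"cannot parse SBML file {path}: {exc}") from exc
    if root.tag != _q("sbml"):
        raise SBMLError(f"{path}: not an SBML L3V1 document")
    model = root.find(_q("model"))
    if model is None:
        raise SBMLError(f"{path}: missing <model>")
    model_id = model.get("id", "")
    kind = "metabolic" if model_id.startswith("metabolic") else "signaling"

    sid_to_gid: dict[str, str] = {}
    fold_changes: dict[str, float] = {}
    display_names: dict[str, str] = {}
    for sp in model.iter(_q("species")):
        sid = sp.get("id")
        gid = sp.get("name") or sid
        if sid in sid_to_gid:
            raise SBMLError(f"{path}: duplicate species id {sid!r}")
        if gid in sid_to_gid.values():
            raise SBMLError(f"{path}: duplicate species (global id {gid!r})")
        sid_to_gid[sid] = gid
        ann = sp.find(f"{_q('annotation')}/{_qa('species')}")
        if ann is not None:
            if ann.get("foldChange"):
                fold_changes[gid] = float(ann.get("foldChange"))
            if ann.get("displayName"):
                display_names[gid] = ann.get("displayName")

    def _refs(rxn, list_tag: str, ref_tag: str) -> tuple[str, ...]:
        lst = rxn.find(_q(list_tag))
        if lst is None:
            return ()
        out = []
        for ref in lst.iter(_q(ref_tag)):
            sid = ref.get("species")
            if sid not in sid_to_gid:
                raise SBMLError(f"{path}: unresolved species reference {sid!r}")
            out.append(sid_to_gid[sid])
        return tuple(out)

    interactions: list[Interaction] = []
    for rxn in model.iter(_q("reaction")):
        ann = rxn.find(f"{_q('annotation')}/{_qa('interaction')}")
        ikind = ann.get("kind") if ann is not None else kind
        interactions.append(
            Interaction(
                kind=ikind,
                substrates=_refs(rxn, "listOfReactants", "speciesReference"),
                products=_refs(rxn, "listOfProducts", "speciesReference"),
                modifiers=_refs(rxn, "listOfModifiers", "modifierSpeciesReference"),
                reversible=rxn.get("reversible") == "true",
                relation_types=tuple((ann.get("relationTypes") or "").split())
                if ann is not None else (),
                subtypes=tuple(
                    s for s in (ann.get("subtypes") or "").split(";") if s
                ) if ann is not None else (),
                reaction_ids=tuple((ann.get("reactionIds") or "").split())
                if ann is not None else (),
                provenance=tuple((ann.get("provenance") or "").split())
                if ann is not None else (),
            )
        )

    net = SuperNetwork(kind=kind, interactions=interactions)
    net.species = _build_species(interactions)
    # re-attach per-species extras
    from dataclasses import replace as _replace

    for gid in list(net.species):
        sp = net.species[gid]
        if gid in fold_changes:
            sp = _replace(sp, fold_change=fold_changes[gid])
        if gid in display_names:
            sp = _replace(sp, display_name=display_names[gid])
        net.species[gid] = sp
    # species present in the file but isolated from every interaction
    for sid, gid in sid_to_gid.items():
        if gid not in net.species:
            from .netmodel import ROLE_MODIFIER, Species

            net.species[gid] = Species(
                global_id=gid,
                display_name=display_names.get(gid, gid),
                role_class=ROLE_MODIFIER,
                fold_change=fold_changes.get(gid),
            )
    return net
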
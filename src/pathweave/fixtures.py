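"""Synthetic fixture generation: annotation tables, KGML maps, gene lists.

The generator emulates the offline inputs of the workflow so the whole
pipeline runs without any database access:

* an annotation TSV of randomized gene→pathway memberships over a shared
  gene pool (pathways overlap through the pool, as KEGG maps do);
* valid synthetic KGML files — half metabolic (compound entries joined
  into reaction chains, each reaction catalyzed by one pathway gene),
  half signaling (gene entries joined by typed relations with subtypes
  drawn from the common KEGG vocabulary), with a configurable fraction
  of compounds shared across maps so merging has real deduplication work
  to do;
* a gene list with a *planted signal*: the designated pathways' member
  genes are fully included, plus a few random noise genes, each with a
  log-normal fold change on the natural scale.

Everything is driven by one integer seed and the output is byte-identical
across runs with the same seed. The manifest records the ground truth
(planted pathways, expected merged species counts) for end-to-end tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kgml import Entry, MetabolicReaction, PathwayGraph, SignalRelation, write_kgml

SIGNAL_SUBTYPES = (
    "phosphorylation",
    "activation",
    "inhibition",
    "expression",
    "binding/association",
)
_SIGNAL_TYPE_FOR_SUBTYPE = {
    "expression": "GErel",
    "phosphorylation": "PPrel",
    "activation": "PPrel",
    "inhibition": "PPrel",
    "binding/association": "PPrel",
}


@dataclass
class FixtureSet:
    """In-memory fixture collection plus its ground-truth manifest."""

    organism: str
    memberships: dict[str, set[str]]
    graphs: list[PathwayGraph]
    gene_list: list[tuple[str, float]]
    planted: list[str]
    manifest: dict = field(default_factory=dict)


def generate_fixture_set(
    seed: int,
    n_pathways: int = 12,
    n_genes: int = 150,
    n_planted: int = 3,
    planted_size: int = 12,
    pathway_size_range: tuple[int, int] = (8, 25),
    species_overlap: float = 0.3,
    n_noise_genes: int = 5,
    organism: str = "syn",
    include_groups: bool = False,
) -> FixtureSet:
    """Build the synthetic study in memory (see module docstring).

    ``species_overlap`` is the probability that a compound slot of a
    metabolic map reuses the shared compound pool instead of a private
    compound, controlling how much the merged network deduplicates.
    Planted pathways alternate between the metabolic and signaling halves
    so both super-networks exist downstream.
    """
    if n_pathways < 2 or n_genes < 4 or n_planted < 1:
        raise ValueError("fixture sizes too small")
    if n_planted > n_pathways:
        raise ValueError("cannot plant more pathways than exist")
    rng = np.random.default_rng(seed)
    genes = [f"{organism}:G{i:04d}" for i in range(1, n_genes + 1)]

    n_metabolic = n_pathways // 2
    pathway_ids = [f"{organism}{100 + i:05d}" for i in range(n_metabolic)] + [
        f"{organism}{4100 + i:05d}" for i in range(n_pathways - n_metabolic)
    ]
    # alternate planted pathways across the two halves
    planted: list[str] = []
    for j in range(n_planted):
        half = j % 2
        idx = j // 2
        planted.append(
            pathway_ids[idx] if half == 0 else pathway_ids[n_metabolic + idx]
        )

    memberships: dict[str, set[str]] = {}
    for pid in pathway_ids:
        size = (
            planted_size
            if pid in planted
            else int(rng.integers(pathway_size_range[0], pathway_size_range[1] + 1))
        )
        size = min(size, n_genes)
        members = rng.choice(n_genes, size=size, replace=False)
        memberships[pid] = {genes[i] for i in members}

    shared_pool = [f"cpd:C9{i:04d}" for i in range(1, 41)]
    private_counter = [0]

    def _compound(pid: str) -> str:
        if rng.random() < species_overlap:
            return shared_pool[int(rng.integers(0, len(shared_pool)))]
        private_counter[0] += 1
        return f"cpd:P{private_counter[0]:05d}"

    graphs: list[PathwayGraph] = []
    metabolic_species: set[str] = set()
    signaling_species: set[str] = set()
    for p_idx, pid in enumerate(pathway_ids):
        member_genes = sorted(memberships[pid])
        metabolic = p_idx < n_metabolic
        graph = PathwayGraph(
            pathway_id=pid,
            title=f"Synthetic {'metabolic' if metabolic else 'signaling'} map {pid}",
            organism=organism,
        )
        if metabolic:
            # a chain of reactions c_i -> c_{i+1}, one catalyst gene each
            compounds = [_compound(pid) for _ in range(len(member_genes) + 1)]
            local = 1
            comp_local: dict[str, str] = {}
            for c in compounds:
                if c not in comp_local:
                    comp_local[c] = str(local)
                    graph.entries.append(
                        Entry(local_id=str(local), names=(c,), category="compound")
                    )
                    local += 1
            for g in member_genes:
                graph.entries.append(
                    Entry(local_id=str(local), names=(g,), category="gene")
                )
                local += 1
            for i, g in enumerate(member_genes):
                sub, prod = compounds[i], compounds[i + 1]
                if sub == prod:  # degenerate slot, skip
                    continue
                graph.reactions.append(
                    MetabolicReaction(
                        reaction_id=f"rn:R{pid[-4:]}{i:03d}",
                        substrates=(sub,),
                        products=(prod,),
                        modifiers=(g,),
                        reversible=bool(rng.random() < 0.3),
                    )
                )
            metabolic_species.update(
                s for r in graph.reactions for s in r.substrates + r.products
            )
            metabolic_species.update(m for r in graph.reactions for m in r.modifiers)
        else:
            local = 1
            gene_local: dict[str, str] = {}
            for g in member_genes:
                gene_local[g] = str(local)
                graph.entries.append(
                    Entry(local_id=str(local), names=(g,), category="gene")
                )
                local += 1
            pairs = [
                (member_genes[i], member_genes[i + 1])
                for i in range(len(member_genes) - 1)
            ]
            n_extra = max(1, len(member_genes) // 3)
            for _ in range(n_extra):
                a, b = rng.choice(len(member_genes), size=2, replace=False)
                pairs.append((member_genes[int(a)], member_genes[int(b)]))
            for src, tgt in pairs:
                subtype = SIGNAL_SUBTYPES[int(rng.integers(0, len(SIGNAL_SUBTYPES)))]
                graph.relations.append(
                    SignalRelation(
                        source=src,
                        target=tgt,
                        relation_type=_SIGNAL_TYPE_FOR_SUBTYPE[subtype],
                        subtypes=(subtype,),
                    )
                )
            if include_groups and len(member_genes) >= 3:
                gid = str(local)
                graph.entries.append(
                    Entry(
                        local_id=gid,
                        names=(),
                        category="group",
                        members=(
                            gene_local[member_genes[0]],
                            gene_local[member_genes[1]],
                        ),
                    )
                )
                graph.relations.append(
                    SignalRelation(
                        source=member_genes[-1],
                        target=f"grp:{gid}",
                        relation_type="PPrel",
                        subtypes=("binding/association",),
                    )
                )
            signaling_species.update(
                e for r in graph.relations for e in (r.source, r.target)
                if not e.startswith("grp:")
            )
            if include_groups:
                signaling_species.update(member_genes[0:2])
        graphs.append(graph)

    planted_genes: list[str] = []
    for pid in planted:
        planted_genes.extend(sorted(memberships[pid]))
    planted_genes = list(dict.fromkeys(planted_genes))
    non_planted = [g for g in genes if g not in set(planted_genes)]
    noise_idx = rng.choice(len(non_planted), size=min(n_noise_genes, len(non_planted)),
                           replace=False)
    input_genes = planted_genes + [non_planted[int(i)] for i in sorted(noise_idx)]
    order = rng.permutation(len(input_genes))
    fold = np.exp(rng.normal(0.0, 0.5, size=len(input_genes)))
    gene_list = [
        (input_genes[int(i)], float(round(fold[int(i)], 4))) for i in order
    ]

    manifest = {
        "seed": seed,
        "organism": organism,
        "n_pathways": n_pathways,
        "n_genes": n_genes,
        "pathway_ids": pathway_ids,
        "metabolic_pathways": pathway_ids[:n_metabolic],
        "signaling_pathways": pathway_ids[n_metabolic:],
        "planted_pathways": planted,
        "n_input_genes": len(gene_list),
        "expected_species": {
            "metabolic": len(metabolic_species),
            "signaling": len(signaling_species),
        },
    }
    return FixtureSet(
        organism=organism,
        memberships=memberships,
        graphs=graphs,
        gene_list=gene_list,
        planted=planted,
        manifest=manifest,
    )


def generate_fixtures(
    seed: int,
    n_pathways: int = 12,
    n_genes: int = 150,
    out_dir: str | Path = ".",
    **kwargs,
) -> dict:
    """Write a fixture set to disk and return its manifest.

    Layout: ``annotations.tsv``, ``genes.tsv``, ``kgml/<pathway_id>.xml``
    and ``manifest.json`` under ``out_dir``. Byte-identical per seed.
    """
    fs = generate_fixture_set(seed, n_pathways=n_pathways, n_genes=n_genes, **kwargs)
    out_dir = Path(out_dir)
    kgml_dir = out_dir / "kgml"
    kgml_dir.mkdir(parents=True, exist_ok=True)

    with open(out_dir / "annotations.tsv", "w", encoding="utf-8") as fh:
        fh.write("# gene_id\tpathway_id\n")
        for pid in sorted(fs.memberships):
            for g in sorted(fs.memberships[pid]):
                fh.write(f"{g}\tpath:{pid}\n")

    with open(out_dir / "genes.tsv", "w", encoding="utf-8") as fh:
        for g, fc in fs.gene_list:
            fh.write(f"{g}\t{fc}\n")

    for graph in fs.graphs:
        write_kgml(graph, kgml_dir / f"{graph.pathway_id}.xml")

    manifest = dict(fs.manifest)
    manifest["files"] = {
        "annotations": "annotations.tsv",
        "gene_list": "genes.tsv",
        "kgml_dir": "kgml",
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
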
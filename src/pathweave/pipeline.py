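"""End-to-end workflow driver.

Stages: load annotations → parse & background-restrict the gene list →
two-stage enrichment → parse the enriched pathways' KGML files →
group-expand → route reactions/relations into metabolic and signaling
merges → fold-change annotation → SBML + graph-JSON export, plus the
gene–pathway bipartite map and a machine-readable run report.

When the enriched set contains pathways of only one kind, only that
kind's SBML (and graph JSON) is produced.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from .annotation import (
    load_annotations,
    parse_gene_list,
    restrict_to_background,
)
from .enrichment import EnrichmentConfig, enrich, write_results_tsv
from .errors import PathweaveError
from .graph_export import (
    color_by_fold_change,
    gene_pathway_map,
    layout,
    write_graph_json,
)
from .kgml import expand_groups, parse_kgml
from .netmodel import annotate_fold_changes, merge
from .sbml_io import write_sbml

logger = logging.getLogger(__name__)


class StageError(PathweaveError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __init__(self):
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            if isinstance(exc, StageError):
                return False
            raise StageError(name, exc) from exc

    return _Ctx()


def run_pipeline(
    gene_list: str | Path,
    annotations: str | Path,
    kgml_dir: str | Path,
    organism: str,
    config: EnrichmentConfig | None = None,
    out_dir: str | Path = ".",
    layout_algorithm: str = "circular",
) -> dict:
    """Run the full workflow; returns (and writes) the run report."""
    config = config or EnrichmentConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kgml_dir = Path(kgml_dir)
    report: dict = {"organism": organism, "outputs": [], "stages": {}}

    with _stage("load"):
        store = load_annotations(annotations, organism)
        genes = parse_gene_list(gene_list)
        restricted, dropped = restrict_to_background(genes, store)
        report["stages"]["load"] = {
            "background_genes": store.n_background,
            "pathways": len(store.pathway_to_genes),
            "input_genes": len(genes),
            "genes_in_background": len(restricted),
            "genes_dropped": len(dropped),
        }

    with _stage("enrich"):
        results = enrich(restricted, store, config)
        report["stages"]["enrich"] = {
            "significant_pathways": len(results),
            "pathway_ids": [r.pathway_id for r in results],
        }

    with _stage("parse_kgml"):
        graphs = []
        titles: dict[str, str] = {}
        missing: list[str] = []
        for r in results:
            kgml_path = kgml_dir / f"{r.pathway_id}.xml"
            if not kgml_path.is_file():
                missing.append(r.pathway_id)
                logger.warning("no KGML file for enriched pathway %s", r.pathway_id)
                continue
            graph = expand_groups(parse_kgml(kgml_path))
            titles[graph.pathway_id] = graph.title
            graphs.append(graph)
        report["stages"]["parse_kgml"] = {
            "parsed": len(graphs),
            "missing_kgml": missing,
        }

    with _stage("write_results"):
        results_path = out_dir / "enrichment.tsv"
        write_results_tsv(results, results_path, descriptions=titles)
        report["outputs"].append(results_path.name)

    with _stage("merge_export"):
        merged = {}
        for kind, side in (
            ("metabolic", [g for g in graphs if g.reactions]),
            ("signaling", [g for g in graphs if g.relations]),
        ):
            if not side:
                continue
            net = merge(side, kind)
            if not net.interactions:
                continue
            net = annotate_fold_changes(net, restricted)
            merged[kind] = net
            sbml_path = out_dir / f"{kind}_supernetwork.sbml.xml"
            val = write_sbml(net, sbml_path)
            report["outputs"].append(sbml_path.name)
            vis = layout(net, algorithm=layout_algorithm, seed=config.seed)
            vis = color_by_fold_change(vis, restricted) if genes.fold_changes else vis
            json_path = out_dir / f"{kind}_supernetwork.json"
            write_graph_json(vis, json_path)
            report["outputs"].append(json_path.name)
            report["stages"].setdefault("merge", {})[kind] = {
                "source_pathways": len(side),
                "species": len(net.species),
                "interactions": len(net.interactions),
                "sbml_validation_errors": len(val.errors),
            }

    with _stage("gene_pathway_map"):
        if results:
            gp = gene_pathway_map(restricted, results, store)
            gp_path = out_dir / "gene_pathway_map.json"
            write_graph_json(gp, gp_path)
            report["outputs"].append(gp_path.name)
            report["stages"]["gene_pathway_map"] = {
                "genes": sum(
                    1 for n in gp.nodes if n.color != "pathway"
                ),
                "pathways": sum(1 for n in gp.nodes if n.color == "pathway"),
                "edges": len(gp.edges),
            }

    report_path = out_dir / "run_report.json"
    report_path.write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
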
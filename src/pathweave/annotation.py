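"""Flat-file annotation store: organism-scoped gene→pathway membership tables.

The store is the statistical background ("universe") for over-representation
analysis: every annotated gene of the organism, together with the membership
of each KEGG-style pathway. It is loaded from plain two-column TSV files
(``gene_id<TAB>pathway_id``, ``#`` comment lines allowed) so that the whole
workflow runs offline and is testable without any database service.

Gene identifiers are normalized once, on the way in, and the same rule is
applied to user gene lists so identifiers compare equal across sources:
whitespace is trimmed; a ``db:ACC`` identifier keeps its accession verbatim
with the database prefix lowercased (``HSA:3630`` → ``hsa:3630``); a bare
symbol is uppercased (``tp53`` → ``TP53``). No cross-namespace identifier
translation is attempted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    EmptyIntersectionError,
    EmptyStoreError,
    GeneListParseError,
    InputError,
)

logger = logging.getLogger(__name__)

_PATHWAY_ORG_RE = re.compile(r"^(?:path:)?([a-z]{2,5})\d+$")


def normalize_gene_id(raw: str) -> str:
    """Normalize a gene identifier (see module docstring for the rule)."""
    s = raw.strip()
    if ":" in s:
        prefix, rest = s.split(":", 1)
        return f"{prefix.strip().lower()}:{rest.strip()}"
    return s.upper()


def normalize_pathway_id(raw: str) -> str:
    """Strip whitespace and a leading ``path:`` prefix from a pathway id."""
    s = raw.strip()
    if s.lower().startswith("path:"):
        s = s[5:]
    return s


def _row_organism(gene_id: str, pathway_id: str) -> str | None:
    """Infer the organism code of an annotation row, or None if unscoped.

    The gene-id database prefix wins (``hsa:3630`` → ``hsa``); otherwise the
    pathway id is matched against the ``<org><digits>`` KEGG pattern.
    """
    if ":" in gene_id:
        return gene_id.split(":", 1)[0]
    m = _PATHWAY_ORG_RE.match(pathway_id.lower())
    if m:
        return m.group(1)
    return None


@dataclass(frozen=True)
class AnnotationStore:
    """Gene↔pathway membership for one organism.

    ``gene_to_pathways`` and ``pathway_to_genes`` are exact transposes;
    ``background_genes`` is the union of all pathway member sets and serves
    as the enrichment universe N.
    """

    organism: str
    gene_to_pathways: dict[str, frozenset[str]]
    pathway_to_genes: dict[str, frozenset[str]]

    @property
    def background_genes(self) -> frozenset[str]:
        return frozenset(self.gene_to_pathways)

    @property
    def n_background(self) -> int:
        return len(self.gene_to_pathways)

    @property
    def pathways(self) -> list[str]:
        return sorted(self.pathway_to_genes)

    def pathway_size(self, pathway_id: str) -> int:
        return len(self.pathway_to_genes[pathway_id])


@dataclass
class GeneList:
    """Ordered, de-duplicated list of input genes with optional fold changes.

    Fold changes are on the natural scale (ratio of expression between
    conditions, strictly positive; 1 means unchanged).
    """

    entries: list[tuple[str, float | None]] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def fold_changes(self) -> dict[str, float]:
        return {g: fc for g, fc in self.entries if fc is not None}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _iter_annotation_rows(path: Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputError(
                    f"{path}:{lineno}: expected gene_id<TAB>pathway_id, got {line!r}"
                )
            yield fields[0], fields[1]


def load_annotations(path: str | Path, organism: str) -> AnnotationStore:
    """Load an :class:`AnnotationStore` for ``organism`` from TSV.

    ``path`` may be a single TSV file or a directory; in a directory,
    ``<organism>.tsv`` is preferred, then ``annotations.tsv``. Rows
    attributable to a different organism are ignored; rows without any
    organism marker are kept. Duplicate rows collapse (set semantics).

    Raises
    ------
    InputError
        if the file is missing or malformed.
    EmptyStoreError
        if no row for the requested organism remains.
    """
    path = Path(path)
    if path.is_dir():
        for candidate in (path / f"{organism}.tsv", path / "annotations.tsv"):
            if candidate.is_file():
                path = candidate
                break
        else:
            raise InputError(f"no annotation TSV for organism {organism!r} in {path}")
    if not path.is_file():
        raise InputError(f"annotation file not found: {path}")

    organism = organism.strip().lower()
    gene_to_pathways: dict[str, set[str]] = {}
    pathway_to_genes: dict[str, set[str]] = {}
    n_skipped = 0
    for raw_gene, raw_pathway in _iter_annotation_rows(path):
        gene = normalize_gene_id(raw_gene)
        pathway = normalize_pathway_id(raw_pathway)
        if not gene or not pathway:
            continue
        org = _row_organism(gene, pathway)
        if org is not None and org != organism:
            n_skipped += 1
            continue
        gene_to_pathways.setdefault(gene, set()).add(pathway)
        pathway_to_genes.setdefault(pathway, set()).add(gene)

    if not gene_to_pathways:
        raise EmptyStoreError(
            f"{path}: no annotation rows for organism {organism!r}"
            + (f" ({n_skipped} rows for other organisms skipped)" if n_skipped else "")
        )
    if n_skipped:
        logger.info("load_annotations: skipped %d rows for other organisms", n_skipped)
    return AnnotationStore(
        organism=organism,
        gene_to_pathways={g: frozenset(ps) for g, ps in gene_to_pathways.items()},
        pathway_to_genes={p: frozenset(gs) for p, gs in pathway_to_genes.items()},
    )


def build_store(
    organism: str, memberships: dict[str, set[str] | frozenset[str]]
) -> AnnotationStore:
    """Build a store in memory from ``pathway_id -> gene set`` memberships.

    Convenience constructor used by the fixture generator and tests; applies
    the same normalization and invariants as :func:`load_annotations`.
    """
    gene_to_pathways: dict[str, set[str]] = {}
    pathway_to_genes: dict[str, set[str]] = {}
    for raw_p, genes in memberships.items():
        p = normalize_pathway_id(raw_p)
        for raw_g in genes:
            g = normalize_gene_id(raw_g)
            gene_to_pathways.setdefault(g, set()).add(p)
            pathway_to_genes.setdefault(p, set()).add(g)
    if not gene_to_pathways:
        raise EmptyStoreError("no gene-pathway memberships supplied")
    return AnnotationStore(
        organism=organism.strip().lower(),
        gene_to_pathways={g: frozenset(ps) for g, ps in gene_to_pathways.items()},
        pathway_to_genes={p: frozenset(gs) for p, gs in pathway_to_genes.items()},
    )


def parse_gene_list(path: str | Path) -> GeneList:
    """Parse a tab-delimited gene list, one gene per line.

    Each nonblank line is ``gene_id`` or ``gene_id<TAB>fold_change`` with the
    fold change on the natural scale; 1- and 2-field lines may be mixed.
    Duplicate identifiers (after normalization) collapse to their first
    occurrence with a logged warning.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"gene list not found: {path}")
    entries: list[tuple[str, float | None]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            gene = normalize_gene_id(fields[0])
            if not gene:
                raise GeneListParseError(f"{path}:{lineno}: empty gene identifier")
            fc: float | None = None
            if len(fields) > 1 and fields[1].strip():
                try:
                    fc = float(fields[1])
                except ValueError:
                    raise GeneListParseError(
                        f"{path}:{lineno}: non-numeric fold change {fields[1]!r}"
                    ) from None
                if not fc > 0:
                    raise GeneListParseError(
                        f"{path}:{lineno}: fold change must be strictly positive "
                        f"(natural scale), got {fc}"
                    )
            if gene in seen:
                logger.warning(
                    "%s:%d: duplicate gene %s collapsed (first occurrence kept)",
                    path,
                    lineno,
                    gene,
                )
                continue
            seen.add(gene)
            entries.append((gene, fc))
    if not entries:
        raise InputError(f"{path}: gene list is empty")
    return GeneList(entries)


def restrict_to_background(
    genes: GeneList, store: AnnotationStore
) -> tuple[GeneList, list[str]]:
    """Keep only genes present in the store background, preserving order.

    Returns the restricted list and the dropped identifiers. Raises
    :class:`EmptyIntersectionError` when nothing remains (the hypergeometric
    counts would be undefined).
    """
    background = store.background_genes
    kept = [(g, fc) for g, fc in genes.entries if g in background]
    dropped = [g for g, _ in genes.entries if g not in background]
    if not kept:
        raise EmptyIntersectionError(
            f"none of the {len(genes)} input genes are annotated for organism "
            f"{store.organism!r}; enrichment is undefined"
        )
    if dropped:
        logger.info(
            "restrict_to_background: dropped %d/%d genes absent from background",
            len(dropped),
            len(genes),
        )
    return GeneList(kept), dropped
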
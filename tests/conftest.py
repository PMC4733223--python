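"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from pathweave import GeneList, build_store


@pytest.fixture
def toy_store():
    """10-gene background, 3 pathways with known overlaps."""
    return build_store(
        "syn",
        {
            "p1": {f"g{i}" for i in range(1, 5)},       # K=4
            "p2": {f"g{i}" for i in range(3, 9)},       # K=6
            "p3": {f"g{i}" for i in range(8, 11)},      # K=3
        },
    )


@pytest.fixture
def random_store():
    """Factory for randomized membership stores (seeded)."""

    def _make(seed: int, n_genes: int = 30, n_pathways: int = 6,
              size_range: tuple[int, int] = (3, 12)):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n_genes)]
        memberships = {}
        for j in range(n_pathways):
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            members = rng.choice(n_genes, size=min(size, n_genes), replace=False)
            memberships[f"p{j:02d}"] = {genes[i] for i in members}
        return build_store("syn", memberships)

    return _make


def gene_list(ids, fold_changes=None):
    fold_changes = fold_changes or {}
    return GeneList([(g, fold_changes.get(g)) for g in ids])


@pytest.fixture(name="gene_list_factory")
def _gene_list_factory():
    return gene_list


def brute_force_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] by exhaustive enumeration of all C(N, n) draws.

    The pathway is the first K background elements; every size-n subset is
    enumerated and counted exactly (integer arithmetic throughout).
    """
    pathway = set(range(K))
    favorable = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if len(pathway.intersection(draw)) >= k
    )
    return favorable / math.comb(N, n)


def enumerate_null_probabilities(store, n: int) -> dict[tuple[int, int], float]:
    """Exact enrichment-cell probabilities over all C(N, n) subsets.

    Returns P[cell (k, K)] under one uniformly drawn subset and one
    uniformly chosen pathway, including zero-overlap cells — the exact law
    the resampled null table estimates.
    """
    background = sorted(store.background_genes)
    pathways = store.pathways
    total = math.comb(len(background), n) * len(pathways)
    counts: dict[tuple[int, int], int] = {}
    for draw in itertools.combinations(background, n):
        s = set(draw)
        for p in pathways:
            members = store.pathway_to_genes[p]
            cell = (len(s & members), len(members))
            counts[cell] = counts.get(cell, 0) + 1
    return {cell: c / total for cell, c in counts.items()}


MINIMAL_METABOLIC_KGML = """<?xml version="1.0"?>
<pathway name="path:syn00010" org="syn" title="Toy glycolysis fragment">
  <entry id="1" name="cpd:C00031" type="compound"/>
  <entry id="2" name="cpd:C00668" type="compound"/>
  <entry id="3" name="syn:G0001" type="gene" reaction="rn:R01786"/>
  <reaction id="10" name="rn:R01786" type="irreversible">
    <substrate id="1" name="cpd:C00031"/>
    <product id="2" name="cpd:C00668"/>
  </reaction>
</pathway>
"""

MINIMAL_SIGNALING_KGML = """<?xml version="1.0"?>
<pathway name="path:syn04010" org="syn" title="Toy kinase cascade">
  <entry id="1" name="syn:G0001" type="gene"/>
  <entry id="2" name="syn:G0002" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="phosphorylation" value="+p"/>
  </relation>
</pathway>
"""
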
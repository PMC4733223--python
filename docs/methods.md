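# Methods

## Scope and model

`pathweave` implements a knowledge-based over-representation workflow:
given a set of differentially expressed genes, find the annotated
pathways containing more of them than chance predicts, then reconstruct
what those pathways jointly describe as two merged molecular networks —
one of metabolic reactions, one of signaling interactions. The package
deliberately targets *visualization and topology*, not simulation: KEGG
pathway maps carry neither stoichiometry nor cofactors, so the exported
SBML fixes every stoichiometry at 1 and makes no mass-balance claims.

## Enrichment statistic

**Universe.** The background N is the set of genes annotated to at least
one pathway of the organism in the loaded store — not the genome — so
that N, K and n are counted in the same space. Input genes outside the
background are dropped (reported) before testing; an empty intersection
is an error rather than a silent zero.

**Hypergeometric stage.** The upper tail P[X ≥ k] is computed as a sum of
exp(log-gamma) pmf terms rather than as 1 − CDF, keeping relative
accuracy ~1e-14 even for tails around 1e-13, where a complement would
cancel catastrophically. Terms with n − i > N − K are structurally zero
and excluded from the summation range.

**Bootstrap stage.** The null resamples uniform gene sets of the observed
size n from the background *without replacement* — matching the sampling
model of the hypergeometric despite the conventional "bootstrap" name —
and tallies the enrichment cell (k, K) of every pathway in every
resample, zero-overlap cells included. Keeping the (0, K) cells makes the
frequency table a probability distribution (it sums to exactly 1 over
cells at the documented denominator R·P) without affecting any p-value,
since no zero cell can be "at least as extreme" as an observed cell with
k ≥ 1.

The extremeness ordering — cell (k′, K′) counts against observed (k, K)
iff k′ ≥ k and k′/K′ ≥ k/K — is this package's own choice of what "less
frequently observed enrichment" means: an enrichment is beaten only by
null cells that are simultaneously at least as large and at least as
dense. The predicate is isolated in one function
(`enrichment.is_at_least_as_extreme`) so alternative orderings can be
swapped in. The +1/+1 pseudocount keeps bootstrap p-values in (0, 1] and
strictly positive for never-observed cells. R defaults to 1000 resamples,
a conventional figure balancing the p-value floor 1/(R·P+1) against run
time; the resampling loop is single-threaded and bit-reproducible given
the seed (subsets are drawn as the n smallest of N iid uniforms, chunked
to bound memory).

**Dual filter and ranking.** A pathway is significant iff its
hypergeometric p ≤ the threshold (default 0.01) *and* its bootstrap p
lies at or below the configured percentile (default 90) of the bootstrap
p-values of all scored pathways. The percentile semantics — cut the worst
(1 − c/100) tail of the observed bootstrap-p distribution, with c = 100
disabling the filter — is a design choice; the parameter's original
description names it without defining it, and the defining references
were not available to this implementation. Survivors are ranked ascending
by bootstrap p, ties broken by hypergeometric p and then lexicographic
pathway id, which makes output ordering total and reproducible.

**What the bootstrap p is not.** Because cells are pooled over pathways
of different sizes, the bootstrap p-value is a *ranking score* with an
approximate-p interpretation: it is strongly conservative in the low tail
(verified by simulation), but as a discrete statistic its largest atom
sits below 1, so its ECDF necessarily crosses the uniform near the top.
Classical multiple-testing corrections are deliberately not offered.

## Annotation store and identifiers

The store is a two-column TSV (`gene_id<TAB>pathway_id`); gene→pathway
and pathway→gene maps are exact transposes, every pathway has ≥ 1 member.
Rows are attributed to an organism by the gene-id prefix (`hsa:1234`),
falling back to the `path:<org><digits>` pattern; unprefixed rows match
any organism. Identifier normalization is minimal and uniform everywhere:
trim whitespace, lowercase the database prefix, uppercase bare symbols.
No Entrez↔symbol or EC↔gene translation is attempted — identifiers are
assumed to already live in the annotation's namespace.

## KGML parsing and network merging

Parsing is tolerant (missing optional attributes, dangling references
dropped with warnings) and ignores all graphics elements. Structural
content decides the pathway kind: any reaction ⇒ metabolic side, any
relation ⇒ signaling side; mixed maps contribute each side to its own
merge. Multi-gene entry boxes fan out to one modifier/relation per gene,
because merged-network nodes must be single biological entities. Group
(complex) entries stay opaque placeholders until `expand_groups`
flattens them recursively into one relation per member; the expansion is
idempotent. Entries linking to other maps are navigational and excluded
from merged networks.

Merging deduplicates species by normalized global id and interactions by
identity key: metabolic = (substrate set, product set, modifier set) with
reversible reactions canonicalized so direction is ignored; signaling =
(source, target, subtype set). Collapsed duplicates union their
provenance, reaction ids and relation types, and reversibility merges by
OR — all order-free operations, which is what makes the merge provably
independent of input order. Species roles (reactant-only, product-only,
reactant-and-product, modifier) are recomputed from the merged
interactions; both sides of a reversible reaction count as reactant and
product.

## SBML output

Documents are SBML Level 3 Version 1 core, one default compartment,
species constant=false, stoichiometry 1, `fast="false"`. KEGG-style ids
map to SId tokens by replacing non-word characters with `_` (injective on
the `db:ACC` id space; the original id is preserved as the species
`name`). Signaling relation subtypes join with `+` into the reaction
name; relation types, provenance and fold changes ride in a dedicated
annotation namespace so generic SBML tools can ignore them while
`read_sbml ∘ write_sbml` stays the identity. An internal structural
validator (namespace/level/version, SId syntax and global uniqueness,
required attributes, resolvable species/compartment references) must
report zero errors for every written document; round-trip identity is
enforced on top of it in the tests.

## Visualization export

Graphs are emitted as plain JSON with semantic color classes instead of
RGB so the renderer owns the palette. Metabolic reactions are reified as
nodes (substrate → reaction → product, modifier → reaction); signaling
relations are labelled edges. Node size is 1 + number of distinct first
neighbors, making size strictly increasing in degree. The circular layout
places the five role classes on five concentric rings, reactions
innermost; the random layout is a seeded uniform scatter; the
force-directed layout is Fruchterman–Reingold (networkx implementation)
at a fixed 200 iterations with a fixed seed, so coordinates are
reproducible. Fold-change coloring maps natural-scale values to
`up` (> 1), `down` (< 1), `constant` (= 1) and `no-info` (absent); the
conventional rendering is up=green, down=red, no-info=gray, but only the
classes are exported because published conventions disagree. The
gene–pathway map is two concentric rings (genes inner, enriched pathways
outer) with one edge per membership, so the edge count equals
Σ_p |genes(p) ∩ input| by construction — verified against an independent
set-intersection count.

## Synthetic studies (what the fixtures emulate — and don't)

The generator builds an annotation table of 12 pathways over 150 genes
(sizes 8–25, drawn uniformly from a common pool so pathways overlap),
KGML maps for each — metabolic maps as compound chains with one catalyst
gene per reaction, ~30% of compound slots drawn from a shared pool so
merging has real deduplication work; signaling maps as gene chains plus
random extra edges with subtypes from the common KEGG vocabulary — and an
input list containing *all* genes of three planted pathways plus five
random noise genes, with log-normal(0, 0.5) fold changes. These defaults
are the package's standing test conditions; single-seed determinism is
byte-exact.

What the fixtures do not emulate: realistic pathway size distributions
(KEGG maps range to hundreds of genes), hub genes shared by dozens of
maps, multi-gene entry boxes, inconsistencies between KGML and the drawn
map images, or partially overlapping planted signals. Passing tests
therefore demonstrate correctness of the machinery and calibration under
the stated null, not performance on any particular organism's database.

## Numerical and degenerate-input choices

- Quantile for the bootstrap cutoff: `numpy.quantile` with linear
  interpolation, inclusive comparison; c = 100 therefore keeps all.
- Empty pathway score table → empty enrichment result (not an error);
  empty gene list, empty store, empty background intersection → typed
  errors naming the cause.
- Empty super-network → valid SBML with zero species/reactions; empty
  graph → empty JSON document.
- Ties everywhere are broken lexicographically; every output (TSV, SBML,
  JSON) is emitted in a deterministic order, which is what the byte-level
  determinism guarantee rests on.
- Problem sizes in the automated checks (N ≤ 12 exhaustive enumeration,
  200-gene/20-pathway calibration store with 1000 simulated lists,
  50,000-resample null on a 6-gene background, 20 planted-recovery
  studies, 100 merge permutations, 50 SBML round-trips) were chosen so
  each check is exhaustive or has narrow Monte-Carlo error at desk scale.

## Known limitations

- The bootstrap score pools cells across pathways; per-pathway calibrated
  p-values would require stratifying the null by pathway size.
- Cross-namespace identity (EC numbers vs gene ids for the same enzyme)
  is not unified; such species appear as distinct nodes.
- The optional `fetch` verb performs a one-shot REST download and is the
  only code path touching the network; it is excluded from the test
  surface and from all library calls.
- SBML validation is structural (identifier, reference and attribute
  consistency); it does not re-implement the full SBML rule catalogue.
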
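# Methods

## Compartment condensation

The Gene Ontology Cellular Component aspect is a DAG in which annotation to
a term implies localization within every ancestor reached through `is_a`
("caveola is a plasma membrane region") and `part_of` ("ribosomal subunit is
part of ribosome") edges.  A *compartment* here is one high-level parent
term together with its full descendant closure over those two relation
types.  Other edge types (`regulates`, cross-aspect links) do not imply
spatial containment and are excluded; the relation set is an argument of
`build_compartments` for users who disagree.

The shipped standard view defines 14 compartments (cytoplasm, cytoskeleton,
endoplasmic reticulum, endosome, extracellular region, Golgi apparatus,
intracellular vesicle, lysosome, mitochondrion, nucleus, peroxisome, plasma
membrane, ribosome, vacuole).  The vacuole entry (`GO:0005773`) is our
inference for completing the set of major membrane-bound organelles in
results tables; it is flagged here because, unlike the other thirteen, its
parent-term choice is not standard across condensation schemes.  The
endosomal view (early `GO:0005769`, late `GO:0005770`, recycling
`GO:0055037` endosomes, lysosome, Golgi, intracellular vesicle, plasma
membrane) targets trafficking experiments, where the coarse "endosome"
label hides exactly the distinctions of interest.  Both tables are plain
TSV data (`src/gocellmap/data/compartments.tsv`), not code, because the
"right" parents drift with ontology releases and species, and users must be
able to fix them without patching the package.

Member sets deliberately overlap: a lysosomal term is also a cytoplasmic
term, and the per-gene membership matrix (UpSet counts) exists precisely to
expose this.  Obsolete terms are excluded from closures, and annotations to
them are dropped.

## Annotations, identifiers, universe

GAF 2.x records are used when: aspect is `C`, and no `NOT` qualifier is
present (a `NOT` annotation is evidence against a localization).  Evidence
codes are all accepted by default, including electronic (IEA) annotations
— large-scale CC annotation is heavily electronic and excluding it would
gut the gene sets — but an exclusion list can be passed for stricter
analyses.

Identifier cleaning removes duplicates, unknown identifiers, and accessions
whose mapped symbols fall outside the universe, each reported separately and
never silently.  Gene identity is the upper-cased symbol for human and rat
(case-insensitive nomenclature) and the exact symbol otherwise (mouse/fly
symbols are case-meaningful); UniProt accessions are resolved through a
user-supplied mapping table first.

The default universe is every gene appearing in the annotation source,
whether or not it carries a CC annotation — the natural "whole annotated
genome" population.  A user background restricts the universe to
`background ∩ universe`; compartment sizes K and the query size n are then
recomputed inside it.  Query genes absent from the background are dropped
from n (with a warning) rather than added to the background, because a gene
that could not have been sampled must not appear in the draw.

## The test

Per compartment, the upper-tail hypergeometric probability
P(X ≥ k), X ~ Hypergeometric(N, K, n), computed through the survival
function (log-space internally in SciPy, stable far beyond N ~ 1e5).  Only
over-representation is tested; depletion is out of scope.  p-values that
underflow double precision are floored at the smallest normal double
(2.2e-308) so that downstream BH and log-scale colouring stay defined —
the same magnitude at which extreme results are conventionally printed.

BH-FDR is applied across exactly the hypotheses emitted: the 14 compartments
in the compartment table, or the emitted rows in the per-term table (terms
with zero query genes are not hypotheses and are not emitted).  No
minimum-set-size filter is applied at either level; the compartment sets
are all large by construction, and the term table documents k/K explicitly
so users can judge small sets themselves.

The "highest enriched compartment" is the row with minimal FDR, ties broken
by smaller p, then larger overlap k, then alphabetical name; it is reported
even when non-significant, because a rank-level answer ("which compartment
fits best") is useful in QC even when no compartment passes the threshold.

## Visualization

Geometry is data: each view is an SVG template with regions identified by
`class="compartment-region"` and `id` = compartment name (spaces →
underscores).  Rendering recolours fills only: FDR < threshold maps to a
sequential colormap (default `Reds`) on −log10(FDR) between `vmin`
(default −log10(threshold)) and `vmax` (default 10, i.e. saturation at
FDR = 1e-10); FDR ≥ threshold is white.  FDR is floored at 1e-300 before
the log.  The colormap range is entered at 0.15 rather than 0 so a
just-significant compartment is visibly non-white.  Output is deterministic:
no timestamps, fixed element order, byte-identical across runs.  PNG export
rasterizes the template's primitive shapes (rect/circle/ellipse/text) with
matplotlib; arbitrary SVG is not supported.

## Synthetic studies

The generator emulates the whole input stack: a random DAG ontology
(designated compartment roots are parentless; each later term attaches to
1–2 uniformly chosen earlier terms, guaranteeing acyclicity; 70% `is_a`,
30% `part_of`), serialized as genuine OBO so the real parser is exercised;
a genuine GAF corpus in which each gene is annotated to
max(1, Poisson(mean)) uniformly chosen terms; and query lists with
`round(signal_fraction · n_query)` genes sampled from a target compartment's
true set and the rest drawn uniformly from the remaining universe.  The
generator records its own ground truth (term closures by its own forward
reachability, gene sets derived from them), which the library is tested
against.

Defaults — 200 terms, 14 compartments, 2,000 genes, ~2 annotations per
gene, a 50-gene query with 60% signal — are sized as a mid-scale
organelle-proteomics study: compartment gene sets around 10–70% of the
universe with the planted target chosen near 10%, and a query of plausible
hit-list size and purity.  All randomness flows from one
`numpy.random.default_rng(seed)` per generation call; identical seeds give
byte-identical files on any platform.

What the generator does *not* emulate: annotation bias (real CC annotation
depth varies enormously by gene), evidence-code structure, correlated
multi-compartment localization, or the heavy-tailed term-size distribution
of the real ontology.  Passing tests therefore demonstrate the statistics,
closures and plumbing are correct — not that any particular biological
conclusion from real GO data is.

## Numerical and design choices

- Hypergeometric via `scipy.stats.hypergeom.sf`; validated against exact
  exhaustive enumeration (all universes N ≤ 12, ~3,200 cases, agreement to
  1e-12) in the acceptance suite.
- BH via `statsmodels.stats.multitest.multipletests(method="fdr_bh")`,
  validated against a hand-written step-up implementation on 1,000 random
  vectors.
- Closure via reversed-edge traversal on a `networkx` multigraph, validated
  against an independent reachability oracle on 100 random DAGs.
- Sorting everywhere uses stable mergesort with explicit tie-break keys, so
  tables and files are deterministic.
- Degenerate inputs: empty OBO/GAF documents, empty cleaned queries, and
  backgrounds disjoint from the universe raise informative errors;
  unknown/duplicate identifiers are reported, never raised.

## Problem sizes

The test and acceptance workloads are sized to what the statistics need,
not more: exhaustive enumeration up to N = 12 (beyond which enumeration
adds no information over the closed form), 100 random DAGs up to 500 terms,
100 independent planted studies at the default study conditions for the
recovery rate, and 1,000 null queries on one fixture for type-I
calibration (Monte-Carlo standard error ≈ 0.007 at the 0.05 level).

## Known limitations

- Term-merge history, `regulates` edges and cross-products in GO releases
  are ignored; only `is_a`/`part_of` (configurable) drive closures.
- Isoform-level annotations (GAF column 17) are collapsed to the gene.
- Compartment definitions are a snapshot; exact child-term counts and gene
  counts depend on the GO/annotation release used to build resources.
- The hypergeometric model treats genes as exchangeable; annotation-depth
  bias in real corpora violates this, as it does for all over-representation
  analysis.
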
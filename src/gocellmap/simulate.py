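"""Synthetic ontologies, annotations, and planted-signal query lists.

Everything downstream of the parsers can be exercised without downloading a
GO release: this module emits a random acyclic ontology as real OBO text, a
random annotation corpus as real GAF 2.2 text, and query lists with a known
fraction of genes planted in one target compartment.  The generator records
its own ground truth (term closures, gene sets) by independent bookkeeping,
which the parsing and closure machinery is tested against.

All randomness flows from a single :class:`numpy.random.Generator` seeded by
``SynthConfig.seed``; identical configs give byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import CompartmentGeneSets, GeneUniverse
from .ontology import CompartmentEntry, CompartmentTable

__all__ = [
    "SynthConfig",
    "SynthOntology",
    "SynthAnnotations",
    "synth_ontology",
    "synth_annotations",
    "synth_query",
    "pick_target_compartment",
    "write_bundle",
]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the synthetic study.

    Defaults emulate a mid-sized spatial-proteomics setting: a 2,000-gene
    universe annotated over a 200-term compartment ontology (so each major
    compartment collects roughly 10% of the universe), ~2 cellular-component
    annotations per gene, and a 50-gene query of which 60% come from the
    compartment of interest — the signal strength of a reasonably clean
    organelle-specific protein list.
    """

    n_terms: int = 200
    n_compartments: int = 14
    n_genes: int = 2000
    mean_annotations_per_gene: float = 2.0
    signal_fraction: float = 0.6
    n_query: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_terms, self.n_compartments, self.n_genes, self.n_query) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_compartments > self.n_terms:
            raise ValueError("need at least one term per compartment")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.n_query > self.n_genes:
            raise ValueError("query cannot exceed the universe")
        if self.mean_annotations_per_gene <= 0:
            raise ValueError("mean_annotations_per_gene must be positive")


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def _gene_id(i: int) -> str:
    return f"SYNG{i + 1:05d}"


@dataclass
class SynthOntology:
    """A generated ontology plus the generator's own ground truth."""

    obo_text: str
    table: CompartmentTable
    parents: dict[str, list[tuple[str, str]]]  # child -> [(parent, relation)]
    true_members: dict[str, frozenset[str]]  # compartment name -> closure (term ids)
    n_terms: int
    n_edges: int


def synth_ontology(config: SynthConfig) -> SynthOntology:
    """Random DAG ontology with designated compartment roots.

    The first ``n_compartments`` terms are parentless roots, one per
    compartment; every later term gets one or two parents drawn uniformly
    from earlier terms, which guarantees acyclicity.  Closures are recorded
    by the generator's own forward reachability over its edge list, kept
    deliberately separate from the library's graph traversal.
    """
    rng = np.random.default_rng(config.seed)
    n, roots = config.n_terms, config.n_compartments
    parents: dict[str, list[tuple[str, str]]] = {_term_id(i): [] for i in range(n)}
    for i in range(roots, n):
        n_parents = int(rng.integers(1, 3))
        choices = rng.choice(i, size=min(n_parents, i), replace=False)
        for j in sorted(int(c) for c in choices):
            relation = "is_a" if rng.random() < 0.7 else "part_of"
            parents[_term_id(i)].append((_term_id(j), relation))

    # ground-truth closures: children of each term via the generator's own lists
    children: dict[str, list[str]] = {t: [] for t in parents}
    for child, plist in parents.items():
        for parent, _ in plist:
            children[parent].append(child)
    true_members: dict[str, frozenset[str]] = {}
    entries = []
    for c in range(roots):
        root = _term_id(c)
        seen = {root}
        stack = [root]
        while stack:
            node = stack.pop()
            for child in children[node]:
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        name = f"Compartment {c + 1:02d}"
        entries.append(CompartmentEntry(name=name, go_id=root, views=frozenset({"standard"})))
        true_members[name] = frozenset(seen)

    stanzas = ["format-version: 1.2", "ontology: gocellmap-synthetic"]
    n_edges = 0
    for i in range(n):
        term = _term_id(i)
        lines = [
            "",
            "[Term]",
            f"id: {term}",
            f"name: synthetic term {i + 1}",
            "namespace: cellular_component",
        ]
        for parent, relation in parents[term]:
            n_edges += 1
            if relation == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: part_of {parent}")
        stanzas.extend(lines)
    return SynthOntology(
        obo_text="\n".join(stanzas) + "\n",
        table=CompartmentTable(tuple(entries)),
        parents=parents,
        true_members=true_members,
        n_terms=n,
        n_edges=n_edges,
    )


@dataclass
class SynthAnnotations:
    """Generated GAF text plus the true compartment gene sets."""

    gaf_text: str
    true_sets: CompartmentGeneSets
    n_records: int


def synth_annotations(ontology: SynthOntology, config: SynthConfig) -> SynthAnnotations:
    """Annotate each gene to Poisson-many uniformly chosen terms.

    Every gene receives at least one annotation, so the universe (all genes
    in the corpus) has full coverage; true compartment gene sets are derived
    from the generator's recorded closures, not from the library.
    """
    rng = np.random.default_rng(config.seed + 1)
    terms = [_term_id(i) for i in range(ontology.n_terms)]
    term_to_comps: dict[str, list[str]] = {t: [] for t in terms}
    for name, members in ontology.true_members.items():
        for t in members:
            term_to_comps[t].append(name)

    lines = ["!gaf-version: 2.2"]
    true_sets: dict[str, set[str]] = {e.name: set() for e in ontology.table}
    n_records = 0
    for g in range(config.n_genes):
        gene = _gene_id(g)
        m = max(1, int(rng.poisson(config.mean_annotations_per_gene)))
        m = min(m, len(terms))
        chosen = rng.choice(len(terms), size=m, replace=False)
        for t_idx in sorted(int(c) for c in chosen):
            term = terms[t_idx]
            n_records += 1
            lines.append(
                "\t".join(
                    [
                        "SYNDB",
                        f"ACC{g + 1:05d}",
                        gene,
                        "located_in",
                        term,
                        "SYN:0000001",
                        "IEA",
                        "",
                        "C",
                        f"synthetic gene {g + 1}",
                        "",
                        "protein",
                        "taxon:0000",
                        "20240101",
                        "SYNDB",
                        "",
                        "",
                    ]
                )
            )
            for comp in term_to_comps[term]:
                true_sets[comp].add(gene)
    universe = GeneUniverse(
        species="synthetic", genes=frozenset(_gene_id(g) for g in range(config.n_genes))
    )
    return SynthAnnotations(
        gaf_text="\n".join(lines) + "\n",
        true_sets=CompartmentGeneSets(
            universe=universe, sets={k: frozenset(v) for k, v in true_sets.items()}
        ),
        n_records=n_records,
    )


def synth_query(
    true_sets: CompartmentGeneSets, target_compartment: str, config: SynthConfig
) -> list[str]:
    """A query with a planted signal: ``signal_fraction`` of it sampled from
    the target compartment's gene set, the remainder uniformly from the rest
    of the universe, without duplicates."""
    rng = np.random.default_rng(config.seed + 2)
    target = sorted(true_sets.sets[target_compartment])
    if not target:
        raise ValueError(f"target compartment {target_compartment!r} has no genes")
    n_signal = round(config.signal_fraction * config.n_query)
    if n_signal > len(target):
        raise ValueError(
            f"target set has {len(target)} genes; cannot plant {n_signal} signal genes"
        )
    signal = [target[i] for i in rng.choice(len(target), size=n_signal, replace=False)]
    rest_pool = sorted(true_sets.universe.genes - set(signal))
    n_rest = config.n_query - n_signal
    if n_rest > len(rest_pool):
        raise ValueError("universe too small for the requested query size")
    rest = [rest_pool[i] for i in rng.choice(len(rest_pool), size=n_rest, replace=False)]
    return sorted(signal + rest)


def pick_target_compartment(true_sets: CompartmentGeneSets, fraction: float = 0.1) -> str:
    """The compartment whose true gene-set size is closest to ``fraction`` of
    the universe — the generator's notion of a typical mid-sized organelle."""
    goal = fraction * len(true_sets.universe)
    return min(true_sets.names, key=lambda name: (abs(len(true_sets.sets[name]) - goal), name))


def write_bundle(ontology: SynthOntology, annotations: SynthAnnotations, out_dir) -> dict[str, Path]:
    """Write the synthetic study to disk as real OBO/GAF/TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": out / "ontology.obo",
        "gaf": out / "annotations.gaf",
        "compartments": out / "compartments.tsv",
        "truth": out / "true_memberships.tsv",
    }
    paths["obo"].write_text(ontology.obo_text)
    paths["gaf"].write_text(annotations.gaf_text)
    ontology.table.to_tsv(paths["compartments"])
    lines = ["compartment\tgene"]
    for name in annotations.true_sets.names:
        for gene in sorted(annotations.true_sets.sets[name]):
            lines.append(f"{name}\t{gene}")
    paths["truth"].write_text("\n".join(lines) + "\n")
    return paths
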
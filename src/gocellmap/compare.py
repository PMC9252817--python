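"""Multi-compartment membership (UpSet counts) and multi-list comparison.

Genes are frequently annotated to several compartments at once (a lysosomal
membrane protein is also a cytoplasmic one); the membership matrix and its
exclusive intersection counts — the tabular form of an UpSet plot — make
that structure visible.  ``compare_lists`` runs the same enrichment on
several query lists against an identical effective universe so their FDR
profiles are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation import CompartmentGeneSets, IdMapping
from .enrichment import CleanQuery, CompartmentEnrichment, EnrichmentResults

__all__ = [
    "MembershipMatrix",
    "ComparisonGrid",
    "membership_matrix",
    "upset_counts",
    "compare_lists",
    "write_upset_counts",
]


@dataclass
class MembershipMatrix:
    """Boolean gene-by-compartment membership for a query.

    Rows cover the query genes with at least one compartment membership;
    genes in no compartment are tallied in ``n_unannotated`` rather than
    given all-False rows.
    """

    matrix: pd.DataFrame  # index: genes, columns: compartments, dtype bool
    n_unannotated: int

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def compartments(self) -> list[str]:
        return list(self.matrix.columns)


def membership_matrix(query: CleanQuery | frozenset[str] | set[str], gene_sets: CompartmentGeneSets) -> MembershipMatrix:
    genes = query.genes if isinstance(query, CleanQuery) else frozenset(query)
    names = gene_sets.names
    rows = {}
    unannotated = 0
    for gene in sorted(genes):
        flags = [gene in gene_sets.sets[name] for name in names]
        if any(flags):
            rows[gene] = flags
        else:
            unannotated += 1
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=names).astype(bool)
    return MembershipMatrix(matrix=matrix, n_unannotated=unannotated)


def upset_counts(matrix: MembershipMatrix) -> list[tuple[tuple[str, ...], int]]:
    """Exclusive intersection counts over membership signatures.

    Each gene contributes to exactly one combination — its full membership
    signature — so the counts sum to the number of genes with at least one
    membership.  Zero-count combinations are omitted.  Sorted by count
    descending, then by combination name for determinism.
    """
    names = matrix.compartments
    counts: dict[tuple[str, ...], int] = {}
    for _, row in matrix.matrix.iterrows():
        signature = tuple(name for name, flag in zip(names, row) if flag)
        if signature:
            counts[signature] = counts.get(signature, 0) + 1
    return sorted(counts.items(), key=lambda item: (-item[1], item[0]))


def write_upset_counts(counts: Sequence[tuple[tuple[str, ...], int]], path, n_unannotated: int = 0) -> None:
    lines = ["combination\tcount"]
    for combo, count in counts:
        lines.append(f"{'+'.join(combo)}\t{count}")
    if n_unannotated:
        lines.append(f"(unannotated)\t{n_unannotated}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ComparisonGrid:
    """Side-by-side enrichment of several named query lists.

    ``fdr`` is compartments x lists, aligned on the model's compartment
    order; ``results`` keeps each list's full fitted results.
    """

    list_names: list[str]
    results: dict[str, EnrichmentResults]
    fdr: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.fdr.to_csv(path, sep="\t", index_label="compartment")


def compare_lists(
    queries: Mapping[str, Sequence[str]],
    gene_sets: CompartmentGeneSets,
    background_ids: Sequence[str] | None = None,
    id_mapping: IdMapping | None = None,
) -> ComparisonGrid:
    """Enrich each named list independently against the identical universe."""
    if len(queries) < 2:
        raise ValueError("need at least two named query lists to compare")
    results: dict[str, EnrichmentResults] = {}
    for name, ids in queries.items():
        model = CompartmentEnrichment(
            ids, gene_sets, background_ids=background_ids, id_mapping=id_mapping
        )
        if not model.query.genes:
            raise ValueError(f"query list {name!r} is empty after cleaning")
        try:
            results[name] = model.fit()
        except ValueError as exc:
            raise ValueError(f"query list {name!r}: {exc}") from exc
    compartments = gene_sets.names
    fdr = pd.DataFrame(index=compartments, columns=list(queries), dtype=float)
    for name, res in results.items():
        indexed = res.table.set_index("compartment")["fdr"]
        fdr[name] = [indexed[c] for c in compartments]
    return ComparisonGrid(list_names=list(queries), results=results, fdr=fdr)
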
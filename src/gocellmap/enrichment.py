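"""Hypergeometric over-representation of compartments in a gene list.

The model: a query of n genes is treated as a draw without replacement from
a universe of N genes, of which K belong to a compartment's gene set.  The
observed overlap k is scored with the upper-tail hypergeometric probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

(the ``phyper(k-1, K, N-K, n, lower.tail=FALSE)`` convention), testing
over-representation only.  P-values are adjusted with the Benjamini-Hochberg
step-up across exactly the compartments tested.  When the user supplies a
background population of expressed genes, the universe is restricted to the
background and every K is recomputed inside it; query genes absent from the
background are dropped from n, keeping the sampling model coherent.

The user-facing surface is :class:`CompartmentEnrichment` (the model, built
from a raw identifier list plus compartment gene sets) whose ``fit()``
returns an :class:`EnrichmentResults` carrying the per-compartment table,
a text ``summary()``, plotting, and TSV export.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import (
    AnnotationRecord,
    CleaningReport,
    CompartmentGeneSets,
    GeneUniverse,
    IdMapping,
    canonicalize_ids,
)
from .ontology import CompartmentModel, OntologyGraph

__all__ = [
    "CleanQuery",
    "hypergeom_pvalue",
    "bh_fdr",
    "effective_universe",
    "enrich_compartments",
    "enrich_terms",
    "highest_enriched",
    "CompartmentEnrichment",
    "EnrichmentResults",
    "TABLE_COLUMNS",
    "read_table",
    "write_table",
]

#: Smallest p-value ever reported; hypergeometric survival probabilities
#: below double precision are floored here rather than reported as zero.
P_FLOOR = sys.float_info.min

TABLE_COLUMNS = ["compartment", "k", "K", "n", "N", "p_value", "fdr", "overlap_genes"]


@dataclass(frozen=True)
class CleanQuery:
    """A cleaned, canonicalized query gene set plus its provenance report."""

    genes: frozenset[str]
    report: CleaningReport = field(default_factory=CleaningReport)

    def __len__(self) -> int:
        return len(self.genes)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the compartment gene-set size, n the query
    size, k the observed overlap.  Computed through the survival function,
    which is numerically safe well beyond N ~ 1e5.
    """
    for label, value in (("k", k), ("K", K), ("n", n), ("N", N)):
        if value != int(value) or value < 0:
            raise ValueError(f"{label} must be a non-negative integer, got {value!r}")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return max(p, P_FLOOR)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def effective_universe(
    gene_sets: CompartmentGeneSets, background: frozenset[str] | set[str] | None = None
) -> tuple[frozenset[str], dict[str, int]]:
    """The universe actually sampled from, and each compartment's K inside it.

    With no background the universe is the full species universe; with a
    background it is the intersection of background and species universe,
    with every K recomputed inside it.
    """
    if background is None:
        universe = gene_sets.universe.genes
    else:
        outside = set(background) - gene_sets.universe.genes
        universe = frozenset(background) & gene_sets.universe.genes
        if not universe:
            raise ValueError("background shares no genes with the species universe")
        if outside:
            warnings.warn(
                f"{len(outside)} background genes are absent from the species universe",
                stacklevel=2,
            )
    k_values = {name: len(genes & universe) for name, genes in gene_sets.sets.items()}
    return frozenset(universe), k_values


def _query_in_universe(query: CleanQuery, universe: frozenset[str]) -> frozenset[str]:
    effective = query.genes & universe
    dropped = len(query.genes) - len(effective)
    if dropped:
        warnings.warn(
            f"{dropped} query genes are outside the effective universe and were dropped",
            stacklevel=3,
        )
    return effective


def enrich_compartments(
    query: CleanQuery,
    gene_sets: CompartmentGeneSets,
    background: frozenset[str] | set[str] | None = None,
) -> pd.DataFrame:
    """One hypergeometric test per compartment, BH-adjusted across them.

    Returns a table with one row per compartment: overlap ``k``, set size
    ``K``, query size ``n``, universe size ``N``, ``p_value``, ``fdr`` and
    the sorted ``overlap_genes``; rows ordered by (fdr, p_value, name).
    """
    universe, k_values = effective_universe(gene_sets, background)
    effective_query = _query_in_universe(query, universe)
    if not effective_query:
        raise ValueError(
            "query is empty after cleaning and background restriction; "
            "check identifier types, species, and background coverage"
        )
    n = len(effective_query)
    big_n = len(universe)
    rows = []
    for name in gene_sets.names:
        members = gene_sets.sets[name] & universe
        overlap = sorted(effective_query & members)
        k = len(overlap)
        p = hypergeom_pvalue(k, k_values[name], n, big_n)
        rows.append((name, k, k_values[name], n, big_n, p, overlap))
    table = pd.DataFrame(rows, columns=["compartment", "k", "K", "n", "N", "p_value", "overlap_genes"])
    table["fdr"] = bh_fdr(table["p_value"])
    table = table[TABLE_COLUMNS]
    table = table.sort_values(
        ["fdr", "p_value", "compartment"], kind="mergesort"
    ).reset_index(drop=True)
    table.attrs["effective_background"] = (
        f"species universe (N={big_n})"
        if background is None
        else f"user background ∩ species universe (N={big_n})"
    )
    return table


def enrich_terms(
    query: CleanQuery,
    graph: OntologyGraph,
    records: Sequence[AnnotationRecord],
    model: CompartmentModel,
    gene_sets: CompartmentGeneSets,
    background: frozenset[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Per-GO-term enrichment over every cellular_component term hit by the query.

    Each term's gene set is the union of annotations to the term and to all
    of its descendants (so a gene annotated to ``caveola`` also counts for
    ``plasma membrane``).  Only terms with at least one query gene are
    emitted; BH runs across the emitted rows, and each row lists the
    compartments the term belongs to.
    """
    universe, _ = effective_universe(gene_sets, background)
    effective_query = _query_in_universe(query, universe)
    if not effective_query:
        raise ValueError("query is empty after cleaning and background restriction")
    n = len(effective_query)
    big_n = len(universe)

    genome = gene_sets.universe
    direct: dict[str, set[str]] = {}
    for rec in records:
        if rec.aspect != "C" or rec.negated:
            continue
        gene = genome.canonical(rec.symbol)
        if gene in universe:
            direct.setdefault(rec.term_id, set()).add(gene)

    # roll annotations up the DAG: children before parents
    import networkx as nx

    closure_edges = [
        (c, p)
        for c, p, r in graph.graph.edges(keys=True)
        if r in model.relations
    ]
    dag = nx.DiGraph()
    dag.add_nodes_from(graph.terms)
    dag.add_edges_from(closure_edges)
    closure_genes: dict[str, set[str]] = {}
    for term in nx.topological_sort(dag):
        genes = set(direct.get(term, ()))
        for child, _ in dag.in_edges(term):
            genes |= closure_genes.get(child, set())
        closure_genes[term] = genes

    rows = []
    for term_id, genes in closure_genes.items():
        info = graph.terms[term_id]
        if info.namespace != "cellular_component" or info.obsolete:
            continue
        overlap = sorted(effective_query & genes)
        if not overlap:
            continue
        k_set = len(genes)
        p = hypergeom_pvalue(len(overlap), k_set, n, big_n)
        rows.append(
            (
                term_id,
                info.name,
                len(overlap),
                k_set,
                n,
                big_n,
                p,
                overlap,
                ";".join(model.compartments_of(term_id)),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["go_id", "term_name", "k", "K", "n", "N", "p_value", "overlap_genes", "compartments"],
    )
    if len(table):
        table["fdr"] = bh_fdr(table["p_value"])
        table = table[
            ["go_id", "term_name", "k", "K", "n", "N", "p_value", "fdr", "overlap_genes", "compartments"]
        ]
        table = table.sort_values(
            ["fdr", "p_value", "go_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["fdr"] = []
    return table


def highest_enriched(table: pd.DataFrame) -> str:
    """The top compartment: minimal fdr, ties broken by smaller p, larger k,
    then alphabetical name.  Returned regardless of significance."""
    if table.empty:
        raise ValueError("enrichment table is empty")
    ranked = table.sort_values(
        ["fdr", "p_value", "k", "compartment"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return str(ranked.iloc[0]["compartment"])


def write_table(table: pd.DataFrame, path) -> None:
    """Write an enrichment table as TSV; overlap genes are semicolon-joined."""
    out = table.copy()
    if "overlap_genes" in out.columns:
        out["overlap_genes"] = [";".join(genes) for genes in out["overlap_genes"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (lossless round-trip)."""
    table = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    if "overlap_genes" in table.columns:
        table["overlap_genes"] = [
            cell.split(";") if cell else [] for cell in table["overlap_genes"].astype(str)
        ]
    return table


class CompartmentEnrichment:
    """Over-representation model for one query list against compartment gene sets.

    Parameters
    ----------
    query_ids
        Raw user identifiers (gene symbols and/or accessions), one per entry.
        Duplicates and unknown identifiers are removed and reported.
    gene_sets
        Compartment gene sets and the species universe (from
        :func:`~gocellmap.annotation.build_gene_sets` or
        :func:`~gocellmap.annotation.load_custom_gene_sets`).
    background_ids
        Optional expressed-gene background; cleaned the same way.
    id_mapping
        Optional accession-to-symbol mapping used during cleaning.
    view
        Label recorded on the results so plots can check they match.
    """

    def __init__(
        self,
        query_ids: Sequence[str],
        gene_sets: CompartmentGeneSets,
        background_ids: Sequence[str] | None = None,
        id_mapping: IdMapping | None = None,
        view: str | None = None,
    ):
        self.gene_sets = gene_sets
        self.id_mapping = id_mapping
        self.view = view
        genes, report = canonicalize_ids(list(query_ids), gene_sets.universe, id_mapping)
        self.query = CleanQuery(genes=frozenset(genes), report=report)
        if background_ids is None:
            self.background: frozenset[str] | None = None
            self.background_report: CleaningReport | None = None
        else:
            bg, bg_report = canonicalize_ids(
                list(background_ids), gene_sets.universe, id_mapping
            )
            self.background = frozenset(bg)
            self.background_report = bg_report

    @classmethod
    def from_files(
        cls,
        query_path,
        gene_sets: CompartmentGeneSets,
        background_path=None,
        id_mapping: IdMapping | None = None,
        view: str | None = None,
    ) -> "CompartmentEnrichment":
        """Build the model from plain-text identifier lists (one per line)."""
        query_ids = _read_id_list(query_path)
        background_ids = _read_id_list(background_path) if background_path else None
        return cls(query_ids, gene_sets, background_ids, id_mapping, view)

    def fit(self) -> "EnrichmentResults":
        table = enrich_compartments(self.query, self.gene_sets, self.background)
        if self.view is not None:
            table.attrs["view"] = self.view
        return EnrichmentResults(model=self, table=table)


def _read_id_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


@dataclass
class EnrichmentResults:
    """Fitted compartment-enrichment results.

    ``table`` holds one row per compartment (k, K, n, N, p_value, fdr,
    overlap genes) sorted by significance; convenience accessors expose the
    top compartment and the significant subset.
    """

    model: CompartmentEnrichment
    table: pd.DataFrame

    @property
    def highest_enriched(self) -> str:
        return highest_enriched(self.table)

    def significant(self, threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < threshold].reset_index(drop=True)

    def summary(self, threshold: float = 0.05) -> str:
        """Human-readable account of the fit."""
        t = self.table
        lines = [
            "Compartment over-representation (hypergeometric, BH-FDR)",
            "=" * 58,
            f"query: {len(self.model.query)} genes after cleaning "
            f"({self.model.query.report.summary()})",
            f"universe: {t.attrs.get('effective_background', 'species universe')}",
            f"compartments tested: {len(t)}; significant at FDR<{threshold:g}: "
            f"{int((t['fdr'] < threshold).sum())}",
            "",
            f"{'compartment':<24}{'k':>5}{'K':>7}{'p-value':>12}{'FDR':>12}",
            "-" * 60,
        ]
        for _, row in t.iterrows():
            lines.append(
                f"{row['compartment']:<24}{row['k']:>5}{row['K']:>7}"
                f"{row['p_value']:>12.3g}{row['fdr']:>12.3g}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        write_table(self.table, path)

    def plot(self, view: str | None = None, style=None, template=None) -> bytes:
        """Render the results on the cell schematic; returns SVG bytes."""
        from .viz import load_schematic, render_schematic

        view = view or self.model.view or "standard"
        schematic = load_schematic(view=view, source=template)
        return render_schematic(self.table, schematic, style)
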
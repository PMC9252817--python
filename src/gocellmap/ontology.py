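"""Gene Ontology parsing and compartment definitions.

The Gene Ontology Cellular Component (GOCC) aspect is a directed acyclic
graph whose terms describe subcellular locations, from general descriptors
near the root (e.g. ``GO:0005886`` plasma membrane) down to very specific
ones (e.g. ``GO:0005901`` caveola).  Because annotation to a descendant term
implies localization within the ancestor compartment, the descendant closure
of a well-chosen high-level term collects every annotation relevant to one
major compartment.  This module parses OBO files, computes descendant
closures, and builds the compartment model: a small, named set of major
compartments, each defined as one parent GO term plus all of its
descendants over a configurable set of relation types.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "GoTerm",
    "OntologyGraph",
    "CompartmentEntry",
    "CompartmentTable",
    "CompartmentModel",
    "OboParseError",
    "DEFAULT_RELATIONS",
    "parse_obo",
    "descendants",
    "build_compartments",
    "default_compartment_table",
]

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

#: Relation types followed when collecting descendants.  ``is_a`` and
#: ``part_of`` together mirror the OFFSPRING semantics of the Bioconductor
#: GO.db tables; other relation types (e.g. regulates) are excluded by
#: default because they do not imply spatial containment.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

VALID_NAMESPACES = {"cellular_component", "biological_process", "molecular_function"}


class OboParseError(ValueError):
    """Raised when an OBO document cannot be parsed."""


@dataclass(frozen=True)
class GoTerm:
    """A single ontology term."""

    term_id: str
    name: str
    namespace: str
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.term_id):
            raise ValueError(f"not a GO accession: {self.term_id!r}")


class OntologyGraph:
    """The ontology DAG: terms plus typed child-to-parent relations.

    Edges point from child to parent, matching the direction OBO files
    state them (``is_a: <parent>``).  Obsolete terms are kept so they can
    be reported, but they carry no edges and are excluded from closures.
    """

    def __init__(self, terms: Iterable[GoTerm], edges: Iterable[tuple[str, str, str]]):
        self.terms: dict[str, GoTerm] = {t.term_id: t for t in terms}
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.terms)
        for child, parent, relation in edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise ValueError(f"edge endpoint {endpoint} not among terms")
            if self.terms[child].obsolete or self.terms[parent].obsolete:
                raise ValueError(f"obsolete term in edge {child} -> {parent}")
            g.add_edge(child, parent, key=relation)
        self.graph = g

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def name_of(self, term_id: str) -> str:
        return self.terms[term_id].name

    def descendants(
        self, term_id: str, relations: frozenset[str] | set[str] = DEFAULT_RELATIONS
    ) -> set[str]:
        """All terms whose annotations roll up to ``term_id``.

        Follows the chosen relation types from children upward; the result
        includes ``term_id`` itself and never includes obsolete terms.
        """
        if term_id not in self.terms:
            raise KeyError(f"unknown term: {term_id}")
        if self.terms[term_id].obsolete:
            raise LookupError(f"term {term_id} is obsolete and has no closure")
        relations = frozenset(relations)
        seen = {term_id}
        stack = [term_id]
        while stack:
            node = stack.pop()
            for child, _parent, relation in self.graph.in_edges(node, keys=True):
                if relation in relations and child not in seen:
                    seen.add(child)
                    stack.append(child)
        return seen


def descendants(
    graph: OntologyGraph, term_id: str, relations: frozenset[str] | set[str] = DEFAULT_RELATIONS
) -> set[str]:
    """Functional alias for :meth:`OntologyGraph.descendants`."""
    return graph.descendants(term_id, relations)


# a line is blank, a stanza header, or "tag: value" with a whitespace-free tag
_STANZA_LINE = re.compile(r"^(\[[^\]]+\]|[^\s:]+:\s*.*)?$")


def _read_text(source) -> str:
    """Accept a path (optionally .gz), bytes, or a file-like object."""
    if hasattr(source, "read"):
        data = source.read()
        return data.decode() if isinstance(data, bytes) else data
    path = Path(source)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return fh.read()
    return path.read_text()


def parse_obo(source) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 document into an :class:`OntologyGraph`.

    ``source`` may be a path (gzip accepted) or a file-like object.  All
    namespaces are retained; obsolete terms are flagged and edge-free.
    """
    text = _read_text(source)
    if not text.strip():
        raise OboParseError("empty OBO document")
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("!"):
            continue
        if not _STANZA_LINE.match(stripped):
            raise OboParseError(f"malformed OBO line {lineno}: {line!r}")
    try:
        multigraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - obonet error text varies
        raise OboParseError(f"OBO parse failed: {exc}") from exc
    if multigraph.number_of_nodes() == 0:
        raise OboParseError("OBO document contains no terms")

    terms = []
    edges: list[tuple[str, str, str]] = []
    for node, data in multigraph.nodes(data=True):
        if not GO_ID_PATTERN.match(node):
            continue  # typedef stubs or foreign accessions
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        terms.append(
            GoTerm(
                term_id=node,
                name=data.get("name", node),
                namespace=data.get("namespace", "cellular_component"),
                obsolete=obsolete,
            )
        )
    known = {t.term_id for t in terms}
    obsolete_ids = {t.term_id for t in terms if t.obsolete}
    for child, parent, relation in multigraph.edges(keys=True):
        if child in known and parent in known:
            if child in obsolete_ids or parent in obsolete_ids:
                continue
            edges.append((child, parent, relation))
    return OntologyGraph(terms, edges)


@dataclass(frozen=True)
class CompartmentEntry:
    name: str
    go_id: str
    views: frozenset[str] = frozenset({"standard"})

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.go_id):
            raise ValueError(f"not a GO accession: {self.go_id!r}")


@dataclass(frozen=True)
class CompartmentTable:
    """Ordered list of (compartment name, parent GO term, view memberships)."""

    entries: tuple[CompartmentEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("compartment table is empty")
        names = [e.name for e in self.entries]
        ids = [e.go_id for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compartment names")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate parent GO IDs")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def for_view(self, view: str) -> "CompartmentTable":
        kept = tuple(e for e in self.entries if view in e.views)
        if not kept:
            raise ValueError(f"no compartments belong to view {view!r}")
        return CompartmentTable(kept)

    @classmethod
    def from_tsv(cls, source) -> "CompartmentTable":
        text = _read_text(source)
        entries = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[:2] == ["name", "go_id"]:
                continue
            if len(fields) < 2:
                raise ValueError(f"compartment table line {lineno}: expected ≥2 columns")
            views = fields[2] if len(fields) > 2 and fields[2] else "standard"
            entries.append(
                CompartmentEntry(
                    name=fields[0],
                    go_id=fields[1],
                    views=frozenset(v for v in views.split(";") if v),
                )
            )
        return cls(tuple(entries))

    def to_tsv(self, path) -> None:
        lines = ["name\tgo_id\tviews"]
        for e in self.entries:
            lines.append(f"{e.name}\t{e.go_id}\t{';'.join(sorted(e.views))}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class CompartmentModel:
    """Major compartments as descendant-term closures.

    ``compartments`` maps each compartment name to the parent term plus all
    of its descendants; member sets may legitimately overlap (e.g. lysosome
    terms are also cytoplasm terms in the real ontology).
    """

    compartments: dict[str, frozenset[str]]
    source_table: CompartmentTable
    relations: frozenset[str] = DEFAULT_RELATIONS
    term_to_compartments: dict[str, tuple[str, ...]] = field(init=False)

    def __post_init__(self) -> None:
        index: dict[str, list[str]] = {}
        for name in self.source_table.names:
            for term in self.compartments[name]:
                index.setdefault(term, []).append(name)
        self.term_to_compartments = {t: tuple(v) for t, v in index.items()}

    @property
    def names(self) -> list[str]:
        return self.source_table.names

    def child_term_counts(self) -> dict[str, int]:
        """Number of child terms per compartment (member set minus the parent)."""
        return {name: len(members) - 1 for name, members in self.compartments.items()}

    def compartments_of(self, term_id: str) -> tuple[str, ...]:
        return self.term_to_compartments.get(term_id, ())


def build_compartments(
    graph: OntologyGraph,
    table: CompartmentTable,
    relations: frozenset[str] | set[str] = DEFAULT_RELATIONS,
) -> CompartmentModel:
    """Materialize each table entry's member set via descendant closure."""
    compartments: dict[str, frozenset[str]] = {}
    for entry in table:
        if entry.go_id not in graph:
            raise KeyError(f"compartment parent term {entry.go_id} ({entry.name}) not in ontology")
        term = graph.terms[entry.go_id]
        if term.namespace != "cellular_component":
            raise ValueError(
                f"compartment parent {entry.go_id} ({entry.name}) is in namespace "
                f"{term.namespace}, not cellular_component"
            )
        compartments[entry.name] = frozenset(graph.descendants(entry.go_id, relations))
    return CompartmentModel(compartments=compartments, source_table=table, relations=frozenset(relations))


def default_compartment_table(view: str = "standard") -> CompartmentTable:
    """The shipped compartment definitions for a view.

    ``standard`` holds the 14 major eukaryotic compartments (cytoplasm,
    nucleus, plasma membrane, ...); ``endosomal`` is the trafficking-focused
    alternative (early/late/recycling endosome, lysosome, Golgi, vesicles,
    plasma membrane).  Both live in a plain TSV under ``gocellmap/data`` so
    they can be copied and edited for other species or ontology releases.
    """
    text = resources.files("gocellmap.data").joinpath("compartments.tsv").read_text()
    table = CompartmentTable.from_tsv(io.StringIO(text))
    views = set().union(*(e.views for e in table))
    if view not in views:
        raise ValueError(f"unknown view {view!r}; available: {sorted(views)}")
    return table.for_view(view)
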
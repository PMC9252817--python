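"""Gene-to-GO annotations, identifier cleaning, and compartment gene sets.

Annotations arrive as GAF 2.x files linking gene products to GO terms.
Downstream only Cellular Component (aspect ``C``) records matter, and
records carrying a ``NOT`` qualifier are evidence *against* a localization,
so they are excluded from gene sets.  The gene universe — the population the
hypergeometric test samples from — defaults to every gene present in the
annotation source, whether or not it carries a CC annotation.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.UniProt import GOA

from .ontology import CompartmentModel

__all__ = [
    "AnnotationRecord",
    "GeneUniverse",
    "CompartmentGeneSets",
    "IdMapping",
    "CleaningReport",
    "GafParseError",
    "parse_gaf",
    "universe_from_records",
    "build_gene_sets",
    "load_custom_gene_sets",
    "export_gene_sets",
    "canonicalize_ids",
]

#: Species whose gene symbols are case-insensitive by convention (human and
#: rat symbols are upper case; mouse, fly and yeast symbols are case-meaningful).
CASE_INSENSITIVE_SPECIES = {"H. sapiens", "R. rattus"}

GAF_COLUMNS = 17


class GafParseError(ValueError):
    """Raised when a GAF document is malformed."""


@dataclass(frozen=True)
class AnnotationRecord:
    object_id: str
    symbol: str
    term_id: str
    qualifiers: tuple[str, ...]
    evidence_code: str
    aspect: str

    @property
    def negated(self) -> bool:
        return "NOT" in self.qualifiers


@dataclass(frozen=True)
class GeneUniverse:
    """The samplable gene population for one species."""

    species: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene universe is empty")

    @property
    def case_insensitive(self) -> bool:
        return self.species in CASE_INSENSITIVE_SPECIES

    def canonical(self, raw: str) -> str:
        raw = raw.strip()
        return raw.upper() if self.case_insensitive else raw

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class CompartmentGeneSets:
    """Per-compartment gene sets plus the universe they live in."""

    universe: GeneUniverse
    sets: dict[str, frozenset[str]]
    n_outside_universe: int = 0

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            extra = genes - self.universe.genes
            if extra:
                raise ValueError(
                    f"compartment {name!r} contains {len(extra)} genes outside the universe"
                )

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.sets.items()}


def _read_text(source) -> str:
    if hasattr(source, "read"):
        data = source.read()
        return data.decode() if isinstance(data, bytes) else data
    path = Path(source)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return fh.read()
    return path.read_text()


def parse_gaf(source) -> list[AnnotationRecord]:
    """Parse a GAF 2.0/2.1/2.2 document.

    Comment lines start with ``!``; every data line must have exactly 17
    tab-separated columns.  Aspect comes from column 9 and qualifiers
    (including ``NOT``) from column 4.
    """
    text = _read_text(source)
    data_lines = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        n = len(line.split("\t"))
        if n != GAF_COLUMNS:
            raise GafParseError(f"GAF line {lineno}: expected {GAF_COLUMNS} columns, found {n}")
        data_lines += 1
    if data_lines == 0:
        return []
    records = []
    for raw in GOA.gafiterator(io.StringIO(text)):
        qualifiers = tuple(q for q in raw["Qualifier"] if q)
        records.append(
            AnnotationRecord(
                object_id=raw["DB_Object_ID"],
                symbol=raw["DB_Object_Symbol"],
                term_id=raw["GO_ID"],
                qualifiers=qualifiers,
                evidence_code=raw["Evidence"],
                aspect=raw["Aspect"],
            )
        )
    return records


def universe_from_records(
    records: Sequence[AnnotationRecord], species: str = "synthetic"
) -> GeneUniverse:
    """All genes present in the annotation source, CC-annotated or not."""
    probe = GeneUniverse(species=species, genes=frozenset({"_"}))
    genes = frozenset(probe.canonical(r.symbol) for r in records)
    return GeneUniverse(species=species, genes=genes)


def build_gene_sets(
    records: Sequence[AnnotationRecord],
    model: CompartmentModel,
    universe: GeneUniverse,
    exclude_evidence: Iterable[str] = (),
) -> CompartmentGeneSets:
    """Collect, per compartment, every universe gene with a usable annotation
    to any term in the compartment's member set.

    Usable means aspect ``C``, not ``NOT``-qualified, and (optionally) not
    carrying an excluded evidence code.  Genes outside the universe are
    skipped and counted.
    """
    if not model.compartments:
        raise ValueError("compartment model is empty")
    exclude_evidence = set(exclude_evidence)
    sets: dict[str, set[str]] = {name: set() for name in model.names}
    outside: set[str] = set()
    for rec in records:
        if rec.aspect != "C" or rec.negated:
            continue
        if rec.evidence_code in exclude_evidence:
            continue
        gene = universe.canonical(rec.symbol)
        if gene not in universe:
            outside.add(gene)
            continue
        for name in model.compartments_of(rec.term_id):
            sets[name].add(gene)
    if outside:
        warnings.warn(
            f"{len(outside)} annotated genes were outside the universe and ignored",
            stacklevel=2,
        )
    return CompartmentGeneSets(
        universe=universe,
        sets={name: frozenset(genes) for name, genes in sets.items()},
        n_outside_universe=len(outside),
    )


def load_custom_gene_sets(source, universe: GeneUniverse | None = None) -> CompartmentGeneSets:
    """Build gene sets directly from a two-column TSV (compartment, gene).

    Bypasses the ontology entirely — the route for user-curated resources
    such as localization predictions.  If no universe is supplied it
    defaults to the union of all listed genes.
    """
    text = _read_text(source)
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValueError(f"gene-set TSV line {lineno}: expected 2 columns, found {len(fields)}")
        if fields == ["compartment", "gene"]:
            continue
        pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValueError("gene-set TSV contains no data rows")
    sets: dict[str, set[str]] = {}
    for compartment, gene in pairs:
        sets.setdefault(compartment, set()).add(gene)
    if universe is None:
        universe = GeneUniverse(
            species="synthetic", genes=frozenset(g for s in sets.values() for g in s)
        )
    return CompartmentGeneSets(
        universe=universe, sets={k: frozenset(v) for k, v in sets.items()}
    )


def export_gene_sets(gene_sets: CompartmentGeneSets, path) -> None:
    """Write gene sets as a (compartment, gene) TSV, deterministically ordered."""
    lines = ["compartment\tgene"]
    for compartment in gene_sets.names:
        for gene in sorted(gene_sets.sets[compartment]):
            lines.append(f"{compartment}\t{gene}")
    Path(path).write_text("\n".join(lines) + "\n")


class IdMapping:
    """Many-to-many UniProt accession <-> gene symbol mapping."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self._acc_to_sym: dict[str, set[str]] = {}
        self._sym_to_acc: dict[str, set[str]] = {}
        for accession, symbol in pairs:
            self._acc_to_sym.setdefault(accession, set()).add(symbol)
            self._sym_to_acc.setdefault(symbol, set()).add(accession)

    @classmethod
    def from_tsv(cls, source) -> "IdMapping":
        """Read the UniProt ``idmapping`` dialect (accession, ID-type, value),
        keeping ``Gene_Name`` rows, or a plain two-column (accession, symbol) file."""
        text = _read_text(source)
        pairs = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 3:
                accession, id_type, value = fields
                if id_type == "Gene_Name":
                    pairs.append((accession, value))
            elif len(fields) == 2:
                pairs.append((fields[0], fields[1]))
            else:
                raise ValueError(f"ID-mapping line {lineno}: expected 2 or 3 columns")
        return cls(pairs)

    def symbols_for(self, accession: str) -> frozenset[str]:
        return frozenset(self._acc_to_sym.get(accession, ()))

    def accessions_for(self, symbol: str) -> frozenset[str]:
        return frozenset(self._sym_to_acc.get(symbol, ()))

    def __len__(self) -> int:
        return sum(len(v) for v in self._acc_to_sym.values())


@dataclass
class CleaningReport:
    """Where each dropped input identifier went, by reason."""

    kept: list[str] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)
    invalid: list[str] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.duplicates) + len(self.invalid) + len(self.unmapped)

    def summary(self) -> str:
        return (
            f"kept {len(self.kept)}; dropped {self.n_dropped} "
            f"({len(self.duplicates)} duplicate, {len(self.invalid)} invalid, "
            f"{len(self.unmapped)} unmapped)"
        )


def canonicalize_ids(
    raw_ids: Sequence[str],
    universe: GeneUniverse,
    mapping: IdMapping | None = None,
) -> tuple[set[str], CleaningReport]:
    """Clean a user list into canonical universe genes.

    Symbols are matched against the universe (case-folded for species with
    case-insensitive nomenclature); anything not matching directly is looked
    up in the accession mapping.  Nothing is silently dropped: every removed
    input is reported as duplicate, invalid (unknown to universe and
    mapping), or unmapped (known accession whose symbols are all outside the
    universe).  Deterministic for a fixed input order.
    """
    report = CleaningReport()
    kept: set[str] = set()
    for raw in raw_ids:
        token = raw.strip()
        if not token:
            continue
        canonical = universe.canonical(token)
        if canonical in universe:
            targets = {canonical}
        elif mapping is not None:
            symbols = mapping.symbols_for(token)
            targets = {universe.canonical(s) for s in symbols} & universe.genes
            if not targets:
                (report.unmapped if symbols else report.invalid).append(token)
                continue
        else:
            report.invalid.append(token)
            continue
        new = targets - kept
        if not new:
            report.duplicates.append(token)
        else:
            kept.update(new)
            report.kept.append(token)
            if targets - new:
                report.duplicates.append(token)
    return kept, report
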
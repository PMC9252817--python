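#!/usr/bin/env python
"""Validate compartment enrichment against a real GO release (needs downloads).

Given a GO ontology (go-basic.obo) and a species GAF — e.g. from
https://geneontology.org/docs/download-ontology/ and
https://current.geneontology.org/products/pages/downloads.html — this script
runs the full pipeline on one or more user gene lists and reports, per list,
the highest-enriched compartment and whether the expected compartments (if
given) occupy the top ranks.  Two classic checks:

  * a list of GPI-anchored proteins should put "Plasma membrane" and
    "Extracellular region" at ranks 1-2;
  * organelle-specific lists from localization atlases or proximity-labelling
    maps should rank their home compartment first.

Example:
    python scripts/validate_go_release.py \
        --obo go-basic.obo --gaf goa_human.gaf.gz \
        --query gpi_anchored.txt --expect "Plasma membrane" \
        --expect "Extracellular region" --out-dir results/gpi
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

from gocellmap.annotation import (
    IdMapping,
    build_gene_sets,
    parse_gaf,
    universe_from_records,
)
from gocellmap.enrichment import CompartmentEnrichment
from gocellmap.ontology import build_compartments, default_compartment_table, parse_obo
from gocellmap.viz import StyleOptions, export_results, load_schematic, render_schematic


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--obo", required=True)
    parser.add_argument("--gaf", required=True)
    parser.add_argument("--query", required=True, help="gene list, one identifier per line")
    parser.add_argument("--idmap", default=None)
    parser.add_argument("--background", default=None)
    parser.add_argument("--species", default="H. sapiens")
    parser.add_argument("--view", default="standard", choices=["standard", "endosomal"])
    parser.add_argument(
        "--expect", action="append", default=[],
        help="compartment expected among the top ranks (repeatable; order = rank)",
    )
    parser.add_argument("--out-dir", default=None)
    args = parser.parse_args()

    print("parsing ontology ...", file=sys.stderr)
    graph = parse_obo(args.obo)
    model = build_compartments(graph, default_compartment_table(args.view))
    print("parsing annotations ...", file=sys.stderr)
    records = parse_gaf(args.gaf)
    universe = universe_from_records(records, species=args.species)
    gene_sets = build_gene_sets(records, model, universe)
    print(
        "compartment sizes: "
        + ", ".join(f"{k}={v}" for k, v in sorted(gene_sets.sizes().items())),
        file=sys.stderr,
    )

    mapping = IdMapping.from_tsv(args.idmap) if args.idmap else None
    results = CompartmentEnrichment.from_files(
        args.query, gene_sets, background_path=args.background, id_mapping=mapping,
        view=args.view,
    ).fit()
    print(results.summary())

    if args.out_dir:
        svg = render_schematic(results.table, load_schematic(args.view), StyleOptions())
        export_results(results.table, svg, args.out_dir)

    if args.expect:
        top = list(results.table["compartment"].head(len(args.expect)))
        ok = set(top) == set(args.expect)
        print(f"\nexpected top compartments: {args.expect}\nobserved top ranks:        {top}")
        print("concordant" if ok else "NOT concordant")
        return 0 if ok else 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
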
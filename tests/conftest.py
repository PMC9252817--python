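import io

import pytest

from gocellmap import simulate
from gocellmap.annotation import build_gene_sets, parse_gaf, universe_from_records
from gocellmap.ontology import build_compartments, parse_obo


@pytest.fixture(scope="session")
def synth_config():
    return simulate.SynthConfig(seed=42)


@pytest.fixture(scope="session")
def synth_ontology(synth_config):
    return simulate.synth_ontology(synth_config)


@pytest.fixture(scope="session")
def synth_annotations(synth_ontology, synth_config):
    return simulate.synth_annotations(synth_ontology, synth_config)


@pytest.fixture(scope="session")
def graph(synth_ontology):
    return parse_obo(io.StringIO(synth_ontology.obo_text))


@pytest.fixture(scope="session")
def model(graph, synth_ontology):
    return build_compartments(graph, synth_ontology.table)


@pytest.fixture(scope="session")
def records(synth_annotations):
    return parse_gaf(io.StringIO(synth_annotations.gaf_text))


@pytest.fixture(scope="session")
def gene_sets(records, model):
    universe = universe_from_records(records)
    return build_gene_sets(records, model, universe)


@pytest.fixture(scope="session")
def target_compartment(synth_annotations):
    return simulate.pick_target_compartment(synth_annotations.true_sets)


@pytest.fixture(scope="session")
def planted_query(synth_annotations, target_compartment, synth_config):
    return simulate.synth_query(synth_annotations.true_sets, target_compartment, synth_config)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, synth_ontology, synth_annotations, synth_config):
    """Synthetic study written to disk as real OBO/GAF/TSV/query files."""
    out = tmp_path_factory.mktemp("bundle")
    paths = simulate.write_bundle(synth_ontology, synth_annotations, out)
    target = simulate.pick_target_compartment(synth_annotations.true_sets)
    query = simulate.synth_query(synth_annotations.true_sets, target, synth_config)
    query_path = out / "query.txt"
    query_path.write_text("\n".join(query) + "\n")
    paths["query"] = query_path
    paths["target"] = target
    return paths
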
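import pandas as pd
import pytest

from rnacensus import taxonomy
from rnacensus.simulate import SimulationParams, simulate


@pytest.fixture(scope="session")
def toy_nodes_tsv(tmp_path_factory):
    """6-node taxonomy: root; Bacteria > Proteobacteria > E. coli;
    Archaea > Euryarchaeota."""
    path = tmp_path_factory.mktemp("tax") / "nodes.tsv"
    rows = [
        (1, 1, "no rank", "root"),
        (2, 1, "superkingdom", "Bacteria"),
        (3, 2, "phylum", "Proteobacteria"),
        (4, 3, "species", "Escherichia coli"),
        (5, 1, "superkingdom", "Archaea"),
        (6, 5, "phylum", "Euryarchaeota"),
    ]
    pd.DataFrame(rows, columns=["taxon_id", "parent_id", "rank", "name"]).to_csv(
        path, sep="\t", index=False
    )
    return path


@pytest.fixture(scope="session")
def toy_index(toy_nodes_tsv):
    return taxonomy.load_taxonomy(toy_nodes_tsv)


@pytest.fixture(scope="session")
def euk_nodes_tsv(tmp_path_factory):
    """8-node eukaryote taxonomy with one supergroup-tagged phylum."""
    path = tmp_path_factory.mktemp("tax") / "euk_nodes.tsv"
    rows = [
        (1, 1, "no rank", "root"),
        (2, 1, "superkingdom", "Eukaryota"),
        (3, 2, "kingdom", "Fungi"),
        (4, 3, "phylum", "Ascomycota"),
        (5, 4, "species", "Saccharomyces cerevisiae"),
        (6, 2, "kingdom", "Viridiplantae"),
        (7, 6, "phylum", "Streptophyta"),
        (8, 7, "species", "Arabidopsis thaliana"),
    ]
    pd.DataFrame(rows, columns=["taxon_id", "parent_id", "rank", "name"]).to_csv(
        path, sep="\t", index=False
    )
    return path


@pytest.fixture(scope="session")
def euk_index(euk_nodes_tsv):
    config = {
        "domains": {"Eukaryota": "Eukaryota"},
        "merges": [],
        "supergroups": {"Fungi": "Opisthokonta", "Streptophyta": "Archaeplastida"},
    }
    return taxonomy.load_taxonomy(euk_nodes_tsv, config=config)


@pytest.fixture(scope="session")
def sim_default():
    """One default-parameter simulated dataset shared across tests."""
    return simulate(SimulationParams(seed=11))


@pytest.fixture(scope="session")
def sim_dir(sim_default, tmp_path_factory):
    out = tmp_path_factory.mktemp("simdata")
    paths = sim_default.write(out)
    return paths
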
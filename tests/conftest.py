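import json
import os

import pytest

from omicview.sc.dataset import load_cell_dataset
from omicview.simulate import (
    SyntheticGenomeSpec,
    SyntheticSCSpec,
    load_assembly,
    make_assembly,
    simulate_genome,
    simulate_sc,
)

GENOME_SEED = 11
SC_SEED = 13


@pytest.fixture(scope="session")
def genome_spec():
    return SyntheticGenomeSpec(seed=GENOME_SEED)


@pytest.fixture(scope="session")
def genome_dir(tmp_path_factory, genome_spec):
    d = tmp_path_factory.mktemp("genome")
    simulate_genome(genome_spec, str(d))
    return str(d)


@pytest.fixture(scope="session")
def genome_manifest(genome_dir):
    with open(os.path.join(genome_dir, "manifest.json")) as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def assembly(genome_dir):
    return load_assembly(os.path.join(genome_dir, "assembly.json"))


@pytest.fixture(scope="session")
def sc_spec():
    return SyntheticSCSpec(seed=SC_SEED)


@pytest.fixture(scope="session")
def sc_dir(tmp_path_factory, sc_spec, genome_spec):
    d = tmp_path_factory.mktemp("sc")
    simulate_sc(sc_spec, str(d), make_assembly(genome_spec))
    return str(d)


@pytest.fixture(scope="session")
def sc_manifest(sc_dir):
    with open(os.path.join(sc_dir, "manifest.json")) as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def rna_dataset(sc_dir):
    return load_cell_dataset(os.path.join(sc_dir, "rna.h5ad"))


@pytest.fixture(scope="session")
def multi_dataset(sc_dir):
    return load_cell_dataset(os.path.join(sc_dir, "multi.h5mu"))
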
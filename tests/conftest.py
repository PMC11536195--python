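import pytest

from malphot.dataset_io import SolventRegistry
from malphot.synthetic import GeneratorConfig, GroundTruthModel, generate_dataset

#: structurally varied SMILES for fingerprint property tests
PROPERTY_MOLECULES = [
    "C", "CC", "CCO", "c1ccccc1", "c1ccncc1", "CC(=O)O", "CC(=O)NC",
    "C1CCCCC1", "C1CCOC1", "CSC", "CC#N", "C=CC=C", "OCC(O)CO",
    "c1ccc2ccccc2c1", "CC(C)(C)N", "FC(F)(F)c1ccccc1", "O=C1C=CC(=O)N1C",
    "O=C1NC(=O)C=C1NCC", "O=C1N(C)C(=O)C(SC)=C1SC",
    "O=C1N(CC)C(=O)C(SC)=C1NC2CCCCC2",
    "O=C1NC(=O)C=C1OC", "N#Cc1ccccc1O", "CCCCCCCC", "CN1CCCC1",
]


@pytest.fixture(scope="session")
def registry():
    return SolventRegistry.default()


@pytest.fixture(scope="session")
def small_synthetic():
    """Small seeded synthetic dataset shared across tests."""
    cfg = GeneratorConfig(n_molecules=24, seed=7)
    records, truth = generate_dataset(cfg)
    return cfg, GroundTruthModel(), records, truth
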
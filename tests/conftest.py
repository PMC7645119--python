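import numpy as np
import pytest

from cellumine.descriptors import DescriptorConfig
from cellumine.ensemble import EnsembleConfig, PipelineConfig
from cellumine.seqio import PROTEIN_ALPHABET, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_protein(rng):
    def make(length: int, seed: int | None = None) -> str:
        r = np.random.default_rng(seed) if seed is not None else rng
        return "".join(r.choice(list(PROTEIN_ALPHABET), size=length))

    return make


@pytest.fixture
def fast_pipeline():
    """Small descriptor set and small models so unit tests stay quick."""
    return PipelineConfig(
        descriptor=DescriptorConfig(blocks=("aac", "gaac", "atom_bond")),
        k="auto",
        smote_k=3,
        ensemble=EnsembleConfig(
            mlp_hidden=(16, 16), mlp_max_iter=300, rf_trees=30
        ),
    )


@pytest.fixture
def protein_records(random_protein):
    return [ProteinRecord(f"p{i}", random_protein(40, seed=100 + i)) for i in range(6)]
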
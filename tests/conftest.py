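import numpy as np
import pytest

from dynrbp.dataset import FixedSample, TranscriptSet
from dynrbp.encoder import EncoderConfig, TransformerEncoder
from dynrbp.model import BindingModel, BindingPredictor, ModelConfig
from dynrbp.synth import SynthConfig, plant_motif_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-motif dataset shared across tests."""
    samples, truth = plant_motif_dataset(SynthConfig(seed=3, n_pos=30, n_neg=30))
    return samples, truth


@pytest.fixture(scope="session")
def small_predictor():
    enc = TransformerEncoder(EncoderConfig.small(), seed=11)
    model = BindingModel(ModelConfig.small(), seed=12)
    return BindingPredictor(enc, model, k=3)


@pytest.fixture
def transcripts(rng):
    bases = np.array(list("ACGU"))
    recs = [(f"tx{i}", "".join(bases[rng.integers(0, 4, size=400)]))
            for i in range(5)]
    return TranscriptSet(recs)


def make_sample(seq=None, label=1, structure=None, seed=0):
    if seq is None:
        bases = np.array(list("ACGU"))
        seq = "".join(bases[np.random.default_rng(seed).integers(0, 4, 101)])
    return FixedSample(sequence=seq, label=label, structure=structure)
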
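"""Shared fixtures.

The desk-scale end-to-end fixtures (synthetic dataset, pretrained and
random-init models) are session-scoped because pretraining the NumPy
backprop stack is the dominant cost of the suite; every test that needs
them shares one run.  Sizes are scaled down relative to a full study
(160 records, input length 512, 12 epochs) purely to fit a CPU-only test
budget; the win-count statistics over paired seeds are unchanged.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiocl.model import AnatomyModel, ModelConfig
from cardiocl.preprocess import preprocess_record
from cardiocl.pretrain import PretrainConfig, pretrain
from cardiocl.synthetic import BeatMorphology, SynthConfig, generate_dataset

# ---- the desk-scale "stated world" ---------------------------------------

E2E_INPUT_LEN = 512
E2E_SYNTH = SynthConfig(n_subjects=40, records_per_subject=10, n_classes=4,
                        seed=918)
E2E_PRETRAIN = PretrainConfig(
    epochs=20, batch_size=8, learning_rate=1e-3,
    model=ModelConfig(input_len=E2E_INPUT_LEN, seed=0), seed=0)


@pytest.fixture(scope="session")
def synth_dataset():
    """(records, manifest) of the 4-class, 40-subject synthetic task."""
    return generate_dataset(E2E_SYNTH)


@pytest.fixture(scope="session")
def preprocessed(synth_dataset):
    records, manifest = synth_dataset
    prep = [preprocess_record(r, 10.0, E2E_INPUT_LEN) for r in records]
    return prep, manifest


@pytest.fixture(scope="session")
def pretrained(preprocessed):
    """(model, trace) of the tiny-profile contrastive pretraining run."""
    prep, _ = preprocessed
    return pretrain(prep, E2E_PRETRAIN)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_morphology():
    return BeatMorphology()
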
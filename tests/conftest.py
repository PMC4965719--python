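import numpy as np
import pytest

from eegwords.records import EEGRecord
from eegwords.sae import SAEConfig, SAEModel, _init_layer, train_sae
from eegwords.segmentation import label_pool, normalize_pool, segment_record
from eegwords.simulate import SimConfig, simulate_record


def random_sae(seed: int, input_dim: int, hidden_dims: list[int],
               rho: float = 0.05, beta: float = 3.0) -> SAEModel:
    """A randomly initialized (untrained) autoencoder for oracle tests."""
    rng = np.random.default_rng(seed)
    dims = [input_dim] + list(hidden_dims)
    enc = [_init_layer(rng, dims[i + 1], dims[i]) for i in range(len(hidden_dims))]
    dec = [_init_layer(rng, dims[i - 1], dims[i]) for i in range(len(hidden_dims), 0, -1)]
    cfg = SAEConfig(input_dim=input_dim, hidden_dims=list(hidden_dims), rho=rho, beta=beta)
    return SAEModel(encoder=enc, decoder=dec, config=cfg)


@pytest.fixture(scope="session")
def small_record() -> EEGRecord:
    """One minute of 3-channel synthetic EEG at 64 Hz with one seizure."""
    return simulate_record(
        SimConfig(fs=64.0, n_channels=3, duration_s=60.0, n_seizures=1,
                  seizure_len_range_s=(10.0, 20.0), seed=7, subject_id="fix01")
    )


@pytest.fixture(scope="session")
def labeled_pool(small_record):
    pool = segment_record(small_record, window_s=3.0, step_s=1.0)
    label_pool(pool, {small_record.subject_id: small_record.annotations})
    return normalize_pool(pool)


@pytest.fixture(scope="session")
def trained_sae(labeled_pool):
    """A small stacked autoencoder trained briefly on the fixture pool."""
    cfg = SAEConfig(input_dim=192, hidden_dims=[12, 8], epochs=3,
                    learning_rate=0.3, batch_size=16, seed=11)
    model, stats = train_sae(labeled_pool, cfg)
    return model, stats
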
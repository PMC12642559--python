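import pytest

from specmol import parse_molecule
from specmol.config import EncoderConfig, SynthConfig, TrainConfig
from specmol.synthetic import generate_dataset
from specmol.trainer import prepare_split


@pytest.fixture(scope="session")
def glucose():
    return parse_molecule("OCC1OC(O)C(O)C(O)C1O", "glucose")


@pytest.fixture(scope="session")
def tiny_encoder_config():
    return EncoderConfig(embed_dim=16, gcn_hidden=16, mlp_hidden=16, dropout=0.0)


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded 16-molecule noise-free dataset shared across tests."""
    return generate_dataset(SynthConfig(n_molecules=16, seed=5, mz_error_ppm=0.0))


@pytest.fixture(scope="session")
def small_prep(small_dataset):
    ds = small_dataset
    spectra = {}
    for split in (ds.train, ds.val, ds.test):
        spectra.update(split.spectra)
    return prepare_split(ds.library, spectra)


@pytest.fixture(scope="session")
def small_train_config(tiny_encoder_config):
    return TrainConfig(
        epochs=5, batch_size=8, learning_rate=1e-3, seed=7,
        encoder=tiny_encoder_config,
    )
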
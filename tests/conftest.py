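import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from shiftbind import synthetic_data, structure_ensemble


@pytest.fixture(scope="session")
def toy_ensemble_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("ens") / "toy.pdb"
    synthetic_data.make_toy_ensemble(path, seed=1, n_models=3, perturbation_sd=0.05)
    return path


@pytest.fixture(scope="session")
def toy_ensemble(toy_ensemble_path):
    return structure_ensemble.read_pdb_ensemble(toy_ensemble_path)


@pytest.fixture(scope="session")
def default_series():
    return synthetic_data.make_titration_series()
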
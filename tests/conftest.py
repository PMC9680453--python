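import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from saxlevel.curation import curate_dataset, load_label_store
from saxlevel.phantoms import PhantomConfig, generate_dataset

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PLAN3 = {
    "subj000": "duplicate-identifier",
    "subj001": "inconsistent-phase-slice-count",
    "subj002": "non-contiguous-indices",
}


@pytest.fixture(scope="session")
def phantom_root(tmp_path_factory):
    """20-subject phantom dataset with one planted violation of each kind."""
    root = tmp_path_factory.mktemp("phantom20")
    config = PhantomConfig(n_subjects=20, seed=42)
    manifest = generate_dataset(config, root, PLAN3)
    return root, manifest


@pytest.fixture(scope="session")
def curated(phantom_root):
    root, manifest = phantom_root
    return curate_dataset(root), load_label_store(root / "labels.json"), manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
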
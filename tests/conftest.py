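import numpy as np
import pytest

import rebrain as rb


@pytest.fixture(scope="session")
def noiseless_train():
    """Single-descriptor noiseless line y = 2x + 1 on x = 0..9."""
    X = np.arange(10, dtype=float).reshape(-1, 1)
    return rb.SarTrainingSet("U87", X, 2 * X[:, 0] + 1, ("x1",))


@pytest.fixture(scope="session")
def noiseless_ensemble(noiseless_train):
    return rb.build_sar_ensemble(
        noiseless_train, n_models=50, subsample_fraction=0.7,
        descriptor_subset_size=1, retention_r2=0.5, seed=3,
    )


@pytest.fixture(scope="session")
def small_catalog():
    """12 mock drugs with uniform-random profiles and MWs in (100, 600)."""
    return rb.make_mock_catalog(12, seed=5)


@pytest.fixture(scope="session")
def toy_profile_set():
    """Three drugs with hand-set profile vectors."""
    pset = rb.ProfileSet()
    vecs = {
        "A": np.linspace(0.0, 1.0, 15),
        "B": np.linspace(1.0, 0.0, 15),
        "C": np.full(15, 0.5),
    }
    for i, (did, vec) in enumerate(vecs.items()):
        rec = rb.DrugRecord(drug_id=did, name=f"drug {did}", molecular_weight=200.0 + 100 * i)
        pset.add(rec, rb.MolecularProfile.from_vector(did, vec))
    return pset
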
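import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from almol.chemio import Molecule, fixture_library, molecule_from_smiles
from almol.predictor import FitConfig, LabeledSet, fit_initial

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def synthetic_molecule(name: str, fingerprint, scaffold_key: str = "") -> Molecule:
    """A hand-made molecule for predictor/acquisition unit tests.

    The fingerprint is set directly, so the 'smiles' field is just an
    identifier and need not parse.
    """
    return Molecule(
        smiles=name, fingerprint=np.asarray(fingerprint, dtype=np.int64),
        scaffold_key=scaffold_key,
    )


@pytest.fixture(scope="session")
def small_library():
    return fixture_library(seed=7, n=120)


@pytest.fixture(scope="session")
def mol():
    """SMILES -> featurized Molecule helper."""
    return molecule_from_smiles


@pytest.fixture(scope="session")
def separable_set():
    """Linearly separable toy set: bit 5 set iff active; 10 + 10 records."""
    rng = np.random.default_rng(0)
    mols, labels = [], []
    for i in range(20):
        fp = np.zeros(16, dtype=np.int64)
        fp[rng.integers(6, 16, size=4)] = 1
        active = i < 10
        if active:
            fp[5] = 1
        mols.append(synthetic_molecule(f"M{i}", fp))
        labels.append(1 if active else 0)
    return LabeledSet(molecules=mols, labels=np.array(labels, dtype=float))


@pytest.fixture(scope="session")
def toy_classifier(separable_set):
    cfg = FitConfig(task="classification", n_estimators=25, max_depth=5)
    return fit_initial(separable_set, cfg, seed=3)


@pytest.fixture(scope="session")
def toy_regression_set():
    """Toy regression set: target equals 2 * count at position 0 plus 1."""
    rng = np.random.default_rng(1)
    mols, labels = [], []
    for i in range(30):
        fp = rng.integers(0, 3, size=16).astype(np.int64)
        mols.append(synthetic_molecule(f"R{i}", fp))
        labels.append(2.0 * fp[0] + 1.0)
    return LabeledSet(molecules=mols, labels=np.array(labels, dtype=float))


@pytest.fixture(scope="session")
def toy_regressor(toy_regression_set):
    cfg = FitConfig(task="regression", n_estimators=25)
    return fit_initial(toy_regression_set, cfg, seed=3)
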
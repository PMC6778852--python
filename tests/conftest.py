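import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from refltriage import UnitCell, parse_spacegroup
from refltriage.reflections import ReflectionSet
from refltriage.simulate import SyntheticConfig, simulate_dataset
from refltriage.twinning import candidate_twin_laws

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_merged_set(hkl, I, cell, sg, sigI=None, anomalous=False) -> ReflectionSet:
    """Assemble a merged ReflectionSet from arrays (test helper)."""
    hkl = np.asarray(hkl, dtype=int)
    I = np.asarray(I, dtype=float)
    if sigI is None:
        sigI = np.maximum(np.abs(I), np.abs(I).mean()) * 1e-4 + 1e-12
    df = pd.DataFrame({"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
                       "I": I, "sigI": sigI})
    return ReflectionSet(cell=cell, sg=sg, data=df, merged=True, anomalous=anomalous)


@pytest.fixture(scope="session")
def p1_big():
    """Large untwinned noise-free P1 dataset (~20k acentric uniques) with an
    orthorhombic-metric cell so a pseudo-merohedral twin law exists."""
    cfg = SyntheticConfig(seed=4001, cell=(40.0, 44.0, 48.0, 90.0, 90.0, 90.0),
                          sg_symbol="P1", n_atoms=80, d_min=2.0, noise_k=0.0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def p1_big_twin_law(p1_big):
    rs = p1_big.reflections
    laws = candidate_twin_laws(rs.cell, rs.sg)
    assert laws, "orthorhombic-metric P1 cell must admit twin laws"
    # pick a diagonal two-fold so partner indices stay inside the sphere
    for lw in laws:
        if np.array_equal(np.abs(lw.operator), np.eye(3, dtype=int)):
            return lw
    return laws[0]


@pytest.fixture(scope="session")
def p41_untwinned():
    """Noise-free P41 dataset (twin-law host) used for twin-fraction sweeps."""
    cfg = SyntheticConfig(seed=4002, cell=(42.0, 42.0, 56.0, 90.0, 90.0, 90.0),
                          sg_symbol="P41", n_atoms=100, d_min=2.2, noise_k=0.0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def p41_law(p41_untwinned):
    rs = p41_untwinned.reflections
    return candidate_twin_laws(rs.cell, rs.sg)[0]


@pytest.fixture(scope="session")
def clean_p21():
    """Realistic small merged P21 dataset with mild noise."""
    cfg = SyntheticConfig(seed=4003, cell=(30.0, 34.0, 40.0, 90.0, 100.0, 90.0),
                          sg_symbol="P21", n_atoms=80, d_min=2.2, noise_k=0.03)
    return simulate_dataset(cfg)
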
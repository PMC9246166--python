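import numpy as np
import pytest

from soilpah.catalog import default_catalog
from soilpah.study import load_study_table
from soilpah.synthetic import SourceProfileLibrary, make_source_profiles, simulate_dataset


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def records():
    return load_study_table()


@pytest.fixture(scope="session")
def library():
    return make_source_profiles()


@pytest.fixture(scope="session")
def four_source_dataset():
    """One 50-sample noisy 4-source mixture with its ground truth."""
    return simulate_dataset(50, seed=100)


@pytest.fixture(scope="session")
def separated_two_source_library(library):
    """Two sources with complementary compound support (fully identifiable)."""
    cat = library.catalog
    f_heavy = library.profile("vehicular_emission").copy()
    f_heavy[cat.lmw_indices()] = 0.0
    f_heavy /= f_heavy.sum()
    f_light = library.profile("petrogenic").copy()
    f_light[cat.hmw_indices()] = 0.0
    f_light /= f_light.sum()
    return SourceProfileLibrary(
        names=("vehicular_emission", "petrogenic"),
        profiles=np.array([f_heavy, f_light]),
        catalog=cat,
    )


def best_permutation_cosines(estimated: np.ndarray, truth: np.ndarray):
    """Cosine similarity per factor under the mean-maximizing factor permutation."""
    from itertools import permutations

    best, best_perm = None, None
    for perm in permutations(range(truth.shape[0])):
        cos = [
            float(
                estimated[k]
                @ truth[perm[k]]
                / (np.linalg.norm(estimated[k]) * np.linalg.norm(truth[perm[k]]))
            )
            for k in range(estimated.shape[0])
        ]
        if best is None or np.mean(cos) > np.mean(best):
            best, best_perm = cos, perm
    return best, best_perm
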
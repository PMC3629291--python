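import numpy as np
import pytest

from mitophen import phenodb, synthetic


@pytest.fixture
def toy_profiles():
    """Three diseases over a five-parameter union with mixed overlap."""
    return [
        phenodb.DiseaseProfile(
            "mito-a", "positive", {"ataxia": 60.0, "hypotonia": 80.0, "seizures": 40.0}
        ),
        phenodb.DiseaseProfile(
            "mito-b", "positive", {"ataxia": 50.0, "hypotonia": 90.0, "deafness": 20.0}
        ),
        phenodb.DiseaseProfile(
            "ctrl-a", "negative", {"polyuria": 70.0, "deafness": 10.0}
        ),
    ]


@pytest.fixture
def toy_matrix(toy_profiles):
    return phenodb.build_matrix(toy_profiles)


@pytest.fixture(scope="session")
def separable_db():
    """Default-size synthetic database with disjoint group cores."""
    return synthetic.generate(synthetic.SyntheticConfig(background_rate=0.0, seed=7))


@pytest.fixture(scope="session")
def separable_matrix(separable_db):
    return phenodb.build_matrix(separable_db.profiles)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_profiles(rng, n_diseases=6, n_params=8, groups=("positive", "negative")):
    """Small random database over a shared parameter pool (dense overlap)."""
    params = [f"p{j}" for j in range(n_params)]
    out = []
    for i in range(n_diseases):
        k = int(rng.integers(2, n_params + 1))
        chosen = rng.choice(n_params, size=k, replace=False)
        prev = {params[j]: float(rng.uniform(1, 100)) for j in chosen}
        out.append(
            phenodb.DiseaseProfile(f"d{i}", groups[i % len(groups)], prev)
        )
    return out
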
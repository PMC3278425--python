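import numpy as np
import pandas as pd
import pytest

from stratcorr import Dataset, GroupPair


@pytest.fixture
def toy_dataset() -> Dataset:
    """12 subjects, two study groups + controls, one age-like nuisance."""
    rng = np.random.default_rng(42)
    groups = ["A"] * 4 + ["B"] * 4 + ["REF"] * 4
    return Dataset(
        [f"s{i}" for i in range(12)],
        groups,
        pd.DataFrame(
            {
                "f1": rng.normal(size=12),
                "f2": rng.normal(size=12),
            }
        ),
        pd.DataFrame({"age": rng.uniform(55, 90, size=12)}),
    )


@pytest.fixture
def pair() -> GroupPair:
    return GroupPair("A", "B", "REF")


def random_dataset(
    rng: np.random.Generator,
    n_subjects: int,
    n_features: int = 2,
    n_nuisance: int = 2,
    groups=("A", "B", "REF"),
    missing_fraction: float = 0.0,
) -> Dataset:
    """Random dataset helper for property tests."""
    feat = rng.normal(size=(n_subjects, n_features))
    nuis = rng.normal(size=(n_subjects, n_nuisance)) * 10 + 70
    labels = rng.choice(list(groups), size=n_subjects)
    if missing_fraction:
        feat[rng.uniform(size=feat.shape) < missing_fraction] = np.nan
    return Dataset(
        [f"s{i}" for i in range(n_subjects)],
        labels,
        pd.DataFrame(feat, columns=[f"f{j}" for j in range(n_features)]),
        pd.DataFrame(nuis, columns=[f"n{j}" for j in range(n_nuisance)]),
    )
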
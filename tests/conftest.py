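import numpy as np
import pytest

from fddlelm import (
    FDDLHyperparams,
    GaussianSpec,
    LabeledDataset,
    MIEEGSpec,
    RunConfig,
    make_gaussian_classes,
    make_mi_eeg,
)


@pytest.fixture(scope="session")
def c_grid():
    return RunConfig().C_grid


@pytest.fixture
def small_dataset():
    """Tiny 2-class dataset (p=4, 3+3 samples), unit-normalized columns."""
    rng = np.random.default_rng(42)
    A = rng.normal(size=(4, 6))
    labels = np.array([1, 1, 1, 2, 2, 2])
    return LabeledDataset.from_arrays(A, labels)


def random_dataset(seed, p=5, n_per_class=(6, 5), normalize=True):
    rng = np.random.default_rng(seed)
    labels = np.concatenate(
        [np.full(n, i + 1) for i, n in enumerate(n_per_class)]
    )
    A = rng.normal(size=(p, labels.size))
    return LabeledDataset.from_arrays(A, labels, normalize=normalize)


@pytest.fixture
def gaussian_split():
    """Well-separated 2-class Gaussian data, split 1:1 (60/class per side)."""
    from fddlelm import train_test_split

    ds = make_gaussian_classes(
        GaussianSpec(seed=0, n_per_class=(120, 120), normalize=False)
    )
    return train_test_split(ds, 0.5, seed=0)


@pytest.fixture(scope="session")
def mieeg_epochs():
    return make_mi_eeg(MIEEGSpec(seed=0))


@pytest.fixture
def default_hyper():
    return FDDLHyperparams(
        lambda1=0.01, lambda2=0.01, atoms_per_class=5, max_outer_iter=8, seed=0
    )
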
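import numpy as np
import pytest

from lightptnet import (WindowedDataset, network_spec_from_hyperparameters,
                        simulate_dataset, default_activity_models)


@pytest.fixture(scope="session")
def tiny_spec():
    """A small but complete network spec (fast to build and run)."""
    return network_spec_from_hyperparameters(
        input_shape=(32, 3), n_blocks=2, filters=8, kernel_sizes=[2, 3, 4],
        dilations=[1, 2], dropout=0.05, n_classes=4, seed=0)


@pytest.fixture(scope="session")
def small_synthetic():
    """Six-class synthetic set, 8 subjects, small enough for fast tests."""
    return simulate_dataset(default_activity_models(), n_subjects=8,
                            windows_per_class_per_subject=4, T=64, C=3,
                            sampling_rate=50.0, seed=7)


@pytest.fixture()
def ucihar_layout(tmp_path):
    """Write a 2-window toy fixture in the UCI HAR fixed-width layout and
    return (root, expected_windows, labels, subjects)."""
    from lightptnet.readers import UCIHAR_CHANNELS

    rng = np.random.default_rng(3)
    n, T = 2, 128
    windows = rng.normal(size=(n, T, 9)).round(6)
    labels = np.array([1, 4])     # 1-based ids as shipped
    subjects = np.array([1, 2])
    for part, sl in (("train", slice(0, 1)), ("test", slice(1, 2))):
        d = tmp_path / part / "Inertial Signals"
        d.mkdir(parents=True)
        for c, name in enumerate(UCIHAR_CHANNELS):
            np.savetxt(d / f"{name}_{part}.txt", windows[sl, :, c],
                       fmt="%.6f")
        np.savetxt(tmp_path / part / f"y_{part}.txt", labels[sl], fmt="%d")
        np.savetxt(tmp_path / part / f"subject_{part}.txt", subjects[sl],
                   fmt="%d")
    return tmp_path, windows, labels, subjects


def make_dataset(n=12, T=16, C=2, K=3, n_subjects=4, seed=0):
    rng = np.random.default_rng(seed)
    return WindowedDataset(
        rng.normal(size=(n, T, C)), rng.integers(0, K, size=n),
        np.array([f"s{i % n_subjects}" for i in range(n)]),
        [f"class{k}" for k in range(K)])
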
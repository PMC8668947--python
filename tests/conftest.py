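import numpy as np
import pytest

from ramangan.dataset import SpectraDataset, SpectralAxis
from ramangan.synthetic import (
    default_benchmark_config,
    generate_benchmark,
    make_axis,
)


@pytest.fixture(scope="session")
def toy_axis():
    return make_axis(600.0, 1700.0, 12)


@pytest.fixture
def toy_dataset(toy_axis):
    """9 spectra, 3 classes, mixed treatment flags, on a 12-point axis."""
    rng = np.random.default_rng(42)
    labels = np.array(["BCC", "BCC", "BCC", "NORMAL", "NORMAL", "NORMAL",
                       "SCC", "SCC", "SCC"], dtype=object)
    block = {"BCC": slice(0, 4), "NORMAL": slice(4, 8), "SCC": slice(8, 12)}
    rows = []
    for c in labels:
        x = rng.normal(0.5, 0.1, 12)
        x[block[c]] += 4.0  # class-specific marker block
        rows.append(x)
    X = np.vstack(rows)
    return SpectraDataset(
        axis=toy_axis,
        X=X,
        labels=labels,
        treated=np.array(["treated", "untreated", "untreated"] * 3, dtype=object),
        sample_ids=np.array([f"s{i}" for i in range(9)], dtype=object),
    )


@pytest.fixture(scope="session")
def default_benchmark():
    return generate_benchmark(default_benchmark_config(seed=7))


@pytest.fixture
def single_class_dataset(toy_axis):
    rng = np.random.default_rng(3)
    X = 2.0 + rng.normal(0, 0.2, (8, 12))
    return SpectraDataset(
        axis=toy_axis,
        X=X,
        labels=np.array(["BCC"] * 8, dtype=object),
        treated=np.array(["unknown"] * 8, dtype=object),
        sample_ids=np.array([f"b{i}" for i in range(8)], dtype=object),
    )


def constant_dataset(value_spectrum: np.ndarray, n: int, axis: SpectralAxis) -> SpectraDataset:
    return SpectraDataset(
        axis=axis,
        X=np.tile(value_spectrum, (n, 1)),
        labels=np.array(["BCC"] * n, dtype=object),
        treated=np.array(["unknown"] * n, dtype=object),
        sample_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
    )
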
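"""SMOTE oversampling baseline.

Each synthetic point is a convex interpolation ``x + u * (x_nn - x)`` between
a uniformly chosen class sample ``x`` and one of its k Euclidean nearest
same-class neighbours ``x_nn``, with ``u ~ Uniform[0, 1]``. Generated points
therefore always lie inside the per-feature envelope of the class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .dataset import SpectraDataset

__all__ = ["SmoteParams", "SmoteSampler", "smote_generate"]


@dataclass
class SmoteParams:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


class SmoteSampler(BaseEstimator):
    """Single-class SMOTE with the scikit-learn estimator protocol.

    ``fit(X)`` indexes the class samples; ``sample(n, random_state)`` draws
    n interpolated points.
    """

    def __init__(self, k_neighbors: int = 5):
        self.k_neighbors = k_neighbors

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("SMOTE requires at least 2 class samples")
        if self.k_neighbors >= X.shape[0]:
            raise ValueError(
                f"k_neighbors={self.k_neighbors} must be < class size {X.shape[0]}"
            )
        self.X_ = X
        nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1).fit(X)
        # drop each point's zero-distance self column
        self.neighbors_ = nn.kneighbors(X, return_distance=False)[:, 1:]
        self.n_features_in_ = X.shape[1]
        return self

    def sample(self, n: int, random_state=None) -> np.ndarray:
        if n < 0:
            raise ValueError("n must be >= 0")
        rng = np.random.default_rng(random_state)
        if n == 0:
            return np.empty((0, self.n_features_in_))
        base = rng.integers(0, self.X_.shape[0], size=n)
        pick = rng.integers(0, self.k_neighbors, size=n)
        u = rng.uniform(0.0, 1.0, size=n)
        x = self.X_[base]
        x_nn = self.X_[self.neighbors_[base, pick]]
        return x + u[:, None] * (x_nn - x)


def smote_generate(
    class_data: SpectraDataset,
    n_new: int,
    params: SmoteParams | None = None,
    random_state=None,
) -> SpectraDataset:
    """Generate ``n_new`` SMOTE samples from a single-class dataset."""
    params = params or SmoteParams()
    labels = set(class_data.labels)
    if len(labels) > 1:
        raise ValueError(f"smote_generate expects a single class, got {sorted(labels)}")
    sampler = SmoteSampler(k_neighbors=params.k_neighbors).fit(class_data.X)
    seed = random_state if random_state is not None else params.seed
    X = sampler.sample(n_new, seed)
    label = next(iter(labels)) if labels else "synthetic"
    return SpectraDataset(
        axis=class_data.axis,
        X=X,
        labels=np.array([label] * n_new, dtype=object),
        treated=np.array(["unknown"] * n_new, dtype=object),
        sample_ids=np.array(
            [f"{label}_smote_{i:04d}" for i in range(n_new)], dtype=object
        ),
        synthetic=np.ones(n_new, dtype=bool),
        class_set=class_data.class_set,
    )
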
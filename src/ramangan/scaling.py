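"""Train-fold-fitted per-feature scaling for spectra.

Two methods are supported: ``minmax01`` (training min -> 0, max -> 1) and
``standardize`` (training mean -> 0, sd -> 1), plus ``none``. A feature that
is constant on the training fold maps to 0 under either method, and the
transform is invertible up to 1e-9. Scalers are always fitted on a stated
training subset and never refitted on application data.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectraDataset

METHODS = ("minmax01", "standardize", "none")

__all__ = ["SpectrumScaler", "fit_scaler", "apply_scaler", "invert_scaler"]


class SpectrumScaler(BaseEstimator, TransformerMixin):
    """Per-feature affine scaler with the degenerate-feature -> 0 convention.

    Parameters
    ----------
    method : {"minmax01", "standardize", "none"}
        ``minmax01``: (x - min) / (max - min); ``standardize``: (x - mean) / sd.
        Zero-range / zero-sd features use a unit divisor so they map to 0.
    """

    def __init__(self, method: str = "minmax01"):
        self.method = method

    def fit(self, X, y=None):
        if self.method not in METHODS:
            raise ValueError(f"unknown scaling method {self.method!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("scaler must be fitted on a non-empty 2-D training matrix")
        if self.method == "minmax01":
            self.offset_ = X.min(axis=0)
            span = X.max(axis=0) - self.offset_
            self.scale_ = np.where(span == 0.0, 1.0, span)
        elif self.method == "standardize":
            self.offset_ = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            self.scale_ = np.where(sd == 0.0, 1.0, sd)
        else:
            self.offset_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.offset_) / self.scale_

    def inverse_transform(self, X):
        X = np.asarray(X, dtype=float)
        return X * self.scale_ + self.offset_


def fit_scaler(train: SpectraDataset, method: str = "minmax01") -> SpectrumScaler:
    if train.n == 0:
        raise ValueError("cannot fit a scaler on an empty dataset")
    return SpectrumScaler(method=method).fit(train.X)


def apply_scaler(scaler: SpectrumScaler, dataset: SpectraDataset) -> SpectraDataset:
    """Return a copy of ``dataset`` with scaled intensities; never refits."""
    out = dataset.subset(np.arange(dataset.n))
    out.X = scaler.transform(dataset.X) if dataset.n else dataset.X.copy()
    return out


def invert_scaler(scaler: SpectrumScaler, dataset: SpectraDataset) -> SpectraDataset:
    out = dataset.subset(np.arange(dataset.n))
    out.X = scaler.inverse_transform(dataset.X) if dataset.n else dataset.X.copy()
    return out
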
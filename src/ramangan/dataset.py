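"""Labeled Raman-spectra containers and CSV round-trip I/O.

A dataset is a table: one row per measured spectrum, with a ``sample_id``,
a tissue class label (e.g. BCC / NORMAL / SCC), a laser-treatment flag
(metadata only, never a model feature), a synthetic marker, and ``d``
intensity values on a shared, evenly spaced wavenumber axis (cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATED_VALUES = ("treated", "untreated", "unknown")

__all__ = [
    "SpectralAxis",
    "SpectraDataset",
    "read_spectra_csv",
    "write_spectra_csv",
    "class_counts",
]


@dataclass(frozen=True)
class SpectralAxis:
    """Evenly spaced wavenumber grid: ``d`` positions from ``start`` to ``end`` cm^-1."""

    start: float
    end: float
    d: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"axis start ({self.start}) must be < end ({self.end})")
        if self.d < 2:
            raise ValueError(f"axis needs at least 2 positions, got d={self.d}")

    @property
    def positions(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.d)

    @classmethod
    def from_positions(cls, positions: np.ndarray, rtol: float = 1e-6) -> "SpectralAxis":
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 1 or positions.size < 2:
            raise ValueError("axis requires a 1-D array of >= 2 wavenumbers")
        diffs = np.diff(positions)
        if np.any(diffs <= 0):
            raise ValueError("wavenumber header is not strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=rtol, atol=1e-9 * abs(positions[-1])):
            raise ValueError("wavenumber header is not evenly spaced")
        return cls(float(positions[0]), float(positions[-1]), int(positions.size))


@dataclass
class SpectraDataset:
    """Labeled spectra sharing one axis.

    ``X`` is the (n, d) intensity matrix; per-sample metadata live in parallel
    arrays. ``class_set`` fixes the label ordering used everywhere an index is
    needed (one-hot encoding, confusion matrices); it defaults to the sorted
    labels present, so BCC < NORMAL < SCC.
    """

    axis: SpectralAxis
    X: np.ndarray
    labels: np.ndarray
    treated: np.ndarray
    sample_ids: np.ndarray
    synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]
    class_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n samples x d features)")
        n = self.X.shape[0]
        if self.X.shape[1] != self.axis.d:
            raise ValueError(
                f"intensity width {self.X.shape[1]} does not match axis d={self.axis.d}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("intensities must be finite")
        self.labels = np.asarray(self.labels, dtype=object)
        self.treated = np.asarray(self.treated, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.synthetic is None:
            self.synthetic = np.zeros(n, dtype=bool)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)
        for name, arr in (
            ("labels", self.labels),
            ("treated", self.treated),
            ("sample_ids", self.sample_ids),
            ("synthetic", self.synthetic),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length n={n}")
        bad = set(self.treated) - set(TREATED_VALUES)
        if bad:
            raise ValueError(f"invalid treated flags: {sorted(bad)}")
        if not self.class_set:
            self.class_set = tuple(sorted(set(self.labels)))
        else:
            self.class_set = tuple(self.class_set)
        unknown = set(self.labels) - set(self.class_set)
        if unknown:
            raise ValueError(f"labels outside class_set: {sorted(unknown)}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.axis.d

    def subset(self, idx) -> "SpectraDataset":
        idx = np.asarray(idx)
        return SpectraDataset(
            axis=self.axis,
            X=self.X[idx],
            labels=self.labels[idx],
            treated=self.treated[idx],
            sample_ids=self.sample_ids[idx],
            synthetic=self.synthetic[idx],
            class_set=self.class_set,
        )

    def class_subset(self, label: str) -> "SpectraDataset":
        return self.subset(np.flatnonzero(self.labels == label))

    def concat(self, other: "SpectraDataset") -> "SpectraDataset":
        if other.axis != self.axis:
            raise ValueError("cannot concatenate datasets on different axes")
        class_set = tuple(dict.fromkeys(self.class_set + other.class_set))
        return SpectraDataset(
            axis=self.axis,
            X=np.vstack([self.X, other.X]) if self.n or other.n else self.X,
            labels=np.concatenate([self.labels, other.labels]),
            treated=np.concatenate([self.treated, other.treated]),
            sample_ids=np.concatenate([self.sample_ids, other.sample_ids]),
            synthetic=np.concatenate([self.synthetic, other.synthetic]),
            class_set=class_set,
        )

    def label_indices(self) -> np.ndarray:
        """Integer label codes under the fixed class ordering."""
        lut = {c: i for i, c in enumerate(self.class_set)}
        return np.array([lut[label] for label in self.labels], dtype=int)

    def one_hot(self) -> np.ndarray:
        y = np.zeros((self.n, len(self.class_set)))
        y[np.arange(self.n), self.label_indices()] = 1.0
        return y


_META_COLS = ["sample_id", "label", "treated"]


def write_spectra_csv(dataset: SpectraDataset, path) -> str:
    """Write the canonical CSV: ``sample_id,label,treated,<w_1>,...,<w_d>``.

    Wavenumbers and intensities are serialized with ``repr`` precision so a
    read-back is bit-stable. The synthetic flag is encoded as a ``synth:``
    prefix on sample ids.
    """
    ids = [
        (f"synth:{sid}" if syn and not str(sid).startswith("synth:") else str(sid))
        for sid, syn in zip(dataset.sample_ids, dataset.synthetic)
    ]
    cols = [repr(float(w)) for w in dataset.axis.positions]
    frame = pd.DataFrame(dataset.X, columns=cols)
    frame.insert(0, "treated", dataset.treated)
    frame.insert(0, "label", dataset.labels)
    frame.insert(0, "sample_id", ids)
    frame.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")
    return str(path)


def read_spectra_csv(path) -> SpectraDataset:
    """Read the canonical CSV back into a :class:`SpectraDataset`.

    Raises ``ValueError`` on a malformed header, ragged rows, non-numeric
    intensities or a non-increasing wavenumber header.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV ({exc})") from exc
    if list(frame.columns[:3]) != _META_COLS:
        raise ValueError(
            f"header must start with {_META_COLS}, got {list(frame.columns[:3])}"
        )
    wave_cols = list(frame.columns[3:])
    if not wave_cols:
        raise ValueError("header declares no wavenumber columns")
    try:
        positions = np.array([float(c) for c in wave_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavenumber in header ({exc})") from exc
    axis = SpectralAxis.from_positions(positions)

    n = len(frame)
    X = np.empty((n, axis.d))
    for j, col in enumerate(wave_cols):
        try:
            X[:, j] = pd.to_numeric(frame[col], errors="raise").to_numpy()
        except (ValueError, TypeError) as exc:
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else -1
            raise ValueError(
                f"non-numeric intensity at row {row}, column {col!r}"
            ) from exc
    raw_ids = frame["sample_id"].to_numpy(dtype=object)
    synthetic = np.array([str(s).startswith("synth:") for s in raw_ids])
    ids = np.array(
        [str(s)[6:] if str(s).startswith("synth:") else str(s) for s in raw_ids],
        dtype=object,
    )
    return SpectraDataset(
        axis=axis,
        X=X,
        labels=frame["label"].to_numpy(dtype=object),
        treated=frame["treated"].to_numpy(dtype=object),
        sample_ids=ids,
        synthetic=synthetic,
    )


def class_counts(dataset: SpectraDataset) -> dict[str, int]:
    """Per-class sample counts; every class in ``class_set`` appears (possibly 0)."""
    counts = {c: 0 for c in dataset.class_set}
    for label in dataset.labels:
        counts[label] += 1
    return counts
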
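"""In-memory containers shared across the pipeline stages."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class EpochSet:
    """Segmented multichannel recording: one fixed-length epoch per sample.

    Attributes
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Signal values, one row-block per epoch.
    fs : float
        Sampling rate in Hz.
    labels : ndarray of int, shape (n_epochs,)
        Integer class label per epoch.
    channel_names : list of str
        One name per channel (e.g. 10-20 electrode labels).
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels length must equal the number of epochs")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal the number of channels")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def save(self, path: str | Path) -> None:
        """Write the epoch bundle as an ``.npz`` archive plus sidecar metadata."""
        path = Path(path)
        np.savez(path, data=self.data, labels=self.labels)
        meta = {"fs": self.fs, "channel_names": list(self.channel_names)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        with np.load(path) as npz:
            data, labels = npz["data"], npz["labels"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(data=data, fs=meta["fs"], labels=labels,
                   channel_names=list(meta["channel_names"]))


@dataclass
class FeatureMatrix:
    """An ``n x m`` numeric feature table with named columns and class labels."""

    values: np.ndarray
    names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite (no NaN/Inf)")
        self.names = list(self.names)
        if len(self.names) != self.values.shape[1]:
            raise ValueError("one name per feature column is required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels length must equal the number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray | None = None,
               cols: np.ndarray | None = None) -> "FeatureMatrix":
        """Row/column restriction; ``cols`` may be indices or a boolean mask."""
        values, labels, names = self.values, self.labels, self.names
        if rows is not None:
            values, labels = values[rows], labels[rows]
        if cols is not None:
            cols = np.asarray(cols)
            if cols.dtype == bool:
                cols = np.flatnonzero(cols)
            values = values[:, cols]
            names = [self.names[i] for i in cols]
        return FeatureMatrix(values=values, names=names, labels=labels)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df["label"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label_column: str = "label") -> "FeatureMatrix":
        df = pd.read_csv(path)
        if label_column not in df.columns:
            raise ValueError(f"missing label column {label_column!r}")
        labels = df[label_column].to_numpy(dtype=int)
        feats = df.drop(columns=[label_column])
        return cls(values=feats.to_numpy(dtype=float),
                   names=list(feats.columns), labels=labels)
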
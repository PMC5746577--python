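"""Windowing, per-(channel, subject) standardization, and the features-as-
points cloud with optional PCA reduction.

The point cloud places each *feature* on a row and each observation (one
whole record, for every subject and channel) on a column, so that Mapper
charts the space of features rather than the space of windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .simulate import Record, RecordingSet

__all__ = [
    "AnalysisWindow",
    "PointCloud",
    "segment_record",
    "window_starts",
    "GroupStandardizer",
    "standardize_features",
    "build_point_cloud",
    "pca_reduce",
    "extract_feature_table",
]

OBS_KEY = ["subject", "channel", "trial", "motion", "repetition"]


@dataclass(frozen=True)
class AnalysisWindow:
    """A sliding window cut from one record (0-based, half-open indices)."""

    record: Record
    start: int
    length: int

    @property
    def samples(self) -> np.ndarray:
        return self.record.samples[self.start:self.start + self.length]

    @property
    def sampling_rate(self) -> float:
        return self.record.sampling_rate


def window_starts(n_samples: int, win_ms: float, inc_ms: float,
                  fs: float) -> tuple[int, int, list[int]]:
    """(window length, stride, start indices); lengths derived by round()
    from milliseconds so 250 ms at 1024 Hz is exactly 256 samples."""
    if inc_ms <= 0:
        raise ValueError("increment must be positive")
    length = int(round(win_ms * fs / 1000.0))
    stride = max(int(round(inc_ms * fs / 1000.0)), 1)
    if length > n_samples:
        return length, stride, []
    count = (n_samples - length) // stride + 1
    return length, stride, [i * stride for i in range(count)]


def segment_record(record: Record, win_ms: float = 250.0,
                   inc_ms: float = 125.0) -> list[AnalysisWindow]:
    """Left-aligned sliding windows; a window longer than the record yields
    an empty list with a warning rather than an error."""
    n = len(record.samples)
    length, _, starts = window_starts(n, win_ms, inc_ms,
                                      record.sampling_rate)
    if not starts and length > n:
        warnings.warn(f"window of {length} samples exceeds record length {n}")
    return [AnalysisWindow(record, s, length) for s in starts]


# ---------------------------------------------------------------------------
# feature tables

def extract_feature_table(recordings: RecordingSet,
                          profile="dataset1",
                          win_ms: float | None = None,
                          inc_ms: float | None = None) -> pd.DataFrame:
    """Battery values for every record (or every sliding window when
    ``win_ms`` is given).  Wide format: MultiIndex observation rows, one
    column per feature name."""
    from .features import extract_battery

    rows, keys = [], []
    for rec in recordings:
        fs = rec.sampling_rate
        if win_ms is None:
            segments = [rec.samples]
            starts = [0]
        else:
            wins = segment_record(rec, win_ms, inc_ms if inc_ms else win_ms)
            segments = [w.samples for w in wins]
            starts = [w.start for w in wins]
        for x, s0 in zip(segments, starts):
            rows.append(extract_battery(x, fs, profile))
            keys.append((rec.subject, rec.channel, rec.trial, rec.motion,
                         rec.repetition, s0))
    index = pd.MultiIndex.from_tuples(keys, names=OBS_KEY + ["start"])
    return pd.DataFrame(rows, index=index)


class GroupStandardizer(BaseEstimator, TransformerMixin):
    """Zero-mean unit-variance scaling within (subject, channel) groups.

    Surface-EMG amplitudes vary strongly between electrodes and between
    people; per-group standardization puts all features on one scale before
    PCA and nearest-neighbour analysis.  Zero-variance groups are mapped to
    zeros with a warning.  Idempotent.
    """

    def __init__(self, by: tuple[str, str] = ("subject", "channel"),
                 ddof: int = 1):
        self.by = by
        self.ddof = ddof

    def fit(self, X: pd.DataFrame, y=None):
        grouped = X.groupby(level=list(self.by), sort=True)
        self.means_ = grouped.mean()
        self.stds_ = grouped.std(ddof=self.ddof)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        keys = list(self.by)
        mu = self.means_.reindex(
            pd.MultiIndex.from_frame(
                X.index.to_frame(index=False)[keys])).to_numpy()
        sd = self.stds_.reindex(
            pd.MultiIndex.from_frame(
                X.index.to_frame(index=False)[keys])).to_numpy()
        zero = ~(sd > 0)
        if zero.any():
            bad = sorted({str(X.columns[j]) for j in np.nonzero(zero)[1]})
            warnings.warn("zero-variance group(s) for feature(s) "
                          f"{bad}: values set to 0")
        out = (X.to_numpy() - mu) / np.where(zero, 1.0, sd)
        out[zero] = 0.0
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def standardize_features(table: pd.DataFrame,
                         by: tuple[str, str] = ("subject", "channel")
                         ) -> pd.DataFrame:
    """Functional wrapper: fit + transform on the same table."""
    sizes = table.groupby(level=list(by)).size()
    if (sizes < 2).any():
        raise ValueError("each (subject, channel) group needs >= 2 "
                         "observations to standardize")
    return GroupStandardizer(by=by).fit_transform(table)


# ---------------------------------------------------------------------------
# point cloud

@dataclass
class PointCloud:
    """Features-as-points: ``X[i]`` is the coordinate vector of feature
    ``feature_names[i]`` across all observations (or PC scores thereof)."""

    X: np.ndarray
    feature_names: list[str]
    column_labels: list | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        if self.X.shape[0] != len(self.feature_names):
            raise ValueError("row count must equal number of features")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("point cloud has non-finite coordinates")

    @property
    def n_points(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.feature_names,
                            columns=self.column_labels)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "PointCloud":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(), list(frame.index),
                   list(frame.columns))


def build_point_cloud(table: pd.DataFrame) -> PointCloud:
    """Transpose a standardized whole-record feature table into the cloud:
    rows = features, columns = observations sorted by (subject, channel,
    trial, motion, repetition)."""
    order = [k for k in OBS_KEY if k in table.index.names]
    sorted_table = table.sort_index(level=order)
    if sorted_table.isna().any().any():
        raise ValueError("feature table has missing values; observation "
                         "keys are inconsistent across features")
    labels = ["|".join(str(v) for v in key)
              for key in sorted_table.index]
    return PointCloud(sorted_table.to_numpy().T,
                      list(sorted_table.columns), labels)


def pca_reduce(cloud: PointCloud, variance_target: float = 0.95
               ) -> tuple[PointCloud, np.ndarray]:
    """Replace observation coordinates by the smallest number of PC scores
    whose cumulative explained variance reaches the target.

    Features act as the observations of the PCA (rows of the cloud); returns
    the reduced cloud and the full explained-variance-ratio vector.
    """
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must lie in (0, 1]")
    if cloud.n_points < 2:
        raise ValueError("PCA needs at least 2 points")
    pca = PCA(svd_solver="full").fit(cloud.X)
    ratios = pca.explained_variance_ratio_
    rank = int(np.sum(pca.explained_variance_ > 1e-12))
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(max(k, 1), rank)
    scores = pca.transform(cloud.X)[:, :k]
    reduced = PointCloud(scores, list(cloud.feature_names),
                         [f"PC{i + 1}" for i in range(k)])
    return reduced, ratios
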
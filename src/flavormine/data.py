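"""Feature-table data model, CSV I/O, modality fusion, scaling, splitting, accuracy.

A :class:`SensorFeatureTable` holds one numeric matrix of extracted sensor
intensities (samples x channels) together with sample ids, class labels,
channel names and a per-channel modality tag (``tongue`` / ``nose`` /
``other``).  All downstream stages of the pipeline consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SensorFeatureTable",
    "SplitPlan",
    "IntervalScaler",
    "load_feature_table",
    "fuse",
    "normalize_fit",
    "normalize_apply",
    "stratified_split",
    "accuracy",
    "derive_seed",
]

MODALITIES = ("tongue", "nose", "other")


def derive_seed(master: int, *keys) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and keys.

    String keys are hashed with CRC32 so hierarchical protocols (subset,
    evaluator, repeat) can address independent random streams by name.
    """
    import zlib

    int_keys = tuple(
        k if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode())
        for k in keys
    )
    ss = np.random.SeedSequence(int(master), spawn_key=int_keys)
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SensorFeatureTable:
    """Samples x variables intensity matrix with labels and modality tags."""

    values: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray
    var_names: list[str]
    modality: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.var_names = [str(v) for v in self.var_names]
        if not self.modality:
            self.modality = ["other"] * len(self.var_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("row count must equal number of sample ids and labels")
        if len(self.var_names) != p:
            raise ValueError("column count must equal number of variable names")
        if len(set(self.var_names)) != p:
            raise ValueError("variable names must be unique")
        if len(set(self.sample_ids)) != n:
            dup = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        if len(self.modality) != p:
            raise ValueError("modality must give one tag per variable")
        bad = set(self.modality) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modality tags: {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at row {self.sample_ids[i]!r}, "
                f"column {self.var_names[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def select_variables(self, names) -> "SensorFeatureTable":
        """Return a new table restricted to ``names`` (order preserved as given)."""
        names = list(names)
        unknown = [v for v in names if v not in self.var_names]
        if unknown:
            raise KeyError(f"unknown variables: {unknown}")
        idx = [self.var_names.index(v) for v in names]
        return SensorFeatureTable(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            var_names=names,
            modality=[self.modality[i] for i in idx],
        )

    def select_samples(self, indices) -> "SensorFeatureTable":
        idx = np.asarray(indices, dtype=int)
        return SensorFeatureTable(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            var_names=list(self.var_names),
            modality=list(self.modality),
        )

    def select_modality(self, tag: str) -> "SensorFeatureTable":
        names = [v for v, m in zip(self.var_names, self.modality) if m == tag]
        return self.select_variables(names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.var_names)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "class", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def with_values(self, values: np.ndarray) -> "SensorFeatureTable":
        return SensorFeatureTable(
            values=values,
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            var_names=list(self.var_names),
            modality=list(self.modality),
        )


def load_feature_table(
    path,
    label_column: str = "class",
    id_column: str = "sample_id",
    modality: str | dict = "other",
) -> SensorFeatureTable:
    """Load a feature table from CSV.

    Expected dialect: comma-separated with a header row; one label column and
    optionally one sample-id column; every other column is a numeric sensor
    channel.  ``modality`` is either one tag applied to all channels or a
    ``{channel: tag}`` mapping.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if label_column not in df.columns:
        raise ValueError(f"{path}: missing label column {label_column!r}")
    if id_column in df.columns:
        sample_ids = df[id_column].astype(str).tolist()
    else:
        sample_ids = [f"sample_{i}" for i in range(len(df))]
    labels = df[label_column].to_numpy()
    sensor_cols = [c for c in df.columns if c not in (label_column, id_column)]
    values = np.empty((len(df), len(sensor_cols)))
    for j, col in enumerate(sensor_cols):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric cell {df[col].iloc[row]!r} in column "
                f"{col!r}, row {row}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ValueError(f"{path}: missing value in column {col!r}, row {row}")
        values[:, j] = converted.to_numpy()
    if isinstance(modality, str):
        tags = [modality] * len(sensor_cols)
    else:
        tags = [modality.get(c, "other") for c in sensor_cols]
    return SensorFeatureTable(values, sample_ids, labels, sensor_cols, tags)


def fuse(tongue: SensorFeatureTable, nose: SensorFeatureTable) -> SensorFeatureTable:
    """Feature-level fusion: column-wise concatenation of two modality tables.

    The tables must list the same samples in the same order (no silent
    reordering) and carry identical labels; channel names must not collide.
    """
    if tongue.sample_ids != nose.sample_ids:
        raise ValueError("sample ids differ or are ordered differently; refusing to reorder")
    if not np.array_equal(tongue.labels, nose.labels):
        raise ValueError("class labels disagree between the two tables")
    collisions = set(tongue.var_names) & set(nose.var_names)
    if collisions:
        raise ValueError(f"variable name collision: {sorted(collisions)}")
    return SensorFeatureTable(
        values=np.hstack([tongue.values, nose.values]),
        sample_ids=list(tongue.sample_ids),
        labels=tongue.labels.copy(),
        var_names=tongue.var_names + nose.var_names,
        modality=tongue.modality + nose.modality,
    )


class IntervalScaler(BaseEstimator, TransformerMixin):
    """Per-variable affine rescaling onto the interval (-1, +1).

    ``x' = -1 + 2 (x - min) / (max - min)`` with min/max taken from the data
    the scaler was fitted on.  Values outside the fitted range map outside
    [-1, +1] without clipping.  Constant columns are an error: a dead sensor
    should be noticed, not silently zeroed.
    """

    def __init__(self, feature_names=None):
        self.feature_names = feature_names

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 samples")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        constant = np.flatnonzero(self.data_max_ == self.data_min_)
        if constant.size:
            names = (
                [self.feature_names[i] for i in constant]
                if self.feature_names is not None
                else constant.tolist()
            )
            raise ValueError(f"constant column(s), cannot scale: {names}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count does not match the fitted scaler")
        span = self.data_max_ - self.data_min_
        return -1.0 + 2.0 * (X - self.data_min_) / span


def normalize_fit(table: SensorFeatureTable) -> IntervalScaler:
    """Fit the (-1, +1) scaler on a table (training rows only, by convention)."""
    return IntervalScaler(feature_names=list(table.var_names)).fit(table.values)


def normalize_apply(model: IntervalScaler, table: SensorFeatureTable) -> SensorFeatureTable:
    if model.feature_names is not None and list(table.var_names) != list(model.feature_names):
        unknown = [v for v in table.var_names if v not in model.feature_names]
        raise ValueError(
            f"variable names do not match the fitted scaler (unknown: {unknown})"
        )
    return table.with_values(model.transform(table.values))


@dataclass
class SplitPlan:
    """Disjoint train/test index sets plus the seed that generated them."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def to_json_dict(self, sample_ids) -> dict:
        return {
            "seed": self.seed,
            "train": [sample_ids[i] for i in self.train_indices],
            "test": [sample_ids[i] for i in self.test_indices],
        }


def stratified_split(
    table: SensorFeatureTable, train_fraction: float = 0.8, seed: int = 0
) -> SplitPlan:
    """Class-stratified random split with largest-remainder per-class allocation.

    With 90 samples (5 classes x 18) at fraction 0.8 this yields the 72/18
    train/test allocation; fractional per-class quotas are rounded by largest
    remainder with ties resolved in class order.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly inside (0, 1)")
    labels = table.labels
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        small = classes[counts < 2].tolist()
        raise ValueError(f"every class needs >=2 samples; too small: {small}")
    n_train_total = int(round(table.n_samples * train_fraction))
    n_train_total = min(max(n_train_total, len(classes)), table.n_samples - len(classes))
    quotas = counts * train_fraction
    base = np.floor(quotas).astype(int)
    remainders = quotas - base
    deficit = n_train_total - base.sum()
    # ties on remainder resolved by class order: stable argsort on -remainder
    order = np.argsort(-remainders, kind="stable")
    take = base.copy()
    for k in order[: max(deficit, 0)]:
        take[k] += 1
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls, n_take in zip(classes, take):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        train.extend(idx[:n_take].tolist())
        test.extend(idx[n_take:].tolist())
    return SplitPlan(
        train_indices=np.sort(np.array(train, dtype=int)),
        test_indices=np.sort(np.array(test, dtype=int)),
        seed=seed,
    )


def accuracy(predicted, truth) -> float:
    """Classification accuracy in percent: 100 * (#correct / #total)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {truth.shape}")
    if predicted.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.mean(predicted == truth))
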
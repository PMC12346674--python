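"""Domain types and CSV I/O for e-nose conductivity-ratio measurements.

A measurement is the response of a 10-sensor metal-oxide array to the
headspace of one sample bottle, recorded at 1 Hz for 120 s.  Each value is
the dimensionless conductivity ratio G/G0 (conductivity under sample gas
over baseline conductivity under filtered air), so every value is strictly
positive.  The sensor axis order is a fixed contract (convolutions slide
along it) and follows the instrument's sensor listing.

On disk a dataset is a long-format CSV with one value per row:
``record_id, class, bottle, repetition, t, sensor, value``.  Seconds are
1-based (t = 1..duration) so that "the 21st second" means t = 21.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: Fixed sensor order of the 10-element MOS array (instrument listing order).
SENSOR_NAMES: tuple[str, ...] = (
    "W1C", "W5S", "W3C", "W6S", "W5C", "W1S", "W1W", "W2S", "W2W", "W3S",
)

N_SENSORS = len(SENSOR_NAMES)

CSV_COLUMNS = ("record_id", "class", "bottle", "repetition", "t", "sensor", "value")


class FormatError(ValueError):
    """The on-disk file does not have the expected columns/layout."""


class ValidationError(ValueError):
    """Data violate a domain invariant (positivity, completeness, ...)."""


@dataclass(frozen=True)
class CollectionDesign:
    """Shape of a collection campaign: classes x bottles x repetitions.

    ``duration_s`` seconds are recorded per measurement at ``sample_rate_hz``
    (the instrument samples at 1 Hz, so one column per second by default).
    """

    n_classes: int
    n_bottles: int
    n_repetitions: int
    duration_s: int = 120
    sample_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_classes", "n_bottles", "n_repetitions", "duration_s"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        n = self.duration_s * self.sample_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("duration_s * sample_rate_hz must be an integer")

    @property
    def n_seconds(self) -> int:
        """Number of samples (columns) per record."""
        return int(round(self.duration_s * self.sample_rate_hz))

    @property
    def n_records(self) -> int:
        return self.n_classes * self.n_bottles * self.n_repetitions


#: 13 varieties x 10 bottles x 10 repetitions (variety-identification design).
DESIGN_A = CollectionDesign(n_classes=13, n_bottles=10, n_repetitions=10)
#: 7 origins x 10 bottles x 10 repetitions (origin-tracing designs).
DESIGN_B = CollectionDesign(n_classes=7, n_bottles=10, n_repetitions=10)
DESIGN_C = DESIGN_B

DESIGNS = {"A": DESIGN_A, "B": DESIGN_B, "C": DESIGN_C}


@dataclass
class SensorRecord:
    """One 10-sensor x n-second G/G0 measurement with its labels."""

    record_id: str
    class_label: int
    bottle_id: int
    repetition_id: int
    values: np.ndarray  # shape (N_SENSORS, n_seconds), strictly positive

    def validate(self, n_seconds: int) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != N_SENSORS:
            raise ValidationError(
                f"record {self.record_id!r}: expected {N_SENSORS} sensor rows, "
                f"got shape {v.shape}"
            )
        if v.shape[1] != n_seconds:
            raise ValidationError(
                f"record {self.record_id!r}: expected {n_seconds} seconds, "
                f"got {v.shape[1]}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"record {self.record_id!r}: non-finite value")
        if not np.all(v > 0):
            raise ValidationError(
                f"record {self.record_id!r}: conductivity ratio must be "
                "strictly positive"
            )


@dataclass
class Dataset:
    """An ordered collection of records plus the design that produced it."""

    records: list[SensorRecord]
    design: CollectionDesign

    def validate(self, require_complete: bool = False) -> None:
        n_seconds = self.design.n_seconds
        triples = set()
        for rec in self.records:
            rec.validate(n_seconds)
            key = (rec.class_label, rec.bottle_id, rec.repetition_id)
            if key in triples:
                raise ValidationError(
                    f"duplicate (class, bottle, repetition) triple {key}"
                )
            triples.add(key)
        if require_complete and len(self.records) != self.design.n_records:
            raise ValidationError(
                f"expected {self.design.n_records} records, got {len(self.records)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def class_labels(self) -> np.ndarray:
        return np.array([r.class_label for r in self.records], dtype=int)


@dataclass
class InstanceTable:
    """Per-second training/test instances.

    Each row is the 10-sensor column of one record at one second: the unit
    the classifier consumes.  ``t`` keeps the (1-based) second index so
    second-by-second accuracy curves can be computed downstream.
    """

    X: np.ndarray            # (n_rows, N_SENSORS) feature vectors
    y: np.ndarray            # (n_rows,) class labels
    record_ids: np.ndarray   # (n_rows,) source record id per row
    t: np.ndarray            # (n_rows,) 1-based second index per row

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.record_ids = np.asarray(self.record_ids)
        self.t = np.asarray(self.t, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != N_SENSORS:
            raise ValidationError(f"feature matrix must be (n, {N_SENSORS})")
        n = self.X.shape[0]
        if not (len(self.y) == len(self.record_ids) == len(self.t) == n):
            raise ValidationError("instance table columns have unequal lengths")

    def __len__(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(SENSOR_NAMES))
        df.insert(0, "record_id", self.record_ids)
        df.insert(1, "class", self.y)
        df.insert(2, "t", self.t)
        return df


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as long-format CSV with deterministic row order.

    Rows are ordered by record (input order), then sensor (fixed array
    order), then ascending second, so writing the same dataset twice yields
    byte-identical files.
    """
    dataset.validate()
    n_seconds = dataset.design.n_seconds
    frames = []
    for rec in dataset.records:
        n = N_SENSORS * n_seconds
        frames.append(
            pd.DataFrame(
                {
                    "record_id": np.repeat(rec.record_id, n),
                    "class": np.repeat(rec.class_label, n),
                    "bottle": np.repeat(rec.bottle_id, n),
                    "repetition": np.repeat(rec.repetition_id, n),
                    "t": np.tile(np.arange(1, n_seconds + 1), N_SENSORS),
                    "sensor": np.repeat(list(SENSOR_NAMES), n_seconds),
                    "value": np.asarray(rec.values, dtype=float).ravel(),
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(CSV_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n")


def read_dataset(path: str | Path, design: CollectionDesign) -> Dataset:
    """Read a long-format CSV written by :func:`write_dataset`.

    Raises :class:`FormatError` for missing columns and
    :class:`ValidationError` (naming the record) for incomplete records or
    non-positive values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"missing CSV columns: {sorted(missing)}")
    n_seconds = design.n_seconds
    sensor_index = {name: i for i, name in enumerate(SENSOR_NAMES)}

    records: list[SensorRecord] = []
    # groupby(sort=False) preserves first-appearance order -> round-trip identity
    for rid, grp in df.groupby("record_id", sort=False):
        unknown = set(grp["sensor"]) - set(SENSOR_NAMES)
        if unknown:
            raise FormatError(f"record {rid!r}: unknown sensors {sorted(unknown)}")
        values = np.full((N_SENSORS, n_seconds), np.nan)
        t = grp["t"].to_numpy(dtype=int)
        if t.min() < 1 or t.max() > n_seconds:
            raise ValidationError(
                f"record {rid!r}: second index outside 1..{n_seconds}"
            )
        rows = np.array([sensor_index[s] for s in grp["sensor"]], dtype=int)
        values[rows, t - 1] = grp["value"].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError(
                f"record {rid!r}: incomplete record "
                f"(expected {N_SENSORS} sensors x {n_seconds} seconds)"
            )
        rec = SensorRecord(
            record_id=str(rid),
            class_label=int(grp["class"].iloc[0]),
            bottle_id=int(grp["bottle"].iloc[0]),
            repetition_id=int(grp["repetition"].iloc[0]),
            values=values,
        )
        rec.validate(n_seconds)
        records.append(rec)
    ds = Dataset(records=records, design=design)
    ds.validate()
    return ds


def slice_instances(dataset: Dataset, window: tuple[int, int]) -> InstanceTable:
    """Cut each record into per-second instances over a 1-based window.

    ``window = (21, 120)`` yields 100 rows per record: the stable phase
    after the initial gas-contact transient.
    """
    t_start, t_end = window
    n_seconds = dataset.design.n_seconds
    if not (1 <= t_start <= t_end <= n_seconds):
        raise ValidationError(
            f"window {window} outside record duration 1..{n_seconds}"
        )
    w = t_end - t_start + 1
    seconds = np.arange(t_start, t_end + 1)
    X, y, rids, ts = [], [], [], []
    for rec in dataset.records:
        X.append(np.asarray(rec.values, dtype=float)[:, t_start - 1 : t_end].T)
        y.append(np.full(w, rec.class_label, dtype=int))
        rids.append(np.repeat(rec.record_id, w))
        ts.append(seconds)
    if not X:
        empty = np.empty((0,))
        return InstanceTable(np.empty((0, N_SENSORS)), empty, empty, empty)
    return InstanceTable(
        X=np.concatenate(X),
        y=np.concatenate(y),
        record_ids=np.concatenate(rids),
        t=np.concatenate(ts),
    )


def write_label_map(labels: Sequence[str] | dict[int, str], path: str | Path) -> None:
    """Write the {class index: human name} sidecar YAML."""
    if not isinstance(labels, dict):
        labels = {i: str(name) for i, name in enumerate(labels)}
    with open(path, "w") as fh:
        yaml.safe_dump(labels, fh, sort_keys=True)


def read_label_map(path: str | Path) -> dict[int, str]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {int(k): str(v) for k, v in raw.items()}
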
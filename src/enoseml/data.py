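"""Data model for e-nose measurements and dataset assembly.

A *measurement* is one 100 s sampling of a liquor headspace: a 100x10 matrix
of dimensionless sensor response ratios (one column per MOS channel, one row
per second), annotated with the liquor label, acquisition day (1-25) and
replicate number (1-9). The full acquisition protocol comprises 25 days x
9 liquor types x 9 replicates = 2025 measurements.

Three dataset variants are assembled from a protocol-complete set:

* ``A`` — the six base liquors (unblended, aged 3-13 years), 1350 measurements;
* ``B`` — the three commercial liquors (blends of the base liquors), 675;
* ``C`` — everything, 2025.

Train/test splitting is by acquisition day (default: days 1-20 train,
21-25 test) so that day-level sensor drift is never shared across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SENSOR_CHANNELS",
    "SENSOR_CODES",
    "LIQUOR_CLASSES",
    "LIQUOR_LABELS",
    "SensorChannel",
    "LiquorClass",
    "Measurement",
    "MeasurementSet",
    "SplitSpec",
    "read_measurement_table",
    "write_measurement_table",
    "assemble_dataset",
    "day_split",
]

N_TIMEPOINTS = 100
N_CHANNELS = 10


@dataclass(frozen=True)
class SensorChannel:
    """One MOS sensor of the PEN3 array."""

    index: int  # 1-based position in the array
    code: str
    descriptor: str


#: The standard PEN3 sensor array, in fixed instrument order MOS1..MOS10.
SENSOR_CHANNELS: tuple[SensorChannel, ...] = (
    SensorChannel(1, "W1C", "Aromatic constituent"),
    SensorChannel(2, "W5S", "Nitride oxides"),
    SensorChannel(3, "W3C", "Ammonia and aromatic constituent"),
    SensorChannel(4, "W6S", "Hydrogen"),
    SensorChannel(5, "W5C", "Alkanes and aromatic constituent"),
    SensorChannel(6, "W1S", "Methane"),
    SensorChannel(7, "W1W", "Sulfide"),
    SensorChannel(8, "W2S", "Alcohol"),
    SensorChannel(9, "W2W", "Aroma constituent and organic sulfur compounds"),
    SensorChannel(10, "W3S", "Alkanes"),
)

SENSOR_CODES: tuple[str, ...] = tuple(c.code for c in SENSOR_CHANNELS)


@dataclass(frozen=True)
class LiquorClass:
    """A liquor type: either a base liquor or a commercial blend.

    ``blend`` lists (base-label, percent) pairs for commercial liquors and is
    empty for base liquors; percentages of a blend sum to 100.
    """

    label: str
    group: str  # "base" or "commercial"
    aging_years: int | None = None
    blend: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.group not in ("base", "commercial"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.blend:
            total = sum(p for _, p in self.blend)
            if abs(total - 100.0) > 1e-9:
                raise ValueError(
                    f"blend percentages for {self.label} sum to {total}, not 100"
                )


#: The closed-world label set: six base liquors (by aging duration, years)
#: and three commercial blends.
LIQUOR_CLASSES: dict[str, LiquorClass] = {
    c.label: c
    for c in (
        LiquorClass("BL13", "base", aging_years=13),
        LiquorClass("BL11", "base", aging_years=11),
        LiquorClass("BL8", "base", aging_years=8),
        LiquorClass("BL6", "base", aging_years=6),
        LiquorClass("BL5", "base", aging_years=5),
        LiquorClass("BL3", "base", aging_years=3),
        LiquorClass(
            "CL1",
            "commercial",
            blend=(("BL13", 0.01), ("BL11", 8.99), ("BL5", 31.0), ("BL3", 60.0)),
        ),
        LiquorClass(
            "CL2",
            "commercial",
            blend=(("BL13", 0.008), ("BL8", 5.992), ("BL5", 24.0), ("BL3", 70.0)),
        ),
        LiquorClass(
            "CL3",
            "commercial",
            blend=(("BL13", 0.006), ("BL6", 3.994), ("BL5", 16.0), ("BL3", 80.0)),
        ),
    )
}

LIQUOR_LABELS: tuple[str, ...] = tuple(LIQUOR_CLASSES)
BASE_LABELS: tuple[str, ...] = tuple(
    l for l, c in LIQUOR_CLASSES.items() if c.group == "base"
)
COMMERCIAL_LABELS: tuple[str, ...] = tuple(
    l for l, c in LIQUOR_CLASSES.items() if c.group == "commercial"
)


@dataclass
class Measurement:
    """One liquor sampling: a 100x10 response matrix plus metadata."""

    responses: np.ndarray  # (100, 10), positive response ratios
    liquor: LiquorClass
    day: int
    replicate: int
    id: str

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.float64)
        if self.responses.shape != (N_TIMEPOINTS, N_CHANNELS):
            raise ValueError(
                f"measurement {self.id!r}: responses must be "
                f"{N_TIMEPOINTS}x{N_CHANNELS}, got {self.responses.shape}"
            )
        if not np.all(np.isfinite(self.responses)):
            raise ValueError(f"measurement {self.id!r}: non-finite response value")
        if np.any(self.responses <= 0):
            raise ValueError(f"measurement {self.id!r}: non-positive response value")

    @property
    def label(self) -> str:
        return self.liquor.label


class MeasurementSet:
    """An ordered collection of measurements with unique ids."""

    def __init__(
        self, measurements: Iterable[Measurement] = (), provenance: str = "synthetic"
    ) -> None:
        self.provenance = provenance
        self._measurements: list[Measurement] = []
        self._ids: set[str] = set()
        for m in measurements:
            self.add(m)

    def add(self, m: Measurement) -> None:
        if m.id in self._ids:
            raise ValueError(f"duplicate measurement id {m.id!r}")
        self._ids.add(m.id)
        self._measurements.append(m)

    def __len__(self) -> int:
        return len(self._measurements)

    def __iter__(self) -> Iterator[Measurement]:
        return iter(self._measurements)

    def __getitem__(self, i: int) -> Measurement:
        return self._measurements[i]

    def ids(self) -> list[str]:
        return [m.id for m in self._measurements]

    def labels(self) -> list[str]:
        return [m.label for m in self._measurements]

    def subset(self, predicate) -> "MeasurementSet":
        return MeasurementSet(
            (m for m in self._measurements if predicate(m)), provenance=self.provenance
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementSet):
            return NotImplemented
        if len(self) != len(other):
            return False
        return all(
            a.id == b.id
            and a.label == b.label
            and a.day == b.day
            and a.replicate == b.replicate
            and np.array_equal(a.responses, b.responses)
            for a, b in zip(self, other)
        )


@dataclass(frozen=True)
class SplitSpec:
    """Day-based train/test partition (disjoint day sets within 1-25)."""

    train_days: frozenset[int] = frozenset(range(1, 21))
    test_days: frozenset[int] = frozenset(range(21, 26))

    def __post_init__(self) -> None:
        train = frozenset(self.train_days)
        test = frozenset(self.test_days)
        object.__setattr__(self, "train_days", train)
        object.__setattr__(self, "test_days", test)
        if train & test:
            raise ValueError(f"overlapping day sets: {sorted(train & test)}")
        if not (train | test) <= set(range(1, 26)):
            bad = sorted((train | test) - set(range(1, 26)))
            raise ValueError(f"days outside 1-25: {bad}")


# ---------------------------------------------------------------------------
# Tabular I/O
#
# Wide CSV dialect: one row per (measurement id, second); columns
#   id,label,day,replicate,t,W1C,W5S,W3C,W6S,W5C,W1S,W1W,W2S,W2W,W3S
# with t an integer second 1-100. Values round-trip at full float precision.
# ---------------------------------------------------------------------------

_META_COLUMNS = ("id", "label", "day", "replicate", "t")


def write_measurement_table(mset: MeasurementSet, path: str | Path) -> None:
    """Write a measurement set as a wide CSV (one row per id and second)."""
    path = Path(path)
    n = len(mset)
    if n == 0:
        pd.DataFrame(columns=list(_META_COLUMNS) + list(SENSOR_CODES)).to_csv(
            path, index=False
        )
        return
    frames = []
    t = np.arange(1, N_TIMEPOINTS + 1)
    for m in mset:
        df = pd.DataFrame(m.responses, columns=list(SENSOR_CODES))
        df.insert(0, "t", t)
        df.insert(0, "replicate", m.replicate)
        df.insert(0, "day", m.day)
        df.insert(0, "label", m.label)
        df.insert(0, "id", m.id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    # repr-precision floats so read -> write -> read is the identity
    out.to_csv(path, index=False, float_format="%.17g")


def read_measurement_table(path: str | Path) -> MeasurementSet:
    """Read a wide-CSV measurement table written by :func:`write_measurement_table`.

    Raises ``ValueError`` with a located message on a missing channel column,
    a non-positive response, a duplicate (id, t) pair, or a measurement with
    other than 100 timepoints.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {missing}")
    missing = [c for c in SENSOR_CODES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing channel column(s) {missing}")
    mset = MeasurementSet(provenance="file")
    if df.empty:
        return mset
    dup = df.duplicated(subset=["id", "t"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (id, t) = ({row['id']!r}, {int(row['t'])})"
        )
    for mid, g in df.groupby("id", sort=False):
        g = g.sort_values("t")
        if len(g) != N_TIMEPOINTS or list(g["t"]) != list(range(1, N_TIMEPOINTS + 1)):
            raise ValueError(
                f"{path}: measurement {mid!r} has {len(g)} timepoints; "
                f"expected t = 1..{N_TIMEPOINTS}"
            )
        label = str(g["label"].iloc[0])
        if label not in LIQUOR_CLASSES:
            raise ValueError(f"{path}: measurement {mid!r} has unknown label {label!r}")
        values = g[list(SENSOR_CODES)].to_numpy(dtype=np.float64)
        if np.any(values <= 0) or not np.all(np.isfinite(values)):
            t_bad = int(g["t"].to_numpy()[np.argwhere(~(values > 0))[0][0]])
            raise ValueError(
                f"{path}: measurement {mid!r} has a non-positive or non-finite "
                f"response at t={t_bad}"
            )
        mset.add(
            Measurement(
                responses=values,
                liquor=LIQUOR_CLASSES[label],
                day=int(g["day"].iloc[0]),
                replicate=int(g["replicate"].iloc[0]),
                id=str(mid),
            )
        )
    return mset


# ---------------------------------------------------------------------------
# Dataset assembly and splitting
# ---------------------------------------------------------------------------


def assemble_dataset(mset: MeasurementSet, variant: str) -> MeasurementSet:
    """Select the measurements of a dataset variant.

    ``A`` keeps base liquors only, ``B`` commercial liquors only, ``C`` all.
    """
    variant = variant.upper()
    if variant not in ("A", "B", "C"):
        raise ValueError(f"unknown dataset variant {variant!r}; expected A, B or C")
    for m in mset:
        if m.label not in LIQUOR_CLASSES:
            raise ValueError(f"unknown liquor label {m.label!r} in measurement {m.id!r}")
    if variant == "C":
        return mset.subset(lambda m: True)
    group = "base" if variant == "A" else "commercial"
    return mset.subset(lambda m: m.liquor.group == group)


def day_split(
    mset: MeasurementSet, spec: SplitSpec | None = None
) -> tuple[MeasurementSet, MeasurementSet]:
    """Partition a measurement set by acquisition day.

    Measurements on days in neither set are dropped (the split is still a
    partition of the measurements whose day is covered).
    """
    spec = spec or SplitSpec()
    train = mset.subset(lambda m: m.day in spec.train_days)
    test = mset.subset(lambda m: m.day in spec.test_days)
    return train, test
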
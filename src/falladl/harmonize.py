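"""Harmonization of heterogeneous waist-IMU recordings.

Source datasets differ in sampling rate (20-238 Hz), axis orientation,
units and sensor range. This module normalizes every recording to a
canonical form: tri-axial accelerometer and gyroscope re-expressed in the
body frame (anteroposterior, mediolateral, vertical), acceleration in
m/s**2, angular velocity in deg/s, uniformly resampled to 50 Hz.

The canonical axis order everywhere in the package is ``(AP, ML, V)``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from falladl.taxonomy import TAXONOMY

CANONICAL_RATE_HZ = 50.0
G_TO_MS2 = 9.81
UNLABELED = -1

CANONICAL_AXES = ("AP", "ML", "V")
_NATIVE_AXES = ("x", "y", "z")

#: native-CSV column layout consumed by :func:`read_stream_csv`
STREAM_COLUMNS = (
    "time_s", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z",
    "label", "subject", "dataset",
)
CANONICAL_COLUMNS = (
    "time_s", "acc_ap", "acc_ml", "acc_v", "gyr_ap", "gyr_ml", "gyr_v",
    "label", "subject", "dataset",
)


class ConfigurationError(ValueError):
    """Invalid sensor mapping or option."""


class DataError(ValueError):
    """Malformed recording data."""


@dataclass(frozen=True)
class SensorMapping:
    """How one source dataset's native sensor frame maps to the body frame.

    Parameters
    ----------
    axis_map : dict
        Assignment of each canonical axis (``AP``, ``ML``, ``V``) to a
        signed native axis, e.g. ``{"AP": "+y", "ML": "-x", "V": "+z"}``.
        Must be a signed permutation whose implied 3x3 matrix is a proper
        rotation (determinant +1, handedness preserved).
    acc_unit : str
        ``"g"`` or ``"m/s^2"``.
    gyro_unit : str
        ``"deg/s"`` or ``"rad/s"``.
    native_rate : float
        Native sampling rate in Hz (> 0).
    acc_range : float, optional
        Symmetric clipping bound of the accelerometer, in ``acc_unit``.
    """

    axis_map: dict = field(default_factory=lambda: {"AP": "+x", "ML": "+y", "V": "+z"})
    acc_unit: str = "m/s^2"
    gyro_unit: str = "deg/s"
    native_rate: float = 50.0
    acc_range: float | None = None

    def __post_init__(self) -> None:
        if set(self.axis_map) != set(CANONICAL_AXES):
            raise ConfigurationError(f"axis_map must assign exactly {CANONICAL_AXES}")
        if self.acc_unit not in ("g", "m/s^2", "m/s²"):
            raise ConfigurationError(f"unknown accelerometer unit {self.acc_unit!r}")
        if self.gyro_unit not in ("deg/s", "rad/s"):
            raise ConfigurationError(f"unknown gyroscope unit {self.gyro_unit!r}")
        if not self.native_rate > 0:
            raise ConfigurationError("native_rate must be > 0")
        R = self.rotation_matrix()
        # signed permutation: one +-1 entry per row and per column
        if not (np.abs(np.abs(R).sum(axis=0) - 1) < 1e-12).all():
            raise ConfigurationError("axis_map must use each native axis exactly once")
        if abs(np.linalg.det(R) - 1.0) > 1e-12:
            raise ConfigurationError(
                "axis_map must be a proper rotation (determinant +1); "
                "this mapping flips handedness"
            )

    def rotation_matrix(self) -> np.ndarray:
        """3x3 signed-permutation matrix R with canonical = R @ native."""
        R = np.zeros((3, 3))
        for i, canon in enumerate(CANONICAL_AXES):
            tok = self.axis_map[canon].strip()
            sign = 1.0
            if tok[0] in "+-":
                sign = -1.0 if tok[0] == "-" else 1.0
                tok = tok[1:]
            if tok not in _NATIVE_AXES:
                raise ConfigurationError(f"unknown native axis {tok!r}")
            R[i, _NATIVE_AXES.index(tok)] = sign
        return R

    @property
    def acc_scale(self) -> float:
        return G_TO_MS2 if self.acc_unit == "g" else 1.0

    @property
    def gyro_scale(self) -> float:
        return 180.0 / math.pi if self.gyro_unit == "rad/s" else 1.0


@dataclass
class RawRecording:
    """One labeled waist-IMU recording in its native frame and units."""

    timestamps: np.ndarray  # (N,) seconds, strictly increasing
    acc: np.ndarray         # (N, 3)
    gyro: np.ndarray        # (N, 3)
    labels: np.ndarray      # (N,) class id or UNLABELED
    subject_id: str
    dataset_id: str

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.timestamps.shape[0]
        if n < 1:
            raise DataError("recording must contain at least one sample")
        for name, arr, shape in (
            ("acc", self.acc, (n, 3)),
            ("gyro", self.gyro, (n, 3)),
            ("labels", self.labels, (n,)),
        ):
            if arr.shape != shape:
                raise DataError(f"{name} has shape {arr.shape}, expected {shape}")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]


@dataclass
class CanonicalStream:
    """Uniform 50 Hz, 6-channel labeled recording in canonical axes/units.

    ``acc`` is (N, 3) in m/s**2 and ``gyro`` (N, 3) in deg/s, both in
    (AP, ML, V) order; implied sample spacing is exactly 1/50 s.
    """

    acc: np.ndarray
    gyro: np.ndarray
    labels: np.ndarray
    subject_id: str
    dataset_id: str
    rate: float = CANONICAL_RATE_HZ

    def __post_init__(self) -> None:
        if self.rate != CANONICAL_RATE_HZ:
            raise DataError("canonical streams are fixed at 50 Hz")
        if not (np.isfinite(self.acc).all() and np.isfinite(self.gyro).all()):
            raise DataError("canonical stream contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def channels(self) -> np.ndarray:
        """(N, 6) array: acc AP, ML, V then gyro AP, ML, V."""
        return np.hstack([self.acc, self.gyro])


def reorient(rec: RawRecording, mapping: SensorMapping) -> RawRecording:
    """Rotate a recording into the body frame and convert units.

    Each sample is the signed permutation of the native sample given by
    ``mapping.axis_map``; acceleration in g is converted to m/s**2 and
    angular velocity in rad/s to deg/s. Timestamps and labels pass
    through untouched. Per-sample vector magnitudes are preserved up to
    the unit conversion (the mapping is a rotation).
    """
    R = mapping.rotation_matrix()
    acc = rec.acc @ R.T * mapping.acc_scale
    if mapping.acc_range is not None:
        bound = mapping.acc_range * mapping.acc_scale
        acc = np.clip(acc, -bound, bound)
    gyro = rec.gyro @ R.T * mapping.gyro_scale
    return RawRecording(
        timestamps=rec.timestamps.copy(),
        acc=acc,
        gyro=gyro,
        labels=rec.labels.copy(),
        subject_id=rec.subject_id,
        dataset_id=rec.dataset_id,
    )


def resample(rec: RawRecording) -> CanonicalStream:
    """Resample an already-reoriented recording onto the 50 Hz grid.

    The output grid is half-open and anchored at the first timestamp:
    ``t_first + k/50`` for ``k = 0 .. floor(T*50) - 1`` where
    ``T = t_last - t_first``. Channels are linearly interpolated (no
    anti-alias filtering; raw signals are deliberately used unfiltered).
    The label at each grid point is the label of the nearest-in-time
    input sample, ties resolved toward the earlier sample.
    """
    t = rec.timestamps
    if rec.n_samples >= 2 and not (np.diff(t) > 0).all():
        raise DataError("timestamps must be strictly increasing")
    T = t[-1] - t[0]
    n_out = int(math.floor(T * CANONICAL_RATE_HZ))
    if n_out < 1:
        raise DataError("recording shorter than one 50 Hz sample")
    grid = t[0] + np.arange(n_out) / CANONICAL_RATE_HZ

    acc = np.column_stack([np.interp(grid, t, rec.acc[:, j]) for j in range(3)])
    gyro = np.column_stack([np.interp(grid, t, rec.gyro[:, j]) for j in range(3)])

    # nearest-sample label transfer, ties -> earlier sample
    idx = np.searchsorted(t, grid)                 # first t >= grid point
    idx = np.clip(idx, 1, len(t) - 1)
    left, right = t[idx - 1], t[idx]
    # tie -> earlier; tolerance so float rounding cannot flip exact ties
    use_left = (grid - left) - (right - grid) <= 1e-9 * (right - left)
    nearest = np.where(use_left, idx - 1, idx)
    nearest[grid <= t[0]] = 0
    labels = rec.labels[nearest]

    return CanonicalStream(
        acc=acc, gyro=gyro, labels=labels,
        subject_id=rec.subject_id, dataset_id=rec.dataset_id,
    )


def harmonize_recording(rec: RawRecording, mapping: SensorMapping) -> CanonicalStream:
    """Reorient then resample: native recording -> canonical stream."""
    return resample(reorient(rec, mapping))


# ---------------------------------------------------------------------------
# CSV / manifest I/O


def read_manifest(path: str | Path) -> SensorMapping:
    """Read a per-dataset YAML manifest into a :class:`SensorMapping`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SensorMapping(
        axis_map=dict(doc["axis_map"]),
        acc_unit=str(doc.get("acc_unit", "m/s^2")),
        gyro_unit=str(doc.get("gyro_unit", "deg/s")),
        native_rate=float(doc["native_rate"]),
        acc_range=None if doc.get("acc_range") is None else float(doc["acc_range"]),
    )


def write_manifest(mapping: SensorMapping, path: str | Path) -> None:
    doc = dataclasses.asdict(mapping)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_stream_csv(path: str | Path) -> RawRecording:
    """Read a native-axis stream CSV (see :data:`STREAM_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = set(STREAM_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"stream CSV missing columns: {sorted(missing)}")
    return RawRecording(
        timestamps=df["time_s"].to_numpy(float),
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(float),
        gyro=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(float),
        labels=df["label"].to_numpy(int),
        subject_id=str(df["subject"].iloc[0]),
        dataset_id=str(df["dataset"].iloc[0]),
    )


def write_stream_csv(rec: RawRecording, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_s": rec.timestamps,
        "acc_x": rec.acc[:, 0], "acc_y": rec.acc[:, 1], "acc_z": rec.acc[:, 2],
        "gyr_x": rec.gyro[:, 0], "gyr_y": rec.gyro[:, 1], "gyr_z": rec.gyro[:, 2],
        "label": rec.labels,
        "subject": rec.subject_id, "dataset": rec.dataset_id,
    })
    df.to_csv(path, index=False)


def write_canonical_csv(stream: CanonicalStream, path: str | Path) -> None:
    n = stream.n_samples
    df = pd.DataFrame({
        "time_s": np.arange(n) / CANONICAL_RATE_HZ,
        "acc_ap": stream.acc[:, 0], "acc_ml": stream.acc[:, 1], "acc_v": stream.acc[:, 2],
        "gyr_ap": stream.gyro[:, 0], "gyr_ml": stream.gyro[:, 1], "gyr_v": stream.gyro[:, 2],
        "label": stream.labels,
        "subject": stream.subject_id, "dataset": stream.dataset_id,
    })
    df.to_csv(path, index=False)


def read_canonical_csv(path: str | Path) -> CanonicalStream:
    df = pd.read_csv(path)
    stream = CanonicalStream(
        acc=df[["acc_ap", "acc_ml", "acc_v"]].to_numpy(float),
        gyro=df[["gyr_ap", "gyr_ml", "gyr_v"]].to_numpy(float),
        labels=df["label"].to_numpy(int),
        subject_id=str(df["subject"].iloc[0]),
        dataset_id=str(df["dataset"].iloc[0]),
    )
    TAXONOMY.validate_labels(stream.labels[stream.labels >= 0])
    return stream
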
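"""CSV and config I/O for sensor, radar and result data.

The wearable's native binary export is out of scope; the on-disk convention
here is plain comma-separated text, ``.`` decimal, UTF-8, one header row:

* IMU: ``t,ax,ay,az,gx,gy,gz`` — seconds, m/s² (specific force, sensor
  frame), rad/s, nominally 200 Hz.
* Speed series (GNSS or radar): ``t,v`` — seconds, m/s.
* Session config: YAML ``key: value`` pairs (see :class:`SessionConfig`).

Timestamps are seconds from recording start.  Accelerations may optionally be
stored in units of g (``acc_in_g: true`` in the config); they are converted
to m/s² on load with g = 9.80665 m/s².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, EmptySeriesError, FormatError

#: Standard gravity, m/s².
GRAVITY = 9.80665

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
SPEED_COLUMNS = ["t", "v"]


def _infer_fs(t: np.ndarray) -> float:
    """Sampling frequency from the median timestep."""
    if len(t) < 2:
        raise EmptySeriesError("need at least two samples to infer a rate")
    return 1.0 / float(np.median(np.diff(t)))


def _check_monotone(t: np.ndarray, what: str) -> None:
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise DataError(f"{what}: time stamps must be strictly increasing")


@dataclass
class ImuRecording:
    """Tri-axial specific force and angular rate in the sensor frame.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Seconds from recording start, strictly increasing.
    acc : ndarray, shape (n, 3)
        Specific force a_SF, m/s² (gravity reaction included).
    gyr : ndarray, shape (n, 3)
        Angular rate, rad/s.
    fs : float
        Sampling rate, Hz (nominally 200).
    """

    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    fs: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if not (len(self.t) == len(self.acc) == len(self.gyr)):
            raise DataError("IMU arrays must have equal length")
        if self.acc.ndim != 2 or self.acc.shape[1] != 3 or self.gyr.shape[1] != 3:
            raise DataError("acc and gyr must be (n, 3) arrays")
        _check_monotone(self.t, "ImuRecording")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SpeedSeries:
    """Scalar ground-speed series (base for GNSS and radar)."""

    t: np.ndarray
    v: np.ndarray
    fs: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.t) != len(self.v):
            raise DataError("t and v must have equal length")
        _check_monotone(self.t, type(self).__name__)
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.t)


class GnssSeries(SpeedSeries):
    """GNSS ground speed v_GNSS, nominally 10 Hz.  Speeds must be >= 0."""

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.v < 0):
            raise DataError("GNSS ground speed must be non-negative")


class RadarSeries(SpeedSeries):
    """Reference radar speed v_R, nominally 50 Hz."""


@dataclass
class SessionConfig:
    """Per-session parameters for the estimation pipeline.

    Parameters
    ----------
    distance : float
        Sprint distance D in metres (30/40/60 m are typical test distances).
    mass : float
        Athlete mass M, kg; used only for the force/power profiles.
    coarse_start : float
        Manually chosen time (s) from which to search for the sprint start.
    static_window : float
        Length (s) of the still-standing window used to initialise the
        orientation filter.
    start_threshold : float
        GNSS speed threshold (m/s) defining the precise start; 0.3 m/s.
    eta : float
        Kalman measurement (GNSS) noise η, (m/s)²; default 0.01.
    eta_escalated : float
        η used when the GNSS speed does not look exponential; default 0.1.
    mu : float
        Kalman process (accelerometer) noise μ, (m/s²)²; default 0.4.
    r2_threshold : float
        R² above which the exponential fit counts as good; default 0.91.
    beta : float
        Gradient-descent gain of the orientation filter, rad/s.
    margin : float
        Extra time (s) past the detected end over which the fusion filter is
        run so the distance crossing can be interpolated.
    acc_in_g : bool
        If true, accelerations on disk are in g and converted on load.
    photocell_times : (float, float), optional
        Reference start/finish times (s) from the timing gates.
    """

    distance: float
    mass: float = 75.0
    coarse_start: float = 0.0
    static_window: float = 1.0
    start_threshold: float = 0.3
    eta: float = 0.01
    eta_escalated: float = 0.1
    mu: float = 0.4
    r2_threshold: float = 0.91
    beta: float = 0.1
    margin: float = 0.5
    acc_in_g: bool = False
    photocell_times: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if self.distance <= 0:
            raise ConfigError("distance must be positive")
        if self.mass <= 0:
            raise ConfigError("mass must be positive")
        if not 0 < self.r2_threshold < 1:
            raise ConfigError("r2_threshold must lie in (0, 1)")
        if self.eta <= 0 or self.eta_escalated <= self.eta:
            raise ConfigError("need 0 < eta < eta_escalated")
        if self.mu < 0:
            raise ConfigError("mu must be non-negative")
        if self.photocell_times is not None:
            self.photocell_times = tuple(float(x) for x in self.photocell_times)

    @property
    def photocell_duration(self) -> Optional[float]:
        if self.photocell_times is None:
            return None
        return self.photocell_times[1] - self.photocell_times[0]


def _read_csv(path, columns, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed text
        raise FormatError(f"{what}: cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: {path} is missing column(s) {missing}")
    if len(df) == 0:
        raise EmptySeriesError(f"{what}: {path} has no data rows")
    return df


def read_imu_csv(path, acc_in_g: bool = False) -> ImuRecording:
    """Read an IMU recording (``t,ax,ay,az,gx,gy,gz``).

    The sampling rate is inferred from the median timestep.  Set
    ``acc_in_g`` when the file stores acceleration in units of g.
    """
    df = _read_csv(path, IMU_COLUMNS, "IMU")
    t = df["t"].to_numpy(dtype=float)
    _check_monotone(t, f"IMU file {path}")
    acc = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if acc_in_g:
        acc = acc * GRAVITY
    gyr = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    return ImuRecording(t=t, acc=acc, gyr=gyr, fs=_infer_fs(t))


def read_speed_csv(path, kind: str) -> SpeedSeries:
    """Read a ``t,v`` speed series; ``kind`` is ``"gnss"`` or ``"radar"``."""
    if kind not in ("gnss", "radar"):
        raise ValueError("kind must be 'gnss' or 'radar'")
    df = _read_csv(path, SPEED_COLUMNS, kind.upper())
    t = df["t"].to_numpy(dtype=float)
    v = df["v"].to_numpy(dtype=float)
    _check_monotone(t, f"{kind} file {path}")
    cls = GnssSeries if kind == "gnss" else RadarSeries
    return cls(t=t, v=v, fs=_infer_fs(t))


def write_imu_csv(path, imu: ImuRecording) -> None:
    df = pd.DataFrame(
        np.column_stack([imu.t, imu.acc, imu.gyr]), columns=IMU_COLUMNS
    )
    df.to_csv(path, index=False)


def write_speed_csv(path, series: SpeedSeries) -> None:
    pd.DataFrame({"t": series.t, "v": series.v}).to_csv(path, index=False)


def load_config(path) -> SessionConfig:
    """Load a YAML session config, applying the documented defaults for any
    absent key."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path}: expected key: value mappings")
    known = set(SessionConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"config {path}: unknown key(s) {sorted(unknown)}")
    if "distance" not in raw:
        raise ConfigError(f"config {path}: 'distance' is required")
    return SessionConfig(**raw)


def save_config(path, config: SessionConfig) -> None:
    data = asdict(config)
    if data["photocell_times"] is not None:
        data["photocell_times"] = list(data["photocell_times"])
    else:
        del data["photocell_times"]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_result_csv(path, t, v_est, p) -> None:
    """Write the estimated velocity series as ``t,v_est,p``."""
    pd.DataFrame({"t": t, "v_est": v_est, "p": p}).to_csv(path, index=False)


def write_summary_json(path, summary: dict) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=_default)
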
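"""Sliding-window features from raw 6-axis IMU recordings.

The observation vector is the trailing-window mean and population standard
deviation of each of the six sensor axes (three acceleration, three angular
rate), giving ``w = 12`` features per sample.  The window is causal so the
same features serve batch and on-line recognition, and it shrinks at the
start of the recording so the feature sequence keeps the raw sequence's
length and label alignment.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .inference import ObservationSequence

RAW_COLUMNS = ["ax", "ay", "az", "gx", "gy", "gz"]

#: Feature column order: trailing means of the six axes, then trailing
#: population standard deviations in the same axis order.
FEATURE_COLUMNS = [f"mean_{c}" for c in RAW_COLUMNS] + [f"std_{c}" for c in RAW_COLUMNS]


@dataclasses.dataclass
class RawImuSequence:
    """A raw 6-axis IMU recording.

    ``acc`` is N x 3 acceleration (units recorded free-form in ``acc_units``),
    ``gyr`` is N x 3 angular rate (deg/s), ``rate`` the sampling rate in Hz.
    """

    acc: np.ndarray
    gyr: np.ndarray
    rate: float
    placement: str = ""
    acc_units: str = "m/s^2"

    def __post_init__(self) -> None:
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyr = np.atleast_2d(np.asarray(self.gyr, dtype=float))
        if self.acc.shape != self.gyr.shape or self.acc.shape[1] != 3:
            raise ValueError("acc and gyr must both be N x 3")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not (np.isfinite(self.acc).all() and np.isfinite(self.gyr).all()):
            raise ValueError("raw signals contain non-finite values")

    def __len__(self) -> int:
        return self.acc.shape[0]


def sliding_features(raw: RawImuSequence, window: int) -> ObservationSequence:
    """Trailing mean/std features over ``window`` samples per axis.

    The first ``window - 1`` samples use the available prefix (the window
    shrinks rather than dropping samples).  Standard deviations are
    population (``1/n``) to match the model's biased covariance convention.
    Raises ``ValueError`` for ``window < 2`` or ``window > N``.
    """
    if window < 2:
        raise ValueError("feature window must be >= 2 samples")
    n = len(raw)
    if window > n:
        raise ValueError(f"feature window {window} exceeds sequence length {n}")
    df = pd.DataFrame(np.hstack([raw.acc, raw.gyr]), columns=RAW_COLUMNS)
    roll = df.rolling(window=window, min_periods=1)
    means = roll.mean()
    stds = roll.std(ddof=0).fillna(0.0)
    values = np.hstack([means.to_numpy(), stds.to_numpy()])
    return ObservationSequence(values=values, rate=raw.rate)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def read_raw_csv(path, rate: Optional[float] = None) -> tuple[RawImuSequence, Optional[np.ndarray], Optional[np.ndarray]]:
    """Read a raw recording from CSV with columns ``t, ax..az, gx..gz`` and
    optional ``label`` / ``phase`` columns (1-based in the file).

    The sampling rate is taken from the ``t`` column spacing unless given
    explicitly.  Returns ``(raw, labels, phase_labels)`` with labels 0-based
    or ``None``.
    """
    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"raw CSV lacks columns {missing}")
    if rate is None:
        if "t" not in df.columns or len(df) < 2:
            raise ValueError("cannot infer rate: no usable 't' column")
        dt = np.median(np.diff(df["t"].to_numpy()))
        rate = 1.0 / dt
    raw = RawImuSequence(
        acc=df[["ax", "ay", "az"]].to_numpy(),
        gyr=df[["gx", "gy", "gz"]].to_numpy(),
        rate=float(rate),
    )
    labels = df["label"].to_numpy(dtype=int) - 1 if "label" in df.columns else None
    phases = df["phase"].to_numpy(dtype=int) - 1 if "phase" in df.columns else None
    return raw, labels, phases


def write_raw_csv(
    path,
    raw: RawImuSequence,
    labels: Optional[np.ndarray] = None,
    phase_labels: Optional[np.ndarray] = None,
) -> None:
    """Write a raw recording (and optional 0-based labels, stored 1-based)."""
    n = len(raw)
    data = {"t": np.arange(n) / raw.rate}
    for k, c in enumerate(RAW_COLUMNS[:3]):
        data[c] = raw.acc[:, k]
    for k, c in enumerate(RAW_COLUMNS[3:]):
        data[c] = raw.gyr[:, k]
    if labels is not None:
        data["label"] = np.asarray(labels, dtype=int) + 1
    if phase_labels is not None:
        data["phase"] = np.asarray(phase_labels, dtype=int) + 1
    pd.DataFrame(data).to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class DatasetAdapter:
    """Column mapping and acquisition metadata for an external recording.

    A stub interface only: it renames columns and fixes the sampling rate so
    externally collected CSVs can enter the pipeline; fetching or converting
    datasets is out of scope.
    """

    rate: float
    placement: str
    columns: dict  # maps source column name -> ax..az/gx..gz/t/label

    def load(self, path) -> tuple[RawImuSequence, Optional[np.ndarray], Optional[np.ndarray]]:
        df = pd.read_csv(path).rename(columns=self.columns)
        missing = [c for c in RAW_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"adapter mapping leaves columns {missing} unresolved")
        raw = RawImuSequence(
            acc=df[["ax", "ay", "az"]].to_numpy(),
            gyr=df[["gx", "gy", "gz"]].to_numpy(),
            rate=self.rate, placement=self.placement,
        )
        labels = df["label"].to_numpy(dtype=int) - 1 if "label" in df.columns else None
        phases = df["phase"].to_numpy(dtype=int) - 1 if "phase" in df.columns else None
        return raw, labels, phases


#: Presets for the two acquisition setups the model targets: a thigh-mounted
#: unit sampled at 25 Hz and a foot-mounted unit sampled at 100 Hz.  Adjust
#: ``columns`` to the source file's header.
THIGH_25HZ = DatasetAdapter(rate=25.0, placement="right thigh", columns={})
FOOT_100HZ = DatasetAdapter(rate=100.0, placement="right foot", columns={})


def write_features_csv(path, obs: ObservationSequence) -> None:
    df = pd.DataFrame(obs.values, columns=FEATURE_COLUMNS)
    if obs.labels is not None:
        df["label"] = np.asarray(obs.labels, dtype=int) + 1
    df.to_csv(path, index=False)
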
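"""Subject-level trial data container and its delimited-text dialect.

A :class:`TrialDataset` holds one randomized two-arm trial with competing
causes of death.  Internally it is a struct-of-arrays (numpy) for speed; the
on-disk form is a plain CSV with header ``id,arm,time,status,rec_time``,
status coded ``0=censored, 1=cancer, 2=noncancer, 3=unknown`` and an empty
``rec_time`` when no recurrence was observed before the end of follow-up.
Times are floating point in abstract units (years for real data).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterator, NamedTuple, Optional

import numpy as np
import pandas as pd

__all__ = ["Status", "CONTROL", "TREATED", "SubjectRecord", "TrialDataset",
           "read_dataset", "write_dataset", "ValidationError"]

CONTROL, TREATED = 0, 1
_ARM_LABELS = {CONTROL: "control", TREATED: "treated"}
_ARM_CODES = {v: k for k, v in _ARM_LABELS.items()}


class Status(IntEnum):
    """Cause-coded end-of-follow-up status."""

    CENSORED = 0
    CANCER = 1
    NONCANCER = 2
    UNKNOWN = 3


_STATUS_LABELS = {
    Status.CENSORED: "censored",
    Status.CANCER: "cancer_death",
    Status.NONCANCER: "noncancer_death",
    Status.UNKNOWN: "unknown_death",
}

CAUSE_CODES = {"cancer": int(Status.CANCER), "noncancer": int(Status.NONCANCER)}


class ValidationError(ValueError):
    """A data file (or array set) violates the trial-data contract."""


class SubjectRecord(NamedTuple):
    """One trial participant, in human-readable form."""

    subject_id: int
    arm: str
    time: float
    status: str
    rec_time: Optional[float]


@dataclass
class TrialDataset:
    """One two-arm trial: follow-up times, cause-coded statuses, recurrences.

    Attributes
    ----------
    time : float array, observed follow-up time per subject
    status : int8 array with :class:`Status` codes
    arm : int8 array, 0=control 1=treated
    rec_time : float array; NaN where no recurrence was observed
    subject_id : int array (defaults to 0..n-1)
    config : the simulator scenario that produced the data, if any
    rep_index : replication index within a simulation run, if any
    """

    time: np.ndarray
    status: np.ndarray
    arm: np.ndarray
    rec_time: np.ndarray
    subject_id: Optional[np.ndarray] = None
    config: object = None
    rep_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=np.int8)
        self.arm = np.asarray(self.arm, dtype=np.int8)
        self.rec_time = np.asarray(self.rec_time, dtype=float)
        if self.subject_id is None:
            self.subject_id = np.arange(self.time.size)
        _validate_arrays(self.time, self.status, self.arm, self.rec_time)

    @property
    def n(self) -> int:
        return int(self.time.size)

    def records(self) -> Iterator[SubjectRecord]:
        for i in range(self.n):
            rec = self.rec_time[i]
            yield SubjectRecord(
                subject_id=int(self.subject_id[i]),
                arm=_ARM_LABELS[int(self.arm[i])],
                time=float(self.time[i]),
                status=_STATUS_LABELS[Status(int(self.status[i]))],
                rec_time=None if np.isnan(rec) else float(rec),
            )

    def copy(self) -> "TrialDataset":
        return dataclasses.replace(
            self,
            time=self.time.copy(),
            status=self.status.copy(),
            arm=self.arm.copy(),
            rec_time=self.rec_time.copy(),
            subject_id=self.subject_id.copy(),
        )

    def equals(self, other: "TrialDataset") -> bool:
        return (
            self.n == other.n
            and np.array_equal(self.time, other.time)
            and np.array_equal(self.status, other.status)
            and np.array_equal(self.arm, other.arm)
            and np.array_equal(self.rec_time, other.rec_time, equal_nan=True)
            and np.array_equal(self.subject_id, other.subject_id)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.subject_id,
                "arm": [_ARM_LABELS[int(a)] for a in self.arm],
                "time": self.time,
                "status": self.status.astype(int),
                "rec_time": self.rec_time,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialDataset":
        required = ["id", "arm", "time", "status", "rec_time"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        try:
            arm = np.array([_ARM_CODES[str(a)] for a in frame["arm"]], dtype=np.int8)
        except KeyError as exc:
            raise ValidationError(f"unknown arm label {exc}") from None
        return cls(
            time=frame["time"].to_numpy(dtype=float),
            status=frame["status"].to_numpy(),
            arm=arm,
            rec_time=frame["rec_time"].to_numpy(dtype=float),
            subject_id=frame["id"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialDataset":
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(frame)


def _validate_arrays(time, status, arm, rec_time) -> None:
    n = time.size
    if not (status.size == n and arm.size == n and rec_time.size == n):
        raise ValidationError("column lengths differ")
    if np.any(time < 0) or np.any(np.isnan(time)):
        bad = int(np.flatnonzero((time < 0) | np.isnan(time))[0])
        raise ValidationError(f"row {bad}: negative or missing time")
    valid = np.isin(status, [int(s) for s in Status])
    if not valid.all():
        bad = int(np.flatnonzero(~valid)[0])
        raise ValidationError(f"row {bad}: unknown status code {int(status[bad])}")
    if not np.isin(arm, [CONTROL, TREATED]).all():
        bad = int(np.flatnonzero(~np.isin(arm, [CONTROL, TREATED]))[0])
        raise ValidationError(f"row {bad}: unknown arm code")
    has_rec = ~np.isnan(rec_time)
    late = has_rec & (rec_time > time)
    if late.any():
        bad = int(np.flatnonzero(late)[0])
        raise ValidationError(f"row {bad}: rec_time exceeds follow-up time")
    if has_rec.any() and np.any(rec_time[has_rec] < 0):
        bad = int(np.flatnonzero(has_rec & (rec_time < 0))[0])
        raise ValidationError(f"row {bad}: negative rec_time")


def read_dataset(path) -> TrialDataset:
    """Read a trial CSV, validating every row against the dialect."""
    return TrialDataset.from_csv(path)


def write_dataset(data: TrialDataset, path) -> None:
    """Write a trial to CSV; a read back reproduces it to full precision."""
    data.to_csv(path)
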
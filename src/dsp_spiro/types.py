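"""Domain containers shared across the pipeline.

All times are seconds from session t=0. Breath-phase intervals are half-open
[start, end). Acceleration is in g, audio amplitudes are dimensionless
(full-scale ±1 after PCM16 decoding).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataError, ParameterError

MODES = ("low_effort", "forceful")
ETHNICITIES = ("Asian", "Caucasian", "Southeast Asian", "Other")


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics and reference spirometry for one participant."""

    subject_id: str
    age: float            # years
    sex: str              # {"male", "female"}
    bmi: float            # kg/m^2
    ethnicity: str        # one of ETHNICITIES
    fvc_ref: float        # liters
    fev1_ref: float       # liters
    pef_ref: float        # liters / second

    def __post_init__(self) -> None:
        if self.age <= 0 or self.bmi <= 0:
            raise ParameterError("age and bmi must be positive")
        if not (self.fvc_ref >= self.fev1_ref > 0):
            raise ParameterError("require fvc_ref >= fev1_ref > 0")
        if self.pef_ref <= 0:
            raise ParameterError("pef_ref must be positive")
        if self.sex not in ("male", "female"):
            raise ParameterError(f"unknown sex {self.sex!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ParameterError(f"unknown ethnicity {self.ethnicity!r}")


@dataclass(frozen=True)
class BreathTimeline:
    """Ground-truth breath cycle boundaries for a simulated session.

    Each cycle is (insp_start, exp_start, cycle_end); ``closing_insp_start``
    is the onset of the inhalation that follows the final expiration (the
    validity rule for cycles needs a subsequent inspiration to close the
    last cycle, and a breathing subject always provides one).
    """

    cycles: tuple[tuple[float, float, float], ...]
    mode: str
    duration: float
    closing_insp_start: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"unknown mode {self.mode!r}")
        prev_end = 0.0
        for (t0, t1, t2) in self.cycles:
            if not (t0 < t1 < t2):
                raise DataError("cycle must satisfy insp_start < exp_start < cycle_end")
            if t0 < prev_end:
                raise DataError("cycles must be ordered and non-overlapping")
            if t0 < 0 or t2 > self.duration:
                raise DataError("cycle outside [0, duration]")
            prev_end = t2

    @property
    def insp_starts(self) -> np.ndarray:
        return np.array([c[0] for c in self.cycles])

    @property
    def exp_starts(self) -> np.ndarray:
        return np.array([c[1] for c in self.cycles])

    def event_times(self) -> tuple[np.ndarray, np.ndarray]:
        """(inspiration onsets incl. closing one, expiration onsets)."""
        insp = list(self.insp_starts)
        if self.closing_insp_start is not None:
            insp.append(self.closing_insp_start)
        return np.array(insp), self.exp_starts


@dataclass(frozen=True)
class AudioRecording:
    """Mono audio track; samples dimensionless, t0 in session time."""

    rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ParameterError("audio rate must be positive")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise DataError("audio samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration


@dataclass(frozen=True)
class ImuRecording:
    """Tri-axial accelerometer track on an explicit time grid (seconds, g)."""

    rate: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "ax", "ay", "az"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise DataError("t, ax, ay, az must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise DataError("IMU timestamps must be strictly increasing")
        if self.rate <= 0:
            raise ParameterError("IMU rate must be positive")

    @property
    def t0(self) -> float:
        return float(self.t[0])

    @property
    def t_end(self) -> float:
        return float(self.t[-1])


@dataclass(frozen=True)
class Session:
    """One recording session: time-aligned audio + IMU + subject metadata."""

    subject_id: str
    mode: str
    audio: AudioRecording
    imu: ImuRecording
    profile: SubjectProfile
    annotation: Optional[BreathTimeline] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"unknown mode {self.mode!r}")
        from .errors import AlignmentError

        if self.audio.t_end <= self.imu.t0 or self.imu.t_end <= self.audio.t0:
            raise AlignmentError(
                "audio and IMU streams do not overlap in session time"
            )


@dataclass(frozen=True)
class Envelope:
    """Conditioned low-rate envelope (TSEng or IMU-Z) on a uniform grid."""

    rate: float
    values: np.ndarray
    kind: str  # {"tseng", "imu_z"}
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise DataError("envelope values must be finite")
        if self.kind not in ("tseng", "imu_z"):
            raise ParameterError(f"unknown envelope kind {self.kind!r}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.rate


@dataclass(frozen=True)
class RespiratoryEvent:
    """A labeled phase onset produced by IMU/TSEng association."""

    time: float
    label: str  # {"inspiration_start", "expiration_start"}
    imu_extremum_time: float
    tseng_minimum_time: Optional[float] = None


@dataclass(frozen=True)
class BreathCycle:
    """One valid breath: inspiration [t0,t1) followed by expiration [t1,t2)."""

    insp: tuple[float, float]
    exp: tuple[float, float]

    def __post_init__(self) -> None:
        t0, t1 = self.insp
        t1b, t2 = self.exp
        if t1 != t1b or not (t0 < t1 < t2):
            raise DataError("cycle intervals must chain as t0 < t1 < t2")

    @property
    def insp_duration(self) -> float:
        return self.insp[1] - self.insp[0]

    @property
    def exp_duration(self) -> float:
        return self.exp[1] - self.exp[0]

    @property
    def duration(self) -> float:
        return self.exp[1] - self.insp[0]
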
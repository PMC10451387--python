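"""Core domain types for instrumented-CTSIB balance assessment.

Coordinate convention (used everywhere in the package): ``x`` is the
anterior–posterior (AP) center-of-pressure excursion and ``y`` the
medio-lateral (ML) excursion, both in centimetres, with the origin at the
center of the measurement device.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

import numpy as np

from .errors import EmptyTrialError, EmptyReportError, SamplingError

#: Absolute tolerance on per-step timestamp deviation from 1/fs (seconds).
TIME_TOLERANCE_S = 1e-6


class Condition(str, enum.Enum):
    """The seven CTSIB task conditions.

    Vision is either open (EO) or closed (EC); the support surface is firm,
    one foam pad (foam1) or two foam pads (foam2); ``EO-firm-DC`` adds a
    cognitive dual task (counting down from 50 by 1) on the firm surface.
    """

    EO_FIRM = "EO-firm"
    EO_FIRM_DC = "EO-firm-DC"
    EO_FOAM1 = "EO-foam1"
    EO_FOAM2 = "EO-foam2"
    EC_FIRM = "EC-firm"
    EC_FOAM1 = "EC-foam1"
    EC_FOAM2 = "EC-foam2"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALL_CONDITIONS: tuple[Condition, ...] = tuple(Condition)


@dataclass(frozen=True)
class CopTrial:
    """A uniformly sampled planar center-of-pressure trajectory.

    Parameters
    ----------
    time : np.ndarray
        Sample times in seconds, strictly increasing with uniform step 1/fs.
    x, y : np.ndarray
        AP and ML CoP excursions in cm.
    fs : float
        Sampling rate in Hz.
    condition : Condition
        The CTSIB task condition under which the trial was recorded.
    subject_id : str
        Opaque subject identifier.
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float
    condition: Condition
    subject_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (len(t) == len(x) == len(y)):
            raise SamplingError(
                f"time/x/y lengths differ: {len(t)}/{len(x)}/{len(y)}"
            )
        if len(t) < 2:
            raise EmptyTrialError(f"trial needs at least 2 samples, got {len(t)}")
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise SamplingError(f"sampling rate must be positive, got {self.fs}")
        dt = np.diff(t)
        if np.any(np.abs(dt - 1.0 / self.fs) > TIME_TOLERANCE_S):
            worst = float(np.max(np.abs(dt - 1.0 / self.fs)))
            raise SamplingError(
                f"timestamps deviate from uniform 1/fs grid by up to {worst:.3g} s"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration_s(self) -> float:
        """Time spanned by the samples, (n-1)/fs seconds."""
        return (self.n_samples - 1) / self.fs

    def replace_signal(self, x: np.ndarray, y: np.ndarray) -> "CopTrial":
        """Return a copy of the trial with new x/y signals on the same grid."""
        return CopTrial(self.time, x, y, self.fs, self.condition, self.subject_id)

    @classmethod
    def from_signals(
        cls,
        x: np.ndarray,
        y: np.ndarray,
        fs: float,
        condition: Condition,
        subject_id: str = "",
    ) -> "CopTrial":
        """Build a trial on the canonical grid t_k = k/fs."""
        t = np.arange(len(np.asarray(x))) / fs
        return cls(t, x, y, fs, condition, subject_id)


#: Canonical feature order used in tables, model vectors and exports.
FEATURE_NAMES: tuple[str, ...] = (
    "mean_cm",
    "mean_path_cm_s",
    "mean_velocity_cm_s",
    "mean_distance_cm",
    "mean_acc_cm_s2",
    "ellipse_area_cm2",
    "freq_high5_hz",
    "freq_center_hz",
    "freq_low5_hz",
    "freq_median_hz",
)


@dataclass
class SwayFeatures:
    """The ten CoP sway variables for one trial.

    Time-domain magnitudes are in cm / cm/s / cm/s^2; frequency-domain
    features are in Hz. Frequency features are NaN (flagged missing) when the
    trial has no band power, e.g. a constant input.
    """

    mean_cm: float = math.nan
    mean_path_cm_s: float = math.nan
    mean_velocity_cm_s: float = math.nan
    mean_distance_cm: float = math.nan
    mean_acc_cm_s2: float = math.nan
    ellipse_area_cm2: float = math.nan
    freq_high5_hz: float = math.nan
    freq_center_hz: float = math.nan
    freq_low5_hz: float = math.nan
    freq_median_hz: float = math.nan

    def to_array(self) -> np.ndarray:
        """Feature vector in canonical :data:`FEATURE_NAMES` order."""
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "SwayFeatures":
        return cls(**{name: float(d[name]) for name in FEATURE_NAMES})

    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.to_array())))

    def update(self, other: "SwayFeatures") -> None:
        """Copy the finite fields of ``other`` into this instance."""
        for f in fields(other):
            v = getattr(other, f.name)
            if isinstance(v, float) and math.isfinite(v):
                setattr(self, f.name, v)


@dataclass
class SessionReport:
    """Per-condition stability-index estimates for one i-CTSIB session.

    ``overall_si`` is the arithmetic mean of the per-condition SI values that
    are present; conditions that were requested but could not be scored are
    listed in ``missing_conditions``.
    """

    subject_id: str
    per_condition_si: dict[Condition, float]
    feature_table: dict[Condition, SwayFeatures] = field(default_factory=dict)
    missing_conditions: list[Condition] = field(default_factory=list)
    overall_si: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if not self.per_condition_si:
            raise EmptyReportError("session report has no per-condition SI values")
        for cond, si in self.per_condition_si.items():
            if not (si >= 0):
                raise ValueError(f"SI for {cond} must be >= 0, got {si}")
        mean_si = float(np.mean(list(self.per_condition_si.values())))
        if math.isnan(self.overall_si):
            self.overall_si = mean_si
        elif abs(self.overall_si - mean_si) > 1e-9:
            raise ValueError(
                f"overall_si={self.overall_si} inconsistent with per-condition mean {mean_si}"
            )
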
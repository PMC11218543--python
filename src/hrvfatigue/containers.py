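"""Core data containers shared across the pipeline.

The pipeline moves through three representations of one physiological
signal: the sampled ECG voltage trace (:class:`EcgRecord`), the detected
R-peak sample indices (:class:`BeatSeries`), and the derived interbeat
(RR) interval sequence (:class:`RRSeries`).  Behavioral session data are
carried by :class:`TrialRecord` and :class:`SessionRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

LIMB_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF")

GROUPS = ("blank", "tDCS", "tACS")
STATES = ("pre-fatigue", "post-fatigue", "post-stimulation")

#: refractory bound between R peaks, ms
REFRACTORY_MS = 200.0
#: physiological RR acceptance window used by the artifact filter, ms
RR_MIN_MS = 300.0
RR_MAX_MS = 2000.0


class InvalidSpecError(ValueError):
    """Raised when a generator or detector configuration violates its invariants."""


class InsufficientDataError(ValueError):
    """Raised when an operation receives fewer samples than it needs."""


@dataclass
class EcgRecord:
    """Multi-lead sampled ECG trace.

    Parameters
    ----------
    samples : ndarray, shape (n_leads, n_samples)
        Voltage in microvolts, one row per lead.
    fs : float
        Sampling rate in Hz.
    leads : sequence of str
        Lead labels (limb-lead subset: I, II, III, aVR, aVL, aVF).
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    leads: Sequence[str] = ("II",)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise InvalidSpecError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.leads):
            raise InvalidSpecError(
                f"{self.samples.shape[0]} sample rows for {len(self.leads)} lead labels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise InvalidSpecError("ECG samples contain non-finite values")
        unknown = set(self.leads) - set(LIMB_LEADS)
        if unknown:
            raise InvalidSpecError(f"unknown lead labels: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs

    def lead(self, label: Optional[str] = None) -> np.ndarray:
        """Return one lead's samples; defaults to lead II, else the first lead."""
        if label is None:
            label = "II" if "II" in self.leads else self.leads[0]
        if label not in self.leads:
            raise KeyError(f"lead {label!r} not in record (has {list(self.leads)})")
        return self.samples[list(self.leads).index(label)]

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class BeatSeries:
    """R-peak sample indices at a given sampling rate."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.fs <= 0:
            raise InvalidSpecError(f"sampling rate must be positive, got {self.fs}")
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise InvalidSpecError("beat indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    def times(self) -> np.ndarray:
        """Beat times in seconds."""
        return self.indices / self.fs


@dataclass
class RRSeries:
    """Sequence of interbeat (RR) intervals in milliseconds.

    ``meta`` carries provenance flags set by upstream stages (artifact
    removal counts, quality warnings, generator ground truth).
    """

    intervals: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise InvalidSpecError("RR intervals must be one-dimensional")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise InvalidSpecError("RR intervals must be positive")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def total_time_s(self) -> float:
        """Cumulative time spanned by the intervals, seconds."""
        return float(self.intervals.sum()) / 1000.0

    def beat_times_s(self) -> np.ndarray:
        """Beat times in seconds, with the first beat at t=0."""
        return np.concatenate([[0.0], np.cumsum(self.intervals)]) / 1000.0


@dataclass
class TrialRecord:
    """One trial of the 2-back + parity test task.

    ``rt_ms`` is present iff the participant responded; responses beyond
    the 800 ms inter-stimulus interval cannot occur.
    """

    stimulus: str  # "letter" or "digit"
    correct: bool
    responded: bool
    rt_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.stimulus not in ("letter", "digit"):
            raise InvalidSpecError(f"unknown stimulus kind {self.stimulus!r}")
        if self.responded:
            if self.rt_ms is None or not (0 < self.rt_ms <= 800):
                raise InvalidSpecError("responded trial needs RT in (0, 800] ms")
        elif self.rt_ms is not None:
            raise InvalidSpecError("non-responded trial cannot carry an RT")
        if self.correct and not self.responded:
            raise InvalidSpecError("a non-responded trial cannot be correct")


@dataclass
class SessionRecord:
    """One subject x group x state observation."""

    subject: str
    group: str
    state: str
    sfs_items: Sequence[int] = ()
    trials: Sequence[TrialRecord] = ()
    rr: Optional[RRSeries] = None
    features: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidSpecError(f"unknown group {self.group!r}")
        if self.state not in STATES:
            raise InvalidSpecError(f"unknown state {self.state!r}")
        if self.sfs_items:
            items = list(self.sfs_items)
            if len(items) != 15 or any((i < 0 or i > 4) for i in items):
                raise InvalidSpecError("SFS needs exactly 15 items, each in 0..4")
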
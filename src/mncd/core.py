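"""Domain model for the MNCD classification of Parkinson's disease.

The MNCD state of a patient at one visit is a tuple over four axes:

* **M** — motor symptoms, four binary sub-axes (motor fluctuations,
  dyskinesia, axial symptoms, tremor), each scored 1 when present and
  clinically relevant in the rater's judgment;
* **N** — non-motor symptoms, four binary sub-axes (neuropsychiatric,
  autonomic, sleep/fatigue, pain/sensory);
* **C** — cognition, a single ordinal axis: 0 normal, 1 mild cognitive
  impairment, 2 dementia;
* **D** — dependency for activities of daily living: 0 independent,
  1 dependent for instrumental ADL, 2 dependent for basic ADL.

The subscripts printed next to M and N are *derived* — they are the counts
of positive sub-axes, never independently supplied.  The full state space
has ``2**4 * 2**4 * 3 * 3 == 2304`` distinct states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

__all__ = [
    "MotorFlags",
    "NonMotorFlags",
    "MNCDRecord",
    "ValidationIssue",
    "motor_score",
    "nonmotor_score",
    "validate",
    "iter_state_space",
    "STATE_SPACE_SIZE",
]

#: Number of distinct MNCD states: 16 motor x 16 non-motor x 3 cognition x 3 dependency.
STATE_SPACE_SIZE = 2 ** 4 * 2 ** 4 * 3 * 3

MOTOR_SUBAXES = ("fluctuations", "dyskinesia", "axial", "tremor")
NONMOTOR_SUBAXES = ("neuropsychiatric", "autonomic", "sleep_fatigue", "pain_sensory")


def _check_binary(name: str, value: int) -> None:
    if value not in (0, 1):
        raise ValueError(f"{name} must be 0 or 1, got {value!r}")


@dataclass(frozen=True)
class MotorFlags:
    """Presence/absence flags for the four motor sub-axes.

    Field order matches the printed sub-axis order inside the notation's
    first parenthesized block.
    """

    fluctuations: int = 0
    dyskinesia: int = 0
    axial: int = 0
    tremor: int = 0

    def __post_init__(self) -> None:
        for name in MOTOR_SUBAXES:
            _check_binary(name, getattr(self, name))

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.fluctuations, self.dyskinesia, self.axial, self.tremor)


@dataclass(frozen=True)
class NonMotorFlags:
    """Presence/absence flags for the four non-motor sub-axes."""

    neuropsychiatric: int = 0
    autonomic: int = 0
    sleep_fatigue: int = 0
    pain_sensory: int = 0

    def __post_init__(self) -> None:
        for name in NONMOTOR_SUBAXES:
            _check_binary(name, getattr(self, name))

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.neuropsychiatric, self.autonomic, self.sleep_fatigue, self.pain_sensory)


@dataclass(frozen=True)
class MNCDRecord:
    """One patient-visit's full MNCD state, optionally time-stamped.

    ``years_from_onset`` is a real number of years since motor symptom
    onset (fractional years allowed — a 6-month history is 0.5).  It is
    the value printed after the dash in the notation string.
    """

    motor: MotorFlags = field(default_factory=MotorFlags)
    nonmotor: NonMotorFlags = field(default_factory=NonMotorFlags)
    cognition: int = 0
    dependency: int = 0
    years_from_onset: Optional[float] = None
    patient_id: Optional[str] = None
    visit_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cognition not in (0, 1, 2):
            raise ValueError(f"cognition must be 0, 1 or 2, got {self.cognition!r}")
        if self.dependency not in (0, 1, 2):
            raise ValueError(f"dependency must be 0, 1 or 2, got {self.dependency!r}")
        if self.years_from_onset is not None and self.years_from_onset < 0:
            raise ValueError(
                f"years_from_onset must be non-negative, got {self.years_from_onset!r}"
            )

    def state_tuple(self) -> tuple[tuple[int, ...], tuple[int, ...], int, int]:
        """The pure classification state, ignoring time and identifiers."""
        return (self.motor.as_tuple(), self.nonmotor.as_tuple(), self.cognition, self.dependency)

    def with_time(self, years_from_onset: float) -> "MNCDRecord":
        return replace(self, years_from_onset=years_from_onset)


@dataclass(frozen=True)
class ValidationIssue:
    """A single validation finding; ``severity`` is ``"ERROR"`` or ``"WARNING"``."""

    severity: str
    code: str
    message: str

    def is_error(self) -> bool:
        return self.severity == "ERROR"


def motor_score(flags: MotorFlags) -> int:
    """Motor subscript M: the number of positive motor sub-axes (0-4)."""
    return sum(flags.as_tuple())


def nonmotor_score(flags: NonMotorFlags) -> int:
    """Non-motor subscript N: the number of positive non-motor sub-axes (0-4)."""
    return sum(flags.as_tuple())


def validate(record: MNCDRecord) -> list[ValidationIssue]:
    """Check a record for clinical coherence; never raises, never mutates.

    Range violations cannot normally reach this layer (the dataclasses
    reject them at construction) but are re-checked defensively for records
    built by other means.  The one coherence rule is that dementia (C=2)
    with full ADL independence (D=0) is clinically incoherent — dementia is
    defined by overt functional decline — yet it is reported as a WARNING,
    not an error: rater-entered data is never discarded, and the staging
    function still assigns such states a stage.
    """
    issues: list[ValidationIssue] = []
    for name in MOTOR_SUBAXES:
        v = getattr(record.motor, name)
        if v not in (0, 1):
            issues.append(ValidationIssue("ERROR", "out-of-range", f"motor.{name}={v!r} is not 0/1"))
    for name in NONMOTOR_SUBAXES:
        v = getattr(record.nonmotor, name)
        if v not in (0, 1):
            issues.append(
                ValidationIssue("ERROR", "out-of-range", f"nonmotor.{name}={v!r} is not 0/1")
            )
    if record.cognition not in (0, 1, 2):
        issues.append(
            ValidationIssue("ERROR", "out-of-range", f"cognition={record.cognition!r} is not in 0..2")
        )
    if record.dependency not in (0, 1, 2):
        issues.append(
            ValidationIssue(
                "ERROR", "out-of-range", f"dependency={record.dependency!r} is not in 0..2"
            )
        )
    if record.years_from_onset is not None and record.years_from_onset < 0:
        issues.append(
            ValidationIssue(
                "ERROR", "out-of-range", f"years_from_onset={record.years_from_onset!r} is negative"
            )
        )
    if record.cognition == 2 and record.dependency == 0:
        issues.append(
            ValidationIssue(
                "WARNING",
                "dementia-without-dependency",
                "cognition=2 (dementia) with dependency=0 (full ADL independence) "
                "is clinically incoherent: dementia entails functional decline",
            )
        )
    return issues


def iter_state_space() -> Iterator[MNCDRecord]:
    """Yield all 2304 distinct MNCD states as time-less records.

    Order is deterministic: motor flags as a 4-bit big-endian counter,
    then non-motor, then C, then D (slowest to fastest varying in that
    listing order).
    """
    for m in range(16):
        mf = MotorFlags(*(int(b) for b in f"{m:04b}"))
        for n in range(16):
            nf = NonMotorFlags(*(int(b) for b in f"{n:04b}"))
            for c in range(3):
                for d in range(3):
                    yield MNCDRecord(motor=mf, nonmotor=nf, cognition=c, dependency=d)
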
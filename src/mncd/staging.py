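"""Derivation of the MNCD stage (1-5) from a classification state.

The five stages, in the published rule form:

======  =======================================================
stage   rule
======  =======================================================
1       M = N = 0, C = 0, D = 0 (the all-zero state)
2       M or N >= 1; C = 0; D = 0
3       C = 1 and/or D = 1 (M and N free)
4       D = 2 with C in {0, 1}
5       C = 2 and D = 2
======  =======================================================

The rows overlap (stage 3 admits D=1 while stage 4 requires D=2) and do
not literally cover every state: C=2 with D in {0,1} matches no row, since
the stage-3 narrative says "cognitive impairment (no dementia)".  This
module makes the function total by matching rules top-down from stage 5,
and assigns the uncovered dementia-without-basic-dependency states to
stage 3, flagged ``table3_conformant=False`` with an explanatory note so
the policy is auditable rather than silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import MNCDRecord, iter_state_space, motor_score, nonmotor_score

__all__ = ["MNCDStage", "stage", "enumerate_stage_distribution"]


@dataclass(frozen=True)
class MNCDStage:
    """A derived stage plus its provenance flags.

    ``table3_conformant`` is True when the state matches one of the
    published rule rows literally; when False, ``notes`` explains which
    policy assigned the stage.
    """

    stage: int
    table3_conformant: bool = True
    notes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3, 4, 5):
            raise ValueError(f"stage must be in 1..5, got {self.stage!r}")
        if not self.table3_conformant and not self.notes:
            raise ValueError("non-conformant stage requires an explanatory note")


def stage(record: MNCDRecord) -> MNCDStage:
    """Derive the stage for one record; total on all 2304 valid states.

    Rules are evaluated severity-descending (5 -> 1) and the first match
    wins, which resolves the overlap between the D=1 clause of stage 3 and
    the D=2 requirement of stage 4 deterministically.
    """
    c, d = record.cognition, record.dependency
    if c == 2 and d == 2:
        return MNCDStage(5)
    if d == 2:
        return MNCDStage(4)
    if c == 2:
        # d is 0 or 1 here: dementia without basic-ADL dependency is not
        # covered by any published row; assign stage 3 by policy.
        return MNCDStage(
            3,
            table3_conformant=False,
            notes=(
                f"C=2 with D={d} matches no published stage rule "
                "(stage 3 narrative excludes dementia); assigned stage 3 by policy",
            ),
        )
    if c == 1 or d == 1:
        return MNCDStage(3)
    if motor_score(record.motor) >= 1 or nonmotor_score(record.nonmotor) >= 1:
        return MNCDStage(2)
    return MNCDStage(1)


def enumerate_stage_distribution() -> dict[int, int]:
    """Stage -> count of distinct states, over the full 2304-state space."""
    counts: dict[int, int] = {s: 0 for s in (1, 2, 3, 4, 5)}
    for record in iter_state_space():
        counts[stage(record).stage] += 1
    return counts
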
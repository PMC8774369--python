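"""Trajectory summaries and inter-rater agreement statistics.

Stage-over-time summaries treat the stage as a right-continuous step
function: the classification is defined only at evaluation moments, so the
stage observed at a visit is held constant until the next visit.  Time in
stage therefore sums exactly to the follow-up duration (last minus first
visit time), and the last visit contributes no dwell time.

Agreement statistics support the planned inter-/intra-observer variability
study: observed (raw) agreement and Cohen's kappa, optionally weighted for
ordinal ratings with linear ``1 - |i-j|/(k-1)`` or quadratic
``1 - (i-j)^2/(k-1)^2`` disagreement weights.  With more than two raters,
statistics are averaged over all rater pairs (a pairwise design; Fleiss'
kappa would be the natural extension for a panel design).  When every
rating in the table is one single category, chance agreement equals 1 and
kappa is undefined; it is reported as NaN while observed agreement is
still returned.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .simulate import Trajectory
from .staging import stage as derive_stage

__all__ = [
    "StageTrajectorySummary",
    "AgreementResult",
    "summarize_trajectory",
    "agreement",
    "read_ratings_csv",
]

STAGES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class StageTrajectorySummary:
    """Per-patient stage dynamics.

    ``transition_counts[i, j]`` counts visit-to-visit moves from stage
    ``i+1`` to stage ``j+1``; diagonal entries are stays.  ``regressions``
    counts transitions to a strictly lower stage.
    """

    patient_id: Optional[str]
    times: tuple[float, ...]
    stages: tuple[int, ...]
    time_in_stage: dict[int, float]
    transition_counts: np.ndarray
    regressions: int

    @property
    def follow_up_years(self) -> float:
        return self.times[-1] - self.times[0]


def summarize_trajectory(traj: Trajectory) -> StageTrajectorySummary:
    """Stage sequence, dwell times and transition counts for one patient."""
    if not traj.visits:
        raise ValueError("trajectory has no visits")
    times = tuple(float(v.years_from_onset) for v in traj.visits)
    stages = tuple(derive_stage(v).stage for v in traj.visits)

    time_in_stage = {s: 0.0 for s in STAGES}
    for (t0, t1), s in zip(itertools.pairwise(times), stages):
        time_in_stage[s] += t1 - t0

    counts = np.zeros((5, 5), dtype=int)
    regressions = 0
    for a, b in itertools.pairwise(stages):
        counts[a - 1, b - 1] += 1
        if b < a:
            regressions += 1
    return StageTrajectorySummary(
        patient_id=traj.patient_id,
        times=times,
        stages=stages,
        time_in_stage=time_in_stage,
        transition_counts=counts,
        regressions=regressions,
    )


@dataclass(frozen=True)
class AgreementResult:
    """Observed agreement and kappa statistics over a rater x item table.

    ``cohen_kappa`` is always the unweighted statistic; ``weighted_kappa``
    uses the requested weighting (and equals ``cohen_kappa`` when the
    weighting is "none").  ``kappa_se`` is the large-sample standard error
    of the unweighted kappa (pair-averaged), reported for interval
    construction but not used for any gating here.  ``per_item`` holds, for
    each item, the fraction of rater pairs in exact agreement.
    """

    observed_agreement: float
    cohen_kappa: float
    weighted_kappa: float
    weighting: str
    n_items: int
    n_raters: int
    kappa_se: float = field(default=float("nan"))
    per_item: tuple[float, ...] = field(default=())

    @property
    def kappa_defined(self) -> bool:
        return not math.isnan(self.cohen_kappa)


def _pair_kappa(a: np.ndarray, b: np.ndarray, labels: Sequence,
                weights: Optional[str]) -> float:
    if len(set(a) | set(b)) < 2:
        return float("nan")  # single observed category: chance agreement is 1
    return float(cohen_kappa_score(a, b, labels=list(labels), weights=weights))


def _pair_kappa_se(a: np.ndarray, b: np.ndarray) -> float:
    """Large-sample SE of unweighted kappa: sqrt(po(1-po)/(n(1-pe)^2))."""
    n = len(a)
    po = float(np.mean(a == b))
    cats = sorted(set(a) | set(b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    pe = float(pa @ pb)
    if pe >= 1.0:
        return float("nan")
    return math.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))


def agreement(ratings, weighting: str = "none",
              labels: Optional[Sequence] = None) -> AgreementResult:
    """Agreement statistics for a ratings matrix of shape (raters, items).

    ``ratings`` holds each rater's judgments of the same items on a shared
    ordinal scale (e.g. MNCD stages 1-5, or a sub-axis 0/1).  ``labels``
    fixes the category set for the ordinal weights; by default it is the
    sorted set of observed ratings.  With more than two raters every
    statistic is the average over rater pairs; item order is irrelevant.
    """
    mat = np.asarray(ratings)
    if mat.ndim != 2:
        raise ValueError("ratings must be a 2-D raters x items matrix")
    n_raters, n_items = mat.shape
    if n_raters < 2:
        raise ValueError("agreement requires at least 2 raters")
    if n_items < 1:
        raise ValueError("agreement requires at least 1 item")
    if weighting not in ("none", "linear", "quadratic"):
        raise ValueError(f"weighting must be none/linear/quadratic, got {weighting!r}")
    if labels is None:
        labels = sorted(set(mat.ravel().tolist()))
    sk_weights = {"none": None, "linear": "linear", "quadratic": "quadratic"}[weighting]

    pairs = list(itertools.combinations(range(n_raters), 2))
    po_values, kappas, wkappas, ses = [], [], [], []
    per_item = np.zeros(n_items)
    for i, j in pairs:
        a, b = mat[i], mat[j]
        agree = a == b
        po_values.append(float(np.mean(agree)))
        per_item += agree
        kappas.append(_pair_kappa(a, b, labels, None))
        wkappas.append(_pair_kappa(a, b, labels, sk_weights))
        ses.append(_pair_kappa_se(a, b))
    per_item /= len(pairs)

    return AgreementResult(
        observed_agreement=float(np.mean(po_values)),
        cohen_kappa=float(np.mean(kappas)),
        weighted_kappa=float(np.mean(wkappas)),
        weighting=weighting,
        n_items=n_items,
        n_raters=n_raters,
        kappa_se=float(np.mean(ses)),
        per_item=tuple(per_item.tolist()),
    )


def read_ratings_csv(path) -> tuple[np.ndarray, list, list]:
    """Load a long-format ratings CSV (item_id, rater_id, rating).

    Returns ``(matrix, rater_ids, item_ids)`` with the matrix shaped
    (raters, items); every rater must rate every item exactly once.
    """
    frame = pd.read_csv(Path(path))
    required = {"item_id", "rater_id", "rating"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: ratings CSV needs columns {sorted(required)}")
    pivot = frame.pivot(index="rater_id", columns="item_id", values="rating")
    if pivot.isna().any().any():
        missing = int(pivot.isna().sum().sum())
        raise ValueError(f"{path}: {missing} missing rater x item cells (incomplete design)")
    return pivot.to_numpy(), list(pivot.index), list(pivot.columns)
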
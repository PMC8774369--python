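"""Trajectory summaries and agreement statistics."""

import math

import numpy as np
import pytest

from mncd import (
    MNCDRecord,
    SimulationConfig,
    Trajectory,
    agreement,
    simulate_cohort,
    summarize_trajectory,
)
from mncd.longitudinal import read_ratings_csv
from conftest import TABLE2


def test_single_visit_trajectory_has_stage_sequence_and_no_transitions():
    traj = Trajectory("p1", (MNCDRecord(years_from_onset=0.0, patient_id="p1"),))
    summary = summarize_trajectory(traj)
    assert summary.stages == (1,)
    assert summary.transition_counts.sum() == 0
    assert summary.regressions == 0
    assert all(v == 0.0 for v in summary.time_in_stage.values())


def test_progression_through_published_states():
    """A patient visiting the stage-1, stage-3 and stage-5 worked-example
    states at years 0, 6 and 20 yields stage sequence 1 -> 3 -> 5."""
    visits = tuple(
        TABLE2[i][1].with_time(t) for i, t in [(0, 0.0), (2, 6.0), (4, 20.0)]
    )
    summary = summarize_trajectory(Trajectory("p1", visits))
    assert summary.stages == (1, 3, 5)
    assert summary.regressions == 0
    assert summary.time_in_stage[1] == 6.0
    assert summary.time_in_stage[3] == 14.0
    assert summary.time_in_stage[5] == 0.0  # stage held only until the next visit


def test_time_in_stage_conserved_and_transition_counts_complete():
    config = SimulationConfig(
        n_patients=40, horizon_years=10,
        onset_hazard_per_flag=(0.3,) * 8,
        cognition_progression_hazard=0.15, dependency_progression_hazard=0.2,
        remission_hazards=(0.1,) * 8,
        seed=13,
    )
    for traj in simulate_cohort(config):
        summary = summarize_trajectory(traj)
        assert math.isclose(sum(summary.time_in_stage.values()), summary.follow_up_years)
        assert summary.transition_counts.sum() == len(traj.visits) - 1
        lower = np.tril(summary.transition_counts, k=-1).sum()
        assert summary.regressions == lower


def test_identical_raters_have_perfect_agreement():
    stages = [1, 2, 3, 4, 5]  # the five worked examples rated identically
    result = agreement([stages, stages])
    assert result.observed_agreement == 1.0
    assert result.cohen_kappa == 1.0
    assert result.weighted_kappa == 1.0


def test_independent_uniform_raters_give_chance_level_kappa():
    """Two independent uniform raters over 5 stages: expected agreement is
    1/5 and kappa is 0 within 3 SE at n=10,000."""
    rng = np.random.default_rng(2024)
    n = 10_000
    a = rng.integers(1, 6, size=n)
    b = rng.integers(1, 6, size=n)
    result = agreement([a, b])
    pe = 0.2
    se = math.sqrt(pe * (1 - pe) / n) / (1 - pe)
    assert abs(result.cohen_kappa) < 3 * se
    assert abs(result.observed_agreement - pe) < 3 * math.sqrt(pe * (1 - pe) / n)


def test_null_weighting_equals_unweighted_kappa():
    rng = np.random.default_rng(7)
    ratings = rng.integers(1, 6, size=(2, 200))
    result = agreement(ratings, weighting="none")
    assert result.weighted_kappa == result.cohen_kappa


def test_ordinal_weighting_forgives_near_misses():
    """Off-by-one disagreements hurt weighted kappa less than unweighted."""
    a = np.array([1, 2, 3, 4, 4] * 20)
    b = np.array([2, 1, 3, 5, 4] * 20)  # near misses only
    unweighted = agreement([a, b], weighting="none", labels=[1, 2, 3, 4, 5])
    linear = agreement([a, b], weighting="linear", labels=[1, 2, 3, 4, 5])
    quadratic = agreement([a, b], weighting="quadratic", labels=[1, 2, 3, 4, 5])
    assert unweighted.cohen_kappa < linear.weighted_kappa < quadratic.weighted_kappa


def test_degenerate_single_category_kappa_undefined_agreement_reported():
    result = agreement([[2, 2, 2, 2], [2, 2, 2, 2]])
    assert result.observed_agreement == 1.0
    assert math.isnan(result.cohen_kappa)
    assert not result.kappa_defined


def test_item_permutation_leaves_statistics_unchanged():
    rng = np.random.default_rng(3)
    ratings = rng.integers(1, 6, size=(3, 150))
    perm = rng.permutation(150)
    before = agreement(ratings, weighting="quadratic", labels=[1, 2, 3, 4, 5])
    after = agreement(ratings[:, perm], weighting="quadratic", labels=[1, 2, 3, 4, 5])
    assert math.isclose(before.observed_agreement, after.observed_agreement)
    assert math.isclose(before.cohen_kappa, after.cohen_kappa)
    assert math.isclose(before.weighted_kappa, after.weighted_kappa)


def test_multirater_statistics_are_pairwise_averages():
    a = [1, 2, 3, 4, 5]
    b = [1, 2, 3, 4, 5]
    c = [5, 4, 3, 2, 1]
    three = agreement([a, b, c])
    pair_po = [1.0, 0.2, 0.2]  # (a,b), (a,c), (b,c)
    assert math.isclose(three.observed_agreement, np.mean(pair_po))
    assert three.n_raters == 3 and three.n_items == 5


def test_per_item_agreement_flags_discordant_items():
    result = agreement([[1, 2, 3], [1, 2, 4]])
    assert result.per_item == (1.0, 1.0, 0.0)


@pytest.mark.parametrize("bad", [[[1, 2, 3]], np.zeros((2, 0))])
def test_agreement_rejects_degenerate_shapes(bad):
    with pytest.raises(ValueError):
        agreement(bad)


def test_ratings_csv_long_format_round_trip(tmp_path):
    lines = ["item_id,rater_id,rating"]
    for item in range(1, 6):
        lines.append(f"case{item},raterA,{item}")
        lines.append(f"case{item},raterB,{item}")
    path = tmp_path / "ratings.csv"
    path.write_text("\n".join(lines) + "\n")
    matrix, raters, items = read_ratings_csv(path)
    assert matrix.shape == (2, 5)
    assert raters == ["raterA", "raterB"]
    result = agreement(matrix)
    assert result.cohen_kappa == 1.0


def test_ratings_csv_incomplete_design_rejected(tmp_path):
    path = tmp_path / "ratings.csv"
    path.write_text("item_id,rater_id,rating\ncase1,raterA,1\ncase2,raterA,2\ncase1,raterB,1\n")
    with pytest.raises(ValueError, match="missing"):
        read_ratings_csv(path)
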
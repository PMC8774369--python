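import pytest

from mncd import MNCDRecord, MotorFlags, NonMotorFlags

# The five published worked examples: notation, record, expected stage.
TABLE2 = [
    (
        "M0N0C0D0 (0000/0000/0/0)-5",
        MNCDRecord(MotorFlags(0, 0, 0, 0), NonMotorFlags(0, 0, 0, 0), 0, 0, 5.0),
        1,
    ),
    (
        "M1N0C0D0 (0001/0000/0/0)-2",
        MNCDRecord(MotorFlags(0, 0, 0, 1), NonMotorFlags(0, 0, 0, 0), 0, 0, 2.0),
        2,
    ),
    (
        "M3N1C1D1 (1110/1000/1/1)-6",
        MNCDRecord(MotorFlags(1, 1, 1, 0), NonMotorFlags(1, 0, 0, 0), 1, 1, 6.0),
        3,
    ),
    (
        "M1N3C0D2 (0010/1011/0/2)-4",
        MNCDRecord(MotorFlags(0, 0, 1, 0), NonMotorFlags(1, 0, 1, 1), 0, 2, 4.0),
        4,
    ),
    (
        "M2N3C2D2 (1010/1110/2/2)-20",
        MNCDRecord(MotorFlags(1, 0, 1, 0), NonMotorFlags(1, 1, 1, 0), 2, 2, 20.0),
        5,
    ),
]


@pytest.fixture(scope="session")
def table2_examples():
    return TABLE2


@pytest.fixture
def table2_cohort_csv(tmp_path):
    """The five worked examples transcribed as a cohort CSV file."""
    lines = ["patient_id,years_from_onset,m_fluct,m_dysk,m_axial,m_tremor,"
             "n_neuropsych,n_autonomic,n_sleep_fatigue,n_pain_sensory,cognition,dependency"]
    for i, (_, rec, _) in enumerate(TABLE2, start=1):
        cells = [f"ex{i}", str(rec.years_from_onset)]
        cells += [str(v) for v in rec.motor.as_tuple() + rec.nonmotor.as_tuple()]
        cells += [str(rec.cognition), str(rec.dependency)]
        lines.append(",".join(cells))
    path = tmp_path / "table2.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
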
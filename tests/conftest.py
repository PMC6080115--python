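import pytest
from hypothesis import settings

from cgmtrends import StudyConfig, generate_study, oracle_config

settings.register_profile("suite", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_study():
    """Three participants, full default schedule and noise — enough records
    for every statistic without the full-trial runtime."""
    return generate_study(StudyConfig(n_participants=3, seed=42))


@pytest.fixture(scope="session")
def small_oracle_study():
    """Like small_study but diary arrows equal the realized-rate category."""
    return generate_study(oracle_config(n_participants=3, seed=42))


def study_to_plain(study, system):
    """Convert a study to the plain-tuple layout of the brute-force oracle."""
    diary_rows = [
        (r.participant_id, r.sensor_id, r.time, r.recorded.code)
        for r in study.diary
        if r.system == system
    ]
    samples = {
        sid: list(zip(tr.times.tolist(), tr.values.tolist()))
        for sid, tr in study.traces.items()
    }
    events = [(e.participant_id, e.time) for e in study.events]
    return diary_rows, samples, events
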
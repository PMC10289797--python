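import dataclasses

import pytest

from paniclepheno import (CALIBRATIONS, build_schedule, flag_series,
                          noise_free, panicle_traits, render_detections,
                          simulate_population, track_stream)

STUDY_DAYS = range(58, 72)


@pytest.fixture(scope="session")
def dense_schedule():
    return build_schedule("dense", STUDY_DAYS)


@pytest.fixture(scope="session")
def hourly_schedule():
    return build_schedule("hourly", STUDY_DAYS)


@pytest.fixture(scope="session")
def n300_clean_scene():
    """Noise-free N300 calibration: truth + dense stream, one fixed seed."""
    cfg = dataclasses.replace(noise_free(CALIBRATIONS["N300"]), seed=11)
    truth = simulate_population(cfg)
    schedule = build_schedule("dense", STUDY_DAYS)
    stream = render_detections(truth, schedule, cfg)
    return cfg, truth, stream


@pytest.fixture(scope="session")
def n300_clean_tracks(n300_clean_scene):
    _cfg, _truth, stream = n300_clean_scene
    return [track_stream(stream, d) for d in stream.schedule.days]


@pytest.fixture(scope="session")
def n300_clean_traits(n300_clean_tracks):
    series = flag_series(n300_clean_tracks)
    return {s.panicle_id: panicle_traits(s) for s in series}
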
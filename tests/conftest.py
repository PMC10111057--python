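"""Shared fixtures: representative participants, schedule and templates."""

import numpy as np
import pytest

import tinnerp as t


@pytest.fixture(scope="session")
def tinnitus_participant():
    """A mid-frequency tinnitus patient with mild high-frequency loss."""
    audiogram = t.Audiogram(
        left={125.0: 10, 250.0: 10, 500.0: 15, 1000.0: 20, 2000.0: 30,
              4000.0: 45, 8000.0: 55},
        right={125.0: 10, 250.0: 15, 500.0: 15, 1000.0: 25, 2000.0: 35,
               4000.0: 50, 8000.0: 60},
    )
    profile = t.TinnitusProfile(pitch=4000.0, intensity=45.0, laterality="B",
                                well_identified=True)
    return t.Participant(
        id="T001", condition="tinnitus", age=52.0, sex="F", heart_rate=70.0,
        audiogram=audiogram, tinnitus=profile, group="TRT",
        thi_score={"S0": 44, "Sf": 30},
        hads_anxiety={"S0": 9, "Sf": 7}, hads_stress={"S0": 8, "Sf": 8},
    )


@pytest.fixture(scope="session")
def low_pitch_participant():
    """A low-pitch patient (BBT-eligible)."""
    audiogram = t.Audiogram(
        left={f: 15.0 for f in t.AUDIOGRAM_FREQS},
        right={f: 20.0 for f in t.AUDIOGRAM_FREQS},
    )
    profile = t.TinnitusProfile(pitch=500.0, intensity=30.0, laterality="L")
    return t.Participant(
        id="T002", condition="tinnitus", age=40.0, sex="M", heart_rate=65.0,
        audiogram=audiogram, tinnitus=profile, group="BBT",
        thi_score={"S0": 20, "Sf": 20},
        hads_anxiety={"S0": 5, "Sf": 5}, hads_stress={"S0": 4, "Sf": 6},
    )


@pytest.fixture(scope="session")
def schedule():
    return t.build_schedule()


@pytest.fixture(scope="session")
def tinnitus_template():
    return t.make_template(t.TINNITUS_COMPONENTS)


@pytest.fixture(scope="session")
def small_session(tinnitus_template, schedule):
    """One clean low-noise session reused by read-only tests."""
    rec, truth = t.simulate_session(tinnitus_template, schedule, itc_level=1.0,
                                    noise_sd=3.0, seed=99, artifacts=None)
    return rec, truth


def multichannel_scale(epochs, template, weights_map):
    """Least-squares template scale across all channels, weighted by the map.

    For truth weights w_ch the recovered scale of a perfect average is 1.
    """
    avg = epochs.data.mean(axis=0)
    w = np.array([weights_map[ch] for ch in epochs.channels])
    return float((w @ (avg @ template)) / ((w @ w) * (template @ template)))
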
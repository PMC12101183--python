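import dataclasses

import numpy as np
import pytest

from saccscreen.paradigm import TrialStimulus
from saccscreen.profiles import default_profiles
from saccscreen.simulate import draw_subject_params


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


def make_static_stim(angle_deg=0.0, fixation_ms=1200.0, trial_id=0):
    return TrialStimulus(
        trial_id=trial_id,
        task="static",
        fixation_duration_ms=fixation_ms,
        target_angle_deg=angle_deg,
        eccentricity_deg=10.0,
        speed_deg_s=0.0,
        target_onset_ms=fixation_ms,
        target_visible_ms=1000.0,
    )


def make_moving_stim(angle_deg=0.0, speed=10.0, fixation_ms=1200.0, trial_id=0):
    return TrialStimulus(
        trial_id=trial_id,
        task="moving",
        fixation_duration_ms=fixation_ms,
        target_angle_deg=angle_deg,
        eccentricity_deg=15.0,
        speed_deg_s=speed,
        target_onset_ms=fixation_ms,
        target_visible_ms=3000.0,
        fixation_offset_ms=fixation_ms + 200.0,
    )


def noise_free(params, gain=None, corrective_rate=0.0):
    """Strip all stochastic components from a subject's parameters."""
    return dataclasses.replace(
        params,
        gain=params.gain if gain is None else gain,
        fixation_jitter_sd_deg=0.0,
        within_trial_latency_sd_ms=1e-9,
        endpoint_scatter_sd_deg=0.0,
        corrective_rate=corrective_rate,
        aiming_by_speed={k: (v[0], 0.0, v[2]) for k, v in params.aiming_by_speed.items()},
    )


@pytest.fixture()
def control_subject(profiles):
    return draw_subject_params(profiles["control"], np.random.default_rng(42), "con000")


@pytest.fixture()
def quiet_control_subject(control_subject):
    return noise_free(control_subject)
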
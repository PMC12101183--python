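import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saccscreen.paradigm import target_position
from saccscreen.profiles import default_profiles
from saccscreen.simulate import (
    draw_cohort_params,
    draw_subject_params,
    iter_cohort,
    rice_bias_for_mean,
    rice_mean,
    rice_sigma_for_mean,
    saccade_waveform,
    synth_cohort,
    synth_trial,
)
from tests.conftest import make_moving_stim, make_static_stim, noise_free


# ---------------------------------------------------------------------------
# waveform

@settings(max_examples=50, derandomize=True)
@given(
    amp=st.floats(min_value=0.3, max_value=20.0),
    dur=st.floats(min_value=15.0, max_value=90.0),
    direction=st.floats(min_value=0.0, max_value=360.0),
)
def test_waveform_displacement_conservation(amp, dur, direction):
    """Total displacement equals the requested amplitude within 0.1%."""
    t, dx, dy = saccade_waveform(amp, direction, dur)
    assert np.hypot(dx[-1], dy[-1]) == pytest.approx(amp, rel=1e-3)


@pytest.mark.parametrize(
    "amp,dur,expected_pkv",
    [(9.4, 50.7, 2000 * 9.4 / 50.7), (8.3, 49.4, 2000 * 8.3 / 49.4)],
)
def test_waveform_peak_velocity_main_sequence(amp, dur, expected_pkv):
    """Raised-cosine identity: peak velocity = 2A/D (~371 and ~336 deg/s here)."""
    t, dx, dy = saccade_waveform(amp, 0.0, dur, dt_ms=0.1)
    v = np.diff(dx) / 1e-4  # deg/s at 0.1 ms steps
    assert np.max(np.abs(v)) == pytest.approx(expected_pkv, rel=0.01)
    assert expected_pkv == pytest.approx({9.4: 370.8, 8.3: 336.0}[amp], abs=1.0)


def test_waveform_rejects_bad_inputs():
    with pytest.raises(ValueError):
        saccade_waveform(-1.0, 0.0, 50.0)
    with pytest.raises(ValueError):
        saccade_waveform(5.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Rice helpers

@settings(max_examples=50, derandomize=True)
@given(
    b=st.floats(min_value=0.0, max_value=5.0),
    sigma=st.floats(min_value=0.01, max_value=2.0),
)
def test_rice_mean_matches_monte_carlo(b, sigma):
    rng = np.random.default_rng(0)
    pts = rng.normal([b, 0.0], sigma, size=(40000, 2))
    mc = np.hypot(pts[:, 0], pts[:, 1]).mean()
    assert rice_mean(b, sigma) == pytest.approx(mc, rel=0.02, abs=0.02)


def test_rice_inversions_roundtrip():
    assert rice_mean(1.7, rice_sigma_for_mean(1.7, 1.87)) == pytest.approx(1.87, abs=1e-8)
    assert rice_mean(rice_bias_for_mean(2.4, 0.84), 0.84) == pytest.approx(2.4, abs=1e-8)
    with pytest.raises(ValueError):
        rice_sigma_for_mean(2.0, 1.5)  # mean below bias is unreachable


# ---------------------------------------------------------------------------
# subject draws

def test_latent_factor_extremes(profiles):
    """f=0: traits independent; f=1: deviations perfectly coupled."""
    rng = np.random.default_rng(1)
    p0 = dataclasses.replace(profiles["control"], shared_severity_fraction=0.0)
    p1 = dataclasses.replace(profiles["control"], shared_severity_fraction=1.0)
    lat0, gain0, lat1, pv1 = [], [], [], []
    for _ in range(4000):
        s = draw_subject_params(p0, rng)
        lat0.append(s.static_latency_mean_ms)
        gain0.append(s.gain)
    for _ in range(500):
        s = draw_subject_params(p1, rng)
        lat1.append(s.static_latency_mean_ms)
        pv1.append(s.peakvel_at_group_amp_deg_s)
    assert abs(np.corrcoef(lat0, gain0)[0, 1]) < 0.06
    # opposite loadings: latency up exactly when peak velocity down
    assert np.corrcoef(lat1, pv1)[0, 1] == pytest.approx(-1.0, abs=1e-6)


def test_subject_draw_recovers_profile_moments(profiles):
    """1e4 i.i.d. control subjects reproduce the latency mean and SD within 2%."""
    rng = np.random.default_rng(2)
    prof = profiles["control"]
    lats = [draw_subject_params(prof, rng).static_latency_mean_ms for _ in range(10000)]
    assert np.mean(lats) == pytest.approx(prof.static_latency_mean_ms, rel=0.02)
    assert np.std(lats, ddof=1) == pytest.approx(prof.static_latency_sd_ms, rel=0.02)


def test_moment_matched_cohort_exact_moments(profiles):
    prof = profiles["control"]
    params = draw_cohort_params(prof, 40, np.random.default_rng(3))
    lats = np.array([p.static_latency_mean_ms for p in params])
    assert lats.mean() == pytest.approx(prof.static_latency_mean_ms, abs=1e-6)
    assert lats.std(ddof=1) == pytest.approx(prof.static_latency_sd_ms, abs=1e-6)


def test_group_ordering_of_generating_parameters(profiles):
    con, pre, mod = (profiles[g] for g in ("control", "preperimetric", "moderate"))
    assert con.static_latency_mean_ms < pre.static_latency_mean_ms < mod.static_latency_mean_ms
    assert con.moving_latency_mean_ms < pre.moving_latency_mean_ms < mod.moving_latency_mean_ms
    assert con.endpoint_err_mean_deg < pre.endpoint_err_mean_deg < mod.endpoint_err_mean_deg
    assert con.intercept_err_mean_deg < pre.intercept_err_mean_deg < mod.intercept_err_mean_deg
    assert con.gain_mean > pre.gain_mean > mod.gain_mean
    assert con.peakvel_at_group_amp_deg_s > pre.peakvel_at_group_amp_deg_s > mod.peakvel_at_group_amp_deg_s


def test_cohort_endpoint_mean_hits_group_value_despite_floor(profiles):
    """The hypometria floor plus recalibrated center leaves the cohort mean on target."""
    rng = np.random.default_rng(4)
    prof = profiles["moderate"]
    errs = [draw_subject_params(prof, rng).endpoint_err_mean_deg for _ in range(20000)]
    assert np.mean(errs) == pytest.approx(prof.endpoint_err_mean_deg, abs=0.02)


# ---------------------------------------------------------------------------
# trial synthesis

def test_noise_free_static_trial_lands_on_target(quiet_control_subject):
    subject = dataclasses.replace(quiet_control_subject, gain=1.0)
    stim = make_static_stim(angle_deg=45.0)
    trace, events = synth_trial(stim, subject, np.random.default_rng(0))
    assert len(events) == 1 and events[0].kind == "primary"
    tx, ty = target_position(stim, stim.target_onset_ms)
    assert trace.x_deg[-1] == pytest.approx(tx, abs=1e-9)
    assert trace.y_deg[-1] == pytest.approx(ty, abs=1e-9)


def test_injected_events_conserve_displacement(quiet_control_subject):
    """Trace displacement over each injected saccade equals its amplitude to 0.1%."""
    subject = dataclasses.replace(quiet_control_subject, corrective_rate=3.0)
    rng = np.random.default_rng(1)
    checked = 0
    for angle in (0.0, 90.0, 135.0, 225.0):
        stim = make_static_stim(angle_deg=angle)
        trace, events = synth_trial(stim, subject, rng)
        for ev in events:
            i0 = int(np.floor(ev.onset_ms))
            i1 = int(np.ceil(ev.offset_ms))
            d = np.hypot(
                trace.x_deg[i1] - trace.x_deg[i0], trace.y_deg[i1] - trace.y_deg[i0]
            )
            assert d == pytest.approx(ev.amplitude_deg, rel=1e-3)
            # raised-cosine main-sequence identity V = 2A/D within 1%
            assert ev.peak_velocity_deg_s == pytest.approx(
                2000.0 * ev.amplitude_deg / ev.duration_ms, rel=0.01
            )
            checked += 1
    assert checked >= 3


def test_noise_free_moving_intercept_error_equals_speed_times_lag(quiet_control_subject):
    """With zero scatter the intercept error reduces to v * lag / 1000."""
    for speed in (5.0, 10.0, 15.0):
        stim = make_moving_stim(speed=speed)
        trace, events = synth_trial(stim, quiet_control_subject, np.random.default_rng(2))
        ev = events[0]
        lag_ms, _, _ = quiet_control_subject.aiming_by_speed[speed]
        end = np.array([trace.x_deg[int(ev.offset_ms) + 1], trace.y_deg[int(ev.offset_ms) + 1]])
        target = np.array(target_position(stim, ev.offset_ms))
        err = float(np.hypot(*(end - target)))
        assert err == pytest.approx(speed * lag_ms / 1000.0, abs=0.08)


def test_ground_truth_latency_matches_subject_mean(control_subject):
    """Mean threshold-crossing latency over 500 trials within 3 ms of the draw mean."""
    rng = np.random.default_rng(3)
    stim = make_static_stim()
    lats = []
    for _ in range(500):
        _, events = synth_trial(stim, control_subject, rng)
        up, _ = events[0].threshold_crossings()
        lats.append(up - stim.target_onset_ms)
    assert np.mean(lats) == pytest.approx(control_subject.static_latency_mean_ms, abs=3.0)


# ---------------------------------------------------------------------------
# cohorts

def test_cohort_shape_and_determinism(profiles):
    cohort = synth_cohort(2, profiles, seed=5)
    assert len(cohort) == 6
    assert all(len(s.static_records) == 64 and len(s.moving_records) == 72 for s in cohort)
    again = synth_cohort(2, profiles, seed=5)
    a, b = cohort[3], again[3]
    assert a.params == b.params
    np.testing.assert_array_equal(a.static_records[10][1].x_deg, b.static_records[10][1].x_deg)
    np.testing.assert_array_equal(a.moving_records[7][1].y_deg, b.moving_records[7][1].y_deg)


def test_cohort_rejects_single_subject(profiles):
    with pytest.raises(ValueError):
        synth_cohort(1, profiles, seed=0)


def test_large_cohort_sample_means_preserve_group_ordering(profiles):
    draws = {}
    for g in ("control", "preperimetric", "moderate"):
        params = draw_cohort_params(profiles[g], 200, np.random.default_rng(6))
        draws[g] = params
    lat = {g: np.mean([p.static_latency_mean_ms for p in v]) for g, v in draws.items()}
    gain = {g: np.mean([p.gain for p in v]) for g, v in draws.items()}
    assert lat["control"] < lat["preperimetric"] < lat["moderate"]
    assert gain["control"] > gain["preperimetric"] > gain["moderate"]
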
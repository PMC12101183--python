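"""Ground-truth-annotated synthetic gaze traces.

A subject is a draw from a :class:`~saccscreen.profiles.GroupProfile`: every
group-level mean is realized per subject through a single latent severity
factor z (loading fraction ``shared_severity_fraction``) plus an independent
trait residual.  Deficit traits (latencies, endpoint/intercept error) load
positively on z; gain, peak velocity, visual-field MD and RNFL thickness load
negatively.

Trial traces are built at 1000 Hz as temporally smoothed fixation jitter plus
injected saccades with raised-cosine velocity profiles, for which peak
velocity obeys V = 2A/D exactly.  Saccade kinematics follow a main-sequence
law V(A) = K * A**0.6 with K set so the subject realizes their drawn peak
velocity at the group's mean static amplitude; durations then come out near
50 ms for 8-10 deg saccades, independent of severity.

Two calibration steps keep the generated data on the published group values:

* The injected primary saccade is placed so that its 30 deg/s velocity-threshold
  crossing (the operational saccade onset used throughout the field, and by
  this package's detector) occurs exactly at the drawn latency.
* Landing-point scatter is solved numerically (Rice-mean inversion) so the
  expected Euclidean endpoint/intercept error of each subject equals that
  subject's drawn error mean; for moving targets an aiming lag per speed
  yields the prescribed linear growth of intercept error with target speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from saccscreen.paradigm import (
    TrialStimulus,
    build_moving_session,
    build_static_session,
    target_position,
)
from saccscreen.profiles import GROUPS, Group, GroupProfile

DETECTION_THRESHOLD_DEG_S = 30.0  # operational saccade-onset definition
MAIN_SEQUENCE_EXPONENT = 0.6
LATENCY_FLOOR_MS = 90.0
JITTER_SMOOTHING_SD_MS = 20.0
CORRECTIVE_GAIN = 0.8  # fraction of residual error covered by a corrective
CORRECTIVE_ISI_RANGE_MS = (150.0, 250.0)
MAX_CORRECTIVES = 3
INTERCEPT_SCATTER_FRACTION = 0.35  # isotropic scatter share of intercept error
REFERENCE_SPEED_DEG_S = 10.0


# ---------------------------------------------------------------------------
# Rice-distribution helpers (expected radial error of a biased isotropic
# Gaussian landing point)

def rice_mean(b: float, sigma: float) -> float:
    """Mean of ||N2(bias b, sigma^2 I)|| (Rice distribution mean)."""
    if sigma <= 0:
        return abs(b)
    x = b * b / (2.0 * sigma * sigma)
    return sigma * math.sqrt(math.pi / 2.0) * ((1.0 + x) * i0e(x / 2.0) + x * i1e(x / 2.0))


def rice_sigma_for_mean(b: float, target_mean: float) -> float:
    """Scatter sigma such that the expected radial error equals ``target_mean``.

    Requires ``target_mean`` > |b| (the Rice mean is bounded below by the bias).
    """
    b = abs(b)
    if target_mean <= b:
        raise ValueError("target mean must exceed the bias magnitude")
    lo, hi = 1e-6, 10.0
    while rice_mean(b, hi) < target_mean:  # pragma: no cover - generous bound
        hi *= 2.0
    return brentq(lambda s: rice_mean(b, s) - target_mean, lo, hi, xtol=1e-10)


def rice_bias_for_mean(target_mean: float, sigma: float) -> float:
    """Bias b such that the expected radial error equals ``target_mean``."""
    if rice_mean(0.0, sigma) > target_mean:
        raise ValueError("scatter alone already exceeds the target mean")
    hi = target_mean + 5.0 * sigma
    return brentq(lambda b: rice_mean(b, sigma) - target_mean, 0.0, hi, xtol=1e-10)


@lru_cache(maxsize=64)
def _endpoint_center(
    err_mean: float, err_sd: float, gain_mean: float, gain_sd: float, f: float
) -> float:
    """Center of the subject endpoint-error draw, recalibrated at group level.

    Subjects whose hypometria offset 10*(1-gain) exceeds their drawn error
    mean are floored to the offset (a Rice mean can never be below its bias),
    which would inflate the cohort mean above the published value.  This
    solves for the draw center mu such that E[max(e, b+0.02)] over the joint
    (error, gain) subject distribution equals the published group mean.
    Gauss-Hermite quadrature over the latent factor and both trait residuals.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(21)
    z, u, w = np.meshgrid(nodes, nodes, nodes, indexing="ij")
    wt = (
        weights[:, None, None] * weights[None, :, None] * weights[None, None, :]
    ) / (2.0 * math.pi) ** 1.5
    sf, su = math.sqrt(f), math.sqrt(1.0 - f)
    gain = np.maximum(gain_mean + gain_sd * (-sf * z + su * w), 0.3)
    bias = np.abs(1.0 - gain) * 10.0

    def cohort_mean(mu: float) -> float:
        e = np.maximum(mu + err_sd * (sf * z + su * u), 0.15)
        return float(np.sum(wt * np.maximum(e, bias + 0.02)))

    if cohort_mean(err_mean) <= err_mean + 1e-12:
        return err_mean
    lo = err_mean - 6.0 * err_sd
    return brentq(lambda m: cohort_mean(m) - err_mean, lo, err_mean, xtol=1e-9)


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True)
class GazeTrace:
    """Uniformly sampled 2-D gaze position, 1 ms steps, degrees."""

    subject_id: str
    trial_id: int
    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    sampling_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        if not (len(self.t_ms) == len(self.x_deg) == len(self.y_deg)):
            raise ValueError("trace arrays must have equal length")
        steps = np.diff(self.t_ms)
        if len(steps) and not np.allclose(steps, 1.0):
            raise ValueError("trace must be uniformly sampled at 1 ms")


@dataclass(frozen=True)
class GroundTruthEvent:
    """One injected saccade (simulation sidecar for detector validation).

    ``onset_ms``/``offset_ms`` delimit the full movement (zero-velocity
    endpoints); the 30 deg/s threshold crossings lie inside this interval and
    are exposed by :meth:`threshold_crossings`.
    """

    trial_id: int
    event_index: int
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    kind: Literal["primary", "corrective"]

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")
        if self.amplitude_deg <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    def threshold_crossings(self, threshold_deg_s: float = DETECTION_THRESHOLD_DEG_S):
        """(up, down) times at which the raised-cosine speed crosses threshold."""
        dt = _threshold_crossing_offset_ms(
            self.amplitude_deg, self.duration_ms, threshold_deg_s
        )
        return self.onset_ms + dt, self.offset_ms - dt


@dataclass(frozen=True)
class SubjectParams:
    """Subject-level realization of the group profile."""

    subject_id: str
    group: Group
    latent_severity_z: float
    static_latency_mean_ms: float
    moving_latency_mean_ms: float
    gain: float
    peakvel_scale: float  # K in V(A) = K * A**MAIN_SEQUENCE_EXPONENT
    peakvel_at_group_amp_deg_s: float
    endpoint_err_mean_deg: float
    endpoint_scatter_sd_deg: float
    intercept_err_mean_deg: float  # at 10 deg/s
    aiming_by_speed: dict  # speed -> (lag_ms, scatter_sd_deg, expected_err_deg)
    latency_speed_slope_ms_per_deg_s: float
    corrective_rate: float
    md_db: float
    rnfl_um: float
    within_trial_latency_sd_ms: float
    fixation_jitter_sd_deg: float

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.within_trial_latency_sd_ms <= 0:
            raise ValueError("within-trial latency SD must be positive")

    def peak_velocity(self, amplitude_deg: float) -> float:
        return self.peakvel_scale * amplitude_deg ** MAIN_SEQUENCE_EXPONENT

    def saccade_duration_ms(self, amplitude_deg: float) -> float:
        # V = 2A/D (raised cosine)  =>  D[ms] = 2000 A / V(A)
        return 2000.0 * amplitude_deg / self.peak_velocity(amplitude_deg)


@dataclass
class SubjectData:
    """All simulated material for one subject: schedules, traces, sidecars."""

    params: SubjectParams
    static_trials: list = field(default_factory=list)
    moving_trials: list = field(default_factory=list)
    static_records: list = field(default_factory=list)  # (stim, trace, events)
    moving_records: list = field(default_factory=list)

    def records(self, task: str):
        return self.static_records if task == "static" else self.moving_records


# ---------------------------------------------------------------------------
# Subject draw

#: trait residual order in the subject normal vector (z first)
TRAIT_NAMES = (
    "static_latency", "moving_latency", "gain", "peakvel",
    "endpoint_err", "intercept_err", "md", "rnfl",
)


def params_from_normals(
    profile: GroupProfile,
    z: float,
    eps: dict,
    subject_id: str = "s0",
) -> SubjectParams:
    """Build a subject from a latent severity z and per-trait residuals."""
    f = profile.shared_severity_fraction

    def _trait(mean, sd, loading, name) -> float:
        return mean + sd * (math.sqrt(f) * loading * z + math.sqrt(1.0 - f) * eps[name])

    static_lat = max(120.0, _trait(profile.static_latency_mean_ms, profile.static_latency_sd_ms, +1, "static_latency"))
    moving_lat = max(120.0, _trait(profile.moving_latency_mean_ms, profile.moving_latency_sd_ms, +1, "moving_latency"))
    gain = max(0.3, _trait(profile.gain_mean, profile.gain_sd, -1, "gain"))
    peakvel = max(120.0, _trait(profile.peakvel_at_group_amp_deg_s, profile.peakvel_subject_sd_deg_s, -1, "peakvel"))
    endpoint_center = _endpoint_center(
        profile.endpoint_err_mean_deg,
        profile.endpoint_err_sd_deg,
        profile.gain_mean,
        profile.gain_sd,
        f,
    )
    endpoint_err = max(0.15, _trait(endpoint_center, profile.endpoint_err_sd_deg, +1, "endpoint_err"))
    hypometria_bias = abs(1.0 - gain) * 10.0
    endpoint_err = max(endpoint_err, hypometria_bias + 0.02)
    scatter = rice_sigma_for_mean(hypometria_bias, endpoint_err)
    intercept_err = max(0.2, _trait(profile.intercept_err_mean_deg, profile.intercept_err_sd_deg, +1, "intercept_err"))
    md = _trait(profile.md_mean_db, profile.md_sd_db, -1, "md")
    rnfl = max(20.0, _trait(profile.rnfl_mean_um, profile.rnfl_sd_um, -1, "rnfl"))

    aiming = {}
    for speed in (5.0, 10.0, 15.0):
        expected = max(
            0.12,
            intercept_err
            + profile.intercept_speed_slope_deg_per_deg_s * (speed - REFERENCE_SPEED_DEG_S),
        )
        sigma = INTERCEPT_SCATTER_FRACTION * expected
        bias = rice_bias_for_mean(expected, sigma)
        aiming[speed] = (1000.0 * bias / speed, sigma, expected)

    group_amp = profile.gain_mean * 10.0
    return SubjectParams(
        subject_id=subject_id,
        group=profile.group,
        latent_severity_z=z,
        static_latency_mean_ms=static_lat,
        moving_latency_mean_ms=moving_lat,
        gain=gain,
        peakvel_scale=peakvel / group_amp ** MAIN_SEQUENCE_EXPONENT,
        peakvel_at_group_amp_deg_s=peakvel,
        endpoint_err_mean_deg=endpoint_err,
        endpoint_scatter_sd_deg=scatter,
        intercept_err_mean_deg=intercept_err,
        aiming_by_speed=aiming,
        latency_speed_slope_ms_per_deg_s=profile.latency_speed_slope_ms_per_deg_s,
        corrective_rate=profile.corrective_rate,
        md_db=md,
        rnfl_um=rnfl,
        within_trial_latency_sd_ms=profile.within_trial_latency_sd_ms,
        fixation_jitter_sd_deg=profile.fixation_jitter_sd_deg,
    )


def draw_subject_params(
    profile: GroupProfile, rng: np.random.Generator, subject_id: str = "s0"
) -> SubjectParams:
    """Realize one i.i.d. subject from a group profile (latent-severity model)."""
    z = float(rng.standard_normal())
    eps = {name: float(rng.standard_normal()) for name in TRAIT_NAMES}
    return params_from_normals(profile, z, eps, subject_id)


def draw_cohort_params(
    profile: GroupProfile,
    n_subjects: int,
    rng: np.random.Generator,
    id_prefix: str = "s",
    moment_match: bool = True,
) -> list[SubjectParams]:
    """Draw a group's subjects, optionally with moment-matched variates.

    With ``moment_match`` the latent-severity and trait-residual columns are
    standardized across the cohort (sample mean 0, sample SD 1, ddof = 1), so
    the realized between-subject trait moments equal the profile values
    exactly (up to floor truncations).  Marginal subject distributions are
    unchanged; subjects become weakly exchangeably dependent, as in
    moment-matched simulation designs.  With ``moment_match=False`` subjects
    are i.i.d.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects per group")
    n_cols = 1 + len(TRAIT_NAMES)
    normals = rng.standard_normal((n_subjects, n_cols))
    if moment_match:
        if n_subjects > n_cols + 1:
            # orthonormalize against the intercept and across columns so every
            # column has exact sample mean 0 / SD 1 and zero sample cross-
            # correlation; trait cross-correlations then equal f exactly
            q, r = np.linalg.qr(np.column_stack([np.ones(n_subjects), normals]))
            q = q[:, 1:] * np.sign(np.diag(r)[1:])
            normals = q * math.sqrt(n_subjects - 1)
        else:
            normals = (normals - normals.mean(axis=0)) / normals.std(axis=0, ddof=1)
    out = []
    for i in range(n_subjects):
        z = float(normals[i, 0])
        eps = {name: float(normals[i, 1 + k]) for k, name in enumerate(TRAIT_NAMES)}
        out.append(params_from_normals(profile, z, eps, f"{id_prefix}{i:03d}"))
    return out


# ---------------------------------------------------------------------------
# Saccade waveform

def saccade_waveform(
    amplitude_deg: float, direction_deg: float, duration_ms: float, dt_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raised-cosine saccade: relative times and cumulative (dx, dy).

    Velocity v(t) = (pi A / 2D) ... in closed form the displacement is
    s(t) = A (t/D - sin(2 pi t / D) / (2 pi)), so total displacement is exactly
    A and peak velocity is exactly 2A/D (A in deg, D in seconds).
    """
    if amplitude_deg <= 0 or duration_ms <= 0:
        raise ValueError("amplitude and duration must be positive")
    t = np.arange(dt_ms, duration_ms + dt_ms / 2.0, dt_ms)
    s = amplitude_deg * (t / duration_ms - np.sin(2.0 * math.pi * t / duration_ms) / (2.0 * math.pi))
    th = math.radians(direction_deg)
    return t, s * math.cos(th), s * math.sin(th)


def _displacement_profile(amplitude: float, duration: float, t_rel: np.ndarray) -> np.ndarray:
    """Closed-form raised-cosine displacement at arbitrary relative times."""
    tau = np.clip(t_rel / duration, 0.0, 1.0)
    return amplitude * (tau - np.sin(2.0 * math.pi * tau) / (2.0 * math.pi))


def _threshold_crossing_offset_ms(
    amplitude: float, duration_ms: float, threshold_deg_s: float
) -> float:
    """Time from movement start to the upward threshold crossing."""
    vpk = 2000.0 * amplitude / duration_ms  # deg/s
    if vpk <= threshold_deg_s:
        return duration_ms / 2.0
    arg = 1.0 - 2.0 * threshold_deg_s / vpk
    return duration_ms * math.acos(arg) / (2.0 * math.pi)


# ---------------------------------------------------------------------------
# Trial synthesis

def _fixation_jitter(n: int, sd_deg: float, rng: np.random.Generator) -> np.ndarray:
    """(2, n) smoothed Gaussian fixation jitter with per-axis SD ``sd_deg``."""
    white = rng.standard_normal((2, n))
    smooth = gaussian_filter1d(white, JITTER_SMOOTHING_SD_MS, axis=1, mode="reflect")
    # analytic variance of Gaussian-filtered unit white noise: 1 / (2 sigma sqrt(pi))
    scale = sd_deg * math.sqrt(2.0 * JITTER_SMOOTHING_SD_MS * math.sqrt(math.pi))
    return smooth * scale


def _add_saccade(
    disp: np.ndarray, t: np.ndarray, start_ms: float, vec: np.ndarray, duration_ms: float
) -> None:
    """Add one saccade's displacement (in place) to the (2, n) field."""
    amp = float(np.hypot(*vec))
    i0 = int(np.searchsorted(t, start_ms))
    i1 = int(np.searchsorted(t, start_ms + duration_ms))
    if i0 < len(t):
        seg = _displacement_profile(amp, duration_ms, t[i0:i1] - start_ms) / amp
        disp[:, i0:i1] += vec[:, None] * seg[None, :]
    disp[:, i1:] += vec[:, None]


def synth_trial(
    stim: TrialStimulus,
    subject: SubjectParams,
    rng: np.random.Generator,
    threshold_deg_s: float = DETECTION_THRESHOLD_DEG_S,
) -> tuple[GazeTrace, list[GroundTruthEvent]]:
    """Simulate one trial trace plus its ground-truth event sidecar."""
    n = int(round(stim.trace_end_ms)) + 1
    t = np.arange(n, dtype=float)
    jitter = (
        _fixation_jitter(n, subject.fixation_jitter_sd_deg, rng)
        if subject.fixation_jitter_sd_deg > 0
        else np.zeros((2, n))
    )
    disp = np.zeros((2, n))
    events: list[GroundTruthEvent] = []

    ref = stim.target_onset_ms
    if stim.task == "static":
        lat_mean = subject.static_latency_mean_ms
    else:
        lat_mean = subject.moving_latency_mean_ms + subject.latency_speed_slope_ms_per_deg_s * (
            stim.speed_deg_s - REFERENCE_SPEED_DEG_S
        )
    latency = max(LATENCY_FLOOR_MS, lat_mean + subject.within_trial_latency_sd_ms * rng.standard_normal())

    # landing point of the primary saccade
    if stim.task == "static":
        tx, ty = target_position(stim, ref)
        landing = subject.gain * np.array([tx, ty])
        if subject.endpoint_scatter_sd_deg > 0:
            landing = landing + subject.endpoint_scatter_sd_deg * rng.standard_normal(2)
        amp = float(np.hypot(*landing))
        dur = subject.saccade_duration_ms(amp)
    else:
        lag_ms, sigma, _ = subject.aiming_by_speed[stim.speed_deg_s]
        # completion-time estimate: crossing at ref+latency, then ~one duration
        amp0 = float(np.hypot(*target_position(stim, ref + latency)))
        dur0 = subject.saccade_duration_ms(amp0)
        tc0 = _threshold_crossing_offset_ms(amp0, dur0, threshold_deg_s)
        completion = ref + latency - tc0 + dur0
        # aiming lag: the landing lags the target by lag_ms of its motion,
        # i.e. sits bias = v*lag/1000 deg behind it along the motion axis
        bias = stim.speed_deg_s * lag_ms / 1000.0
        th = math.radians(stim.target_angle_deg)
        outward = np.array([math.cos(th), math.sin(th)])  # opposite to motion
        landing = np.array(target_position(stim, completion)) + bias * outward
        if sigma > 0:
            landing = landing + sigma * rng.standard_normal(2)
        amp = float(np.hypot(*landing))
        dur = subject.saccade_duration_ms(amp)

    vpk = subject.peak_velocity(amp)
    # place the waveform so its threshold crossing lands at ref + latency
    onset = ref + latency - _threshold_crossing_offset_ms(amp, dur, threshold_deg_s)
    _add_saccade(disp, t, onset, landing, dur)
    events.append(
        GroundTruthEvent(
            trial_id=stim.trial_id,
            event_index=0,
            onset_ms=onset,
            offset_ms=onset + dur,
            amplitude_deg=amp,
            peak_velocity_deg_s=vpk,
            kind="primary",
        )
    )

    # corrective saccades toward the (possibly moving) target
    n_corr = min(int(rng.poisson(subject.corrective_rate)), MAX_CORRECTIVES)
    prev_end = onset + dur
    eye = landing.copy()
    for _ in range(n_corr):
        isi = rng.uniform(*CORRECTIVE_ISI_RANGE_MS)
        c_onset = prev_end + isi
        if c_onset + 60.0 > stim.trace_end_ms:
            break
        residual = np.array(target_position(stim, c_onset)) - eye
        c_amp = CORRECTIVE_GAIN * float(np.hypot(*residual))
        if c_amp < 0.25:
            break
        vec = CORRECTIVE_GAIN * residual
        c_dur = subject.saccade_duration_ms(c_amp)
        _add_saccade(disp, t, c_onset, vec, c_dur)
        events.append(
            GroundTruthEvent(
                trial_id=stim.trial_id,
                event_index=len(events),
                onset_ms=c_onset,
                offset_ms=c_onset + c_dur,
                amplitude_deg=c_amp,
                peak_velocity_deg_s=subject.peak_velocity(c_amp),
                kind="corrective",
            )
        )
        prev_end = c_onset + c_dur
        eye = eye + vec

    trace = GazeTrace(
        subject_id=subject.subject_id,
        trial_id=stim.trial_id,
        t_ms=t,
        x_deg=jitter[0] + disp[0],
        y_deg=jitter[1] + disp[1],
    )
    return trace, events


# ---------------------------------------------------------------------------
# Cohort synthesis

def _subject_seed(seed: int, group_index: int, subject_index: int) -> np.random.SeedSequence:
    # counter-based fan-out: adding subjects never perturbs existing ones
    return np.random.SeedSequence(entropy=seed, spawn_key=(group_index, subject_index))


def synth_subject(
    profile: GroupProfile,
    seed_seq: np.random.SeedSequence,
    subject_id: str,
    params: SubjectParams | None = None,
) -> SubjectData:
    """Simulate one subject: parameter draw plus both full sessions."""
    s_params, s_static, s_moving, s_trials = seed_seq.spawn(4)
    if params is None:
        params = draw_subject_params(profile, np.random.default_rng(s_params), subject_id)
    static_trials = build_static_session(s_static)
    moving_trials = build_moving_session(s_moving)
    rng = np.random.default_rng(s_trials)
    data = SubjectData(params=params, static_trials=static_trials, moving_trials=moving_trials)
    for stim in static_trials:
        data.static_records.append((stim, *synth_trial(stim, params, rng)))
    for stim in moving_trials:
        data.moving_records.append((stim, *synth_trial(stim, params, rng)))
    return data


def iter_cohort(
    n_per_group: int,
    profiles: dict[Group, GroupProfile] | None = None,
    seed: int = 0,
    moment_match: bool = True,
) -> Iterator[SubjectData]:
    """Stream subjects of a cohort one at a time (memory-friendly).

    Subject parameters are drawn per group with moment matching by default
    (see :func:`draw_cohort_params`); session schedules and trial noise use
    per-subject counter-based seed streams.
    """
    from saccscreen.profiles import default_profiles

    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    profiles = profiles or default_profiles()
    for gi, group in enumerate(GROUPS):
        group_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(gi, 1 << 20))
        )
        params_list = draw_cohort_params(
            profiles[group], n_per_group, group_rng,
            id_prefix=group[:3], moment_match=moment_match,
        )
        for si, params in enumerate(params_list):
            yield synth_subject(
                profiles[group],
                _subject_seed(seed, gi, si),
                subject_id=params.subject_id,
                params=params,
            )


def synth_cohort(
    n_per_group: int,
    profiles: dict[Group, GroupProfile] | None = None,
    seed: int = 0,
    moment_match: bool = True,
) -> list[SubjectData]:
    """Materialize a full cohort (use :func:`iter_cohort` for large n)."""
    return list(iter_cohort(n_per_group, profiles, seed, moment_match))
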
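"""Group-level generative profiles for the three study cohorts.

Each :class:`GroupProfile` holds the population parameters of one cohort
(control, preperimetric POAG, moderate POAG): task latencies, static-task gain
and peak velocity, endpoint and intercept accuracy, the speed dependence of
latency and intercept error, corrective-saccade propensity, and the clinical
covariates (visual-field mean deviation, RNFL thickness).  Means and SDs are
between-subject parameters of subject-level means.

The default profiles carry the published group values for the static task
(latency 221/237/256 ms, gain 0.94/0.91/0.83, peak velocity 371/352/336 deg/s,
endpoint error 1.14/1.42/1.87 deg), the moving task (latency 234/271/312 ms,
intercept error 1.95/2.78/3.64 deg at the 10 deg/s reference speed) and the
clinic (MD -0.23/-0.87/-8.56 dB, RNFL 96.2/82.7/68.3 um).

A single latent severity factor with loading fraction
``shared_severity_fraction`` couples a subject's deficits across traits;
deficit traits (latencies, errors) load positively, gain, peak velocity, MD
and RNFL negatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import yaml

Group = Literal["control", "preperimetric", "moderate"]
GROUPS: tuple[Group, ...] = ("control", "preperimetric", "moderate")

#: latent-severity loading fraction shared by the default profiles; calibrated
#: once against the published multi-parameter AUCs (see docs/methods.md)
SHARED_SEVERITY_FRACTION = 0.2


@dataclass
class GroupProfile:
    group: Group
    static_latency_mean_ms: float
    static_latency_sd_ms: float
    moving_latency_mean_ms: float
    moving_latency_sd_ms: float
    gain_mean: float
    gain_sd: float
    peakvel_at_group_amp_deg_s: float
    peakvel_subject_sd_deg_s: float
    endpoint_err_mean_deg: float
    endpoint_err_sd_deg: float
    intercept_err_mean_deg: float  # at the 10 deg/s reference speed
    intercept_err_sd_deg: float
    latency_speed_slope_ms_per_deg_s: float = -1.5
    intercept_speed_slope_deg_per_deg_s: float = 0.1
    corrective_rate: float = 0.5  # expected corrective saccades per trial
    shared_severity_fraction: float = SHARED_SEVERITY_FRACTION
    md_mean_db: float = 0.0
    md_sd_db: float = 1.0
    rnfl_mean_um: float = 95.0
    rnfl_sd_um: float = 7.0
    # within-subject nuisance parameters (identical across default groups)
    within_trial_latency_sd_ms: float = 25.0
    fixation_jitter_sd_deg: float = 0.08

    def __post_init__(self) -> None:
        for name in (
            "static_latency_sd_ms",
            "moving_latency_sd_ms",
            "gain_sd",
            "peakvel_subject_sd_deg_s",
            "endpoint_err_sd_deg",
            "intercept_err_sd_deg",
            "md_sd_db",
            "rnfl_sd_um",
            "within_trial_latency_sd_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.gain_mean <= 1.2:
            raise ValueError("gain_mean must be in (0, 1.2]")
        if not 0.0 <= self.shared_severity_fraction <= 1.0:
            raise ValueError("shared_severity_fraction must be in [0, 1]")
        if not 0.0 <= self.corrective_rate <= 3.0:
            raise ValueError("corrective_rate must be in [0, 3]")


def default_profiles() -> dict[Group, GroupProfile]:
    """The published-value calibration of the three cohorts."""
    return {
        "control": GroupProfile(
            group="control",
            static_latency_mean_ms=221.0,
            static_latency_sd_ms=24.0,
            moving_latency_mean_ms=234.0,
            moving_latency_sd_ms=29.0,
            gain_mean=0.94,
            gain_sd=0.06,
            peakvel_at_group_amp_deg_s=371.0,
            peakvel_subject_sd_deg_s=38.0,
            endpoint_err_mean_deg=1.14,
            endpoint_err_sd_deg=0.43,
            intercept_err_mean_deg=1.95,
            intercept_err_sd_deg=0.67,
            latency_speed_slope_ms_per_deg_s=-2.2,
            intercept_speed_slope_deg_per_deg_s=0.05,
            corrective_rate=0.3,
            md_mean_db=-0.23,
            md_sd_db=0.79,
            rnfl_mean_um=96.2,
            rnfl_sd_um=6.8,
        ),
        "preperimetric": GroupProfile(
            group="preperimetric",
            static_latency_mean_ms=237.0,
            static_latency_sd_ms=28.0,
            moving_latency_mean_ms=271.0,
            moving_latency_sd_ms=35.0,
            gain_mean=0.91,
            gain_sd=0.07,
            peakvel_at_group_amp_deg_s=352.0,
            peakvel_subject_sd_deg_s=43.0,
            endpoint_err_mean_deg=1.42,
            endpoint_err_sd_deg=0.52,
            intercept_err_mean_deg=2.78,
            intercept_err_sd_deg=0.93,
            latency_speed_slope_ms_per_deg_s=-1.5,
            intercept_speed_slope_deg_per_deg_s=0.135,
            corrective_rate=0.7,
            md_mean_db=-0.87,
            md_sd_db=0.93,
            rnfl_mean_um=82.7,
            rnfl_sd_um=7.3,
        ),
        "moderate": GroupProfile(
            group="moderate",
            static_latency_mean_ms=256.0,
            static_latency_sd_ms=31.0,
            moving_latency_mean_ms=312.0,
            moving_latency_sd_ms=43.0,
            gain_mean=0.83,
            gain_sd=0.09,
            peakvel_at_group_amp_deg_s=336.0,
            peakvel_subject_sd_deg_s=41.0,
            endpoint_err_mean_deg=1.87,
            endpoint_err_sd_deg=0.68,
            intercept_err_mean_deg=3.64,
            intercept_err_sd_deg=1.12,
            latency_speed_slope_ms_per_deg_s=-0.8,
            intercept_speed_slope_deg_per_deg_s=0.24,
            corrective_rate=1.4,
            md_mean_db=-8.56,
            md_sd_db=2.31,
            rnfl_mean_um=68.3,
            rnfl_sd_um=9.1,
        ),
    }


def profiles_to_yaml(profiles: dict[Group, GroupProfile]) -> str:
    return yaml.safe_dump({g: asdict(p) for g, p in profiles.items()}, sort_keys=False)


def profiles_from_yaml(text: str) -> dict[Group, GroupProfile]:
    raw = yaml.safe_load(text)
    return {g: GroupProfile(**vals) for g, vals in raw.items()}
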
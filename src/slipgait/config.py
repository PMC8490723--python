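"""Study configuration: belt protocol, generator calibration, analysis settings.

All tunable parameters of the simulated study and of the analysis pipeline
live here, with the defaults the package ships.  Configs round-trip through
plain dicts (and hence YAML/JSON) unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "BeltProtocol",
    "GeneratorConfig",
    "AnalysisConfig",
    "StudyConfig",
    "load_config",
    "dump_config",
]


@dataclass
class BeltProtocol:
    """Commanded treadmill-belt perturbation: a triangular speed bump on the
    belt under the perturbed foot, starting and ending at fixed fractions of
    that foot's stance phase.

    The ramp-up and ramp-down slopes both equal ``acceleration`` so the speed
    profile is an isosceles triangle peaking midway between onset and
    recovery.
    """

    nominal_speed: float = 1.2  # m/s
    acceleration: float = 5.0  # m/s^2
    onset_pct_stance: float = 20.0  # % stance at which the belt accelerates
    recovery_pct_stance: float = 70.0  # % stance at which speed is nominal again
    n_slips: int = 10
    washout_steps: int = 4  # unlabelled lead-in steps before Pre2

    def __post_init__(self) -> None:
        if self.nominal_speed <= 0:
            raise ValueError("nominal_speed must be positive")
        if self.acceleration < 0:
            raise ValueError("acceleration must be non-negative")
        if not (0 < self.onset_pct_stance < self.recovery_pct_stance <= 100):
            raise ValueError(
                "require 0 < onset_pct_stance < recovery_pct_stance <= 100"
            )
        if self.n_slips < 1:
            raise ValueError("n_slips must be >= 1")


@dataclass
class GeneratorConfig:
    """Calibration of the synthetic perturbed-gait generator.

    The step-to-step balance model imposes, for recovery step k of slip s,

        MoS(s, k) = baseline + anticipation(s)
                    - A1 * rate**(s-1) * exp(-(k-1)/tau) + noise

    with anticipation(s) = gain * (1 - exp(-(s-1)/anticipation_tau_slips)).
    The shipped amplitude/rate values were calibrated (seeded search against
    the cohort-mean targets 4.6 cm Normal, 2.8 cm Slip01 Rec6, 2.0 cm Slip03
    Rec1) and are not free knobs.
    """

    n_ya: int = 17
    n_oa: int = 17

    # acquisition / timing
    marker_rate: float = 120.0  # Hz
    force_rate: float = 300.0  # Hz (treadmill force plates)
    step_time: float = 0.55  # s between consecutive heel strikes
    stance_time: float = 0.70  # s, normal stance duration
    pert_stance_time: float = 0.65  # s, quicker stance on the perturbed step
    n_recovery_steps: int = 15
    n_normal_steps: int = 16  # heel strikes in the unperturbed trial

    # cohort anthropometry (cm / kg; group mean and SD)
    ya_height_mean: float = 176.1
    ya_height_sd: float = 8.1
    ya_mass_mean: float = 71.8
    ya_mass_sd: float = 10.1
    ya_age_mean: float = 25.2
    ya_age_sd: float = 3.7
    oa_height_mean: float = 161.8
    oa_height_sd: float = 7.2
    oa_mass_mean: float = 66.5
    oa_mass_sd: float = 11.3
    oa_age_mean: float = 62.4
    oa_age_sd: float = 6.6

    # balance model (cm unless stated)
    baseline_mos_mean: float = 4.6
    baseline_mos_between_sd: float = 1.0  # between-participant SD of the mean
    mos_noise_sd_mean: float = 1.3  # mean within-participant step-to-step SD
    mos_noise_sd_sd: float = 0.5
    mos_noise_sd_min: float = 0.4
    mos_noise_sd_max: float = 3.1
    recovery_amplitude_mean: float = 6.0428  # A1, calibrated
    recovery_amplitude_loading: float = 1.5  # cm per unit latent proficiency
    recovery_amplitude_min: float = 0.5
    recovery_tau_mean: float = 4.0  # steps
    recovery_tau_sd: float = 0.4
    recovery_tau_loading: float = 0.8  # steps per unit latent proficiency
    adaptation_rate: float = 0.7147  # calibrated, per slip
    anticipation_gain_mean: float = 1.0
    anticipation_gain_sd: float = 0.3
    anticipation_tau_slips: float = 3.0

    # temporo-spatial / kinetic deviations (fractions of normal)
    pert_step_lengthening: float = 0.08  # maintained across slips
    rec1_step_shortening: float = 0.21  # decays with adaptation_rate
    rec1_knee_gain: float = 2.0  # +200% extensor peak, decays
    rec1_ankle_deficit: float = 0.25  # -25% push-off peak, decays
    pert_ankle_deficit: float = 0.12  # push-off deficit on the slipped foot
    theta_mid_shift_deg: float = -4.0  # GRF angle, mid-stance, all slips
    theta_push_shift_deg: float = 3.0  # GRF angle, push-off, all slips
    proficiency_theta_loading: float = 0.2
    step_len_noise_pctbh: float = 1.0
    scale_noise_sd: float = 0.05
    waveform_noise_sd: float = 0.06  # per-step template-amplitude variability
    moment_additive_sd: float = 0.05  # N.m/kg, smooth per-step moment noise
    theta_additive_sd: float = 0.8  # deg, smooth per-step GRF-angle noise
    noise_scale: float = 1.0  # global multiplier; 0 -> deterministic trials

    # waveform templates
    grf_peak_bw: float = 1.1  # vertical GRF hump peaks, body weights
    grf_valley_bw: float = 0.75
    grf_contact_floor_n: float = 30.0  # vertical force pedestal during stance
    theta_amplitude_deg: float = 8.0  # normal braking/propulsion GRF angle
    ankle_peak_nmkg: float = 1.4
    ankle_peak_oa_deficit: float = 0.15
    knee_ext_peak_nmkg: float = 0.5
    knee_flex_peak_nmkg: float = 0.3
    hip_ext_peak_nmkg: float = 0.8
    hip_flex_peak_nmkg: float = 0.8
    toe_offset_m: float = 0.12  # second-toe marker ahead of foot CoM


@dataclass
class AnalysisConfig:
    """Settings of the analysis pipeline applied to any trial, synthetic or
    imported."""

    filter_cutoff_hz: float = 8.0
    filter_order: int = 4
    event_threshold_n: float = 20.0
    event_min_contact_s: float = 0.05
    gravity: float = 9.81  # m/s^2
    leg_length_factor: float = 0.53  # leg length as fraction of body height
    n_baseline_cycles: int = 5
    baseline_skip_steps: int = 2  # warm-up steps ignored in the Normal trial
    spm_alpha: float = 0.0056  # nine-contrast family
    n_permutations: int = 1000
    alpha_nsteps_posthoc: float = 0.0011  # 45 pairwise slip comparisons
    alpha_pre_posthoc: float = 0.0063
    alpha_mos_anova: float = 0.005  # analysis repeated per slip
    alpha_scalar_posthoc: float = 0.0056
    normality_alpha: float = 0.05


@dataclass
class StudyConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    protocol: BeltProtocol = field(default_factory=BeltProtocol)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        return cls(
            generator=GeneratorConfig(**d.get("generator", {})),
            protocol=BeltProtocol(**d.get("protocol", {})),
            analysis=AnalysisConfig(**d.get("analysis", {})),
            seed=int(d.get("seed", 0)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str) -> StudyConfig:
    with open(path) as fh:
        return StudyConfig.from_dict(yaml.safe_load(fh) or {})


def dump_config(config: StudyConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
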
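"""Synthetic perturbed-treadmill-gait generator.

Emulates a repeated backward-slip protocol: participants walk at a fixed
belt speed, and on each of ten slip trials the belt under one foot briefly
accelerates during stance, displacing the stance foot backwards and
depressing the margin of stability (MoS) of the following steps.  Balance
recovers exponentially over the recovery steps, the disturbance amplitude
shrinks across slips (adaptation), and the pre-slip MoS rises with exposure
(anticipation).

The generator imposes per-step targets — MoS at heel strike, step length,
ground-reaction-force (GRF) angle and joint-moment deviations — and then
reconstructs marker and force channels that are *consistent* with those
targets: running the analysis pipeline on an emitted trial recovers the
imposed numbers.  The reconstruction works backwards from the definition of
the extrapolated centre of mass (XCoM): a target XCoM trajectory is
interpolated through the per-heel-strike constraints and the CoM position is
obtained by integrating x' = omega0 * (XCoM - x), which makes
x + x'/omega0 equal the target identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.interpolate import BPoly, CubicSpline

from .config import BeltProtocol, GeneratorConfig, StudyConfig

__all__ = [
    "ParticipantProfile",
    "TrialTimeSeries",
    "StudyDataset",
    "make_cohort",
    "belt_speed_profile",
    "simulate_trial",
    "simulate_study",
    "recovery_mos_model",
]

SIDES = ("left", "right")


@dataclass
class ParticipantProfile:
    """Latent description of one synthetic participant.

    ``proficiency`` is a standard-normal latent factor with signed loadings
    onto the recovery amplitude, step-length and GRF-angle deviations; it is
    the single source of the between-participant couplings the correlation
    analysis measures.
    """

    id: str
    age_group: str  # "YA" | "OA"
    age: float  # years
    height: float  # m
    mass: float  # kg
    perturbed_side: str  # "left" | "right"
    baseline_mos_mean: float  # cm
    baseline_mos_sd: float  # cm, step-to-step variability
    proficiency: float
    recovery_amplitude: float  # A1, cm
    recovery_tau: float  # steps
    adaptation_rate: float  # per slip, in (0, 1]
    anticipation_gain: float  # cm

    def __post_init__(self) -> None:
        if self.height <= 0 or self.mass <= 0:
            raise ValueError("height and mass must be positive")
        if self.baseline_mos_sd <= 0:
            raise ValueError("baseline_mos_sd must be positive")
        if self.recovery_tau <= 0:
            raise ValueError("recovery_tau must be positive")
        if not (0 < self.adaptation_rate <= 1):
            raise ValueError("adaptation_rate must be in (0, 1]")
        if self.age_group not in ("YA", "OA"):
            raise ValueError("age_group must be 'YA' or 'OA'")
        if self.perturbed_side not in SIDES:
            raise ValueError("perturbed_side must be 'left' or 'right'")


@dataclass
class TrialTimeSeries:
    """All channels of one walking trial.

    Marker-clock channels (``marker_rate``): CoM and per-side foot-CoM /
    second-toe AP positions, joint moments.  Force-clock channels
    (``force_rate``): per-side GRF components and belt speed.  The
    ``annotations`` dict records the imposed per-step targets and the event
    schedule, so that round-trip tests can compare pipeline output against
    the generator's intent.
    """

    participant: str
    slip_index: int  # 0 = unperturbed Normal trial
    marker_rate: float
    force_rate: float
    time_marker: np.ndarray
    time_force: np.ndarray
    com_ap: np.ndarray
    com_vert: np.ndarray
    foot_com_ap: dict[str, np.ndarray]
    toe2_ap: dict[str, np.ndarray]
    moment_hip: dict[str, np.ndarray]
    moment_knee: dict[str, np.ndarray]
    moment_ankle: dict[str, np.ndarray]
    grf_ap: dict[str, np.ndarray]
    grf_vert: dict[str, np.ndarray]
    belt_speed: dict[str, np.ndarray]
    pert_hs_time: float | None = None
    annotations: dict[str, Any] = field(default_factory=dict)


@dataclass
class StudyDataset:
    participants: list[ParticipantProfile]
    trials: dict[tuple[str, int], TrialTimeSeries]
    config_echo: dict[str, Any]
    seed: int


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Draw by rejection from N(mean, sd) restricted to [lo, hi]."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
    return out


def make_cohort(
    n_ya: int, n_oa: int, seed: int, config: GeneratorConfig | None = None
) -> list[ParticipantProfile]:
    """Draw a cohort of synthetic participants.

    Heights and masses follow the per-group means and SDs of the emulated
    study; the balance parameters are drawn around the calibrated defaults,
    coupled through a single latent proficiency factor.
    """
    if n_ya < 0 or n_oa < 0 or n_ya + n_oa < 1:
        raise ValueError("need at least one participant and non-negative counts")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0C0]))

    profiles: list[ParticipantProfile] = []
    groups = [("YA", n_ya)] + [("OA", n_oa)]
    idx = 0
    for group, n in groups:
        if group == "YA":
            h_m, h_s = cfg.ya_height_mean, cfg.ya_height_sd
            m_m, m_s = cfg.ya_mass_mean, cfg.ya_mass_sd
            a_m, a_s = cfg.ya_age_mean, cfg.ya_age_sd
        else:
            h_m, h_s = cfg.oa_height_mean, cfg.oa_height_sd
            m_m, m_s = cfg.oa_mass_mean, cfg.oa_mass_sd
            a_m, a_s = cfg.oa_age_mean, cfg.oa_age_sd
        for _ in range(n):
            idx += 1
            z = rng.normal()
            amp = max(
                cfg.recovery_amplitude_min,
                cfg.recovery_amplitude_mean - cfg.recovery_amplitude_loading * z,
            )
            profiles.append(
                ParticipantProfile(
                    id=f"P{idx:02d}",
                    age_group=group,
                    age=float(_truncated_normal(rng, a_m, a_s, 18.0, 90.0)),
                    height=float(_truncated_normal(rng, h_m, h_s, 120.0, 220.0))
                    / 100.0,
                    mass=float(_truncated_normal(rng, m_m, m_s, 35.0, 150.0)),
                    perturbed_side=SIDES[int(rng.integers(2))],
                    baseline_mos_mean=float(
                        rng.normal(cfg.baseline_mos_mean, cfg.baseline_mos_between_sd)
                    ),
                    baseline_mos_sd=float(
                        _truncated_normal(
                            rng,
                            cfg.mos_noise_sd_mean,
                            cfg.mos_noise_sd_sd,
                            cfg.mos_noise_sd_min,
                            cfg.mos_noise_sd_max,
                        )
                    ),
                    proficiency=float(z),
                    recovery_amplitude=float(amp),
                    recovery_tau=float(
                        _truncated_normal(
                            rng,
                            cfg.recovery_tau_mean - cfg.recovery_tau_loading * z,
                            cfg.recovery_tau_sd,
                            1.0,
                            12.0,
                        )
                    ),
                    adaptation_rate=float(cfg.adaptation_rate),
                    anticipation_gain=float(
                        max(0.0, rng.normal(cfg.anticipation_gain_mean,
                                            cfg.anticipation_gain_sd))
                    ),
                )
            )
    return profiles


def belt_speed_profile(
    protocol: BeltProtocol, stance_duration: float, rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Belt speed over one stance phase: nominal with a triangular bump.

    Returns (time, speed).  The speed ramps up at ``+acceleration`` from the
    onset instant and back down at the same rate, reaching nominal exactly at
    the recovery instant, so the peak is nominal + acceleration * half-width.
    """
    if stance_duration <= 0:
        raise ValueError("stance_duration must be positive")
    if protocol.recovery_pct_stance <= protocol.onset_pct_stance:
        raise ValueError("recovery_pct_stance must exceed onset_pct_stance")
    t = np.arange(0.0, stance_duration, 1.0 / rate)
    t1 = protocol.onset_pct_stance / 100.0 * stance_duration
    t2 = protocol.recovery_pct_stance / 100.0 * stance_duration
    half = 0.5 * (t2 - t1)
    tri = np.clip(half - np.abs(t - (t1 + half)), 0.0, None)
    speed = protocol.nominal_speed + protocol.acceleration * tri * (
        (t >= t1) & (t <= t2)
    )
    return t, speed


def _belt_speed_fn(protocol: BeltProtocol, episode: tuple[float, float] | None):
    """Continuous belt speed of one belt as a function of absolute time."""
    v0 = protocol.nominal_speed
    if episode is None:
        return lambda t: v0 * np.ones_like(np.asarray(t, dtype=float))
    t1, t2 = episode
    half = 0.5 * (t2 - t1)

    def fn(t):
        t = np.asarray(t, dtype=float)
        tri = np.clip(half - np.abs(t - (t1 + half)), 0.0, None)
        return v0 + protocol.acceleration * tri * ((t >= t1) & (t <= t2))

    return fn


def _belt_displacement(fn, t_a: float, t_b: float, n: int = 201) -> float:
    ts = np.linspace(t_a, t_b, n)
    return float(np.trapezoid(fn(ts), ts))


class _BeltDisplacement:
    """Cumulative belt displacement, precomputed on a dense grid so that
    per-sample evaluation is a cheap interpolation (the speed profile is
    piecewise linear, so trapezoid integration is essentially exact)."""

    def __init__(self, speed_fn, t_min: float, t_max: float, rate: float = 1200.0):
        self._t = np.arange(t_min, t_max + 1.0 / rate, 1.0 / rate)
        v = speed_fn(self._t)
        self._cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(self._t))]
        )

    def cumulative(self, t):
        return np.interp(t, self._t, self._cum)

    def between(self, t_a, t_b):
        return self.cumulative(t_b) - self.cumulative(t_a)


def recovery_mos_model(
    profile: ParticipantProfile,
    slip_index: int,
    step_k: np.ndarray | int,
    anticipation_tau_slips: float = 3.0,
) -> np.ndarray:
    """Expected MoS (cm) of recovery step k (1-based) after slip s.

    baseline + anticipation(s) - A1 * rate**(s-1) * exp(-(k-1)/tau).
    """
    s = slip_index
    k = np.asarray(step_k, dtype=float)
    ant = profile.anticipation_gain * (
        1.0 - np.exp(-(s - 1) / anticipation_tau_slips)
    )
    deficit = (
        profile.recovery_amplitude
        * profile.adaptation_rate ** (s - 1)
        * np.exp(-(k - 1.0) / profile.recovery_tau)
    )
    return profile.baseline_mos_mean + ant - deficit


# ---------------------------------------------------------------------------
# waveform templates (unit stance fraction u in [0, 1])

def _vert_grf_template(u, peak_bw, valley_bw):
    """Double-hump vertical GRF in body weights; peaks near 25/75 % stance."""
    c_sum = valley_bw  # value at u = 0.5
    c_dif = peak_bw / np.sin(np.pi * 0.25) - c_sum  # fixes the 25 % peak
    c0 = 0.5 * (c_sum + c_dif)
    c1 = 0.5 * (c_dif - c_sum)
    return c0 * np.sin(np.pi * u) - c1 * np.sin(3.0 * np.pi * u)


def _bump(u, centre, width):
    return np.exp(-(((u - centre) / width) ** 2))


def _ankle_template(u):
    """Monotone rise to a push-off peak at 75 % stance, normalised to 1."""
    return (u**3) * (1.0 - u) / (0.75**3 * 0.25)


def _knee_template(u, ext_peak, flex_peak):
    return ext_peak * _bump(u, 0.15, 0.09) - flex_peak * _bump(u, 0.55, 0.18)


def _hip_template(u, ext_peak, flex_peak):
    return ext_peak * _bump(u, 0.10, 0.10) - flex_peak * _bump(u, 0.85, 0.10)


def _theta_template(u, amplitude_deg):
    """Normal GRF angle over stance: posterior braking then anterior push."""
    return -amplitude_deg * np.sin(2.0 * np.pi * u)


def _additive(u, coefs):
    """Smooth per-step waveform disturbance: offset plus two broad lobes."""
    if coefs is None:
        return 0.0
    e0, e1, e2 = coefs
    return e0 + e1 * _bump(u, 0.30, 0.22) + e2 * _bump(u, 0.75, 0.20)


# ---------------------------------------------------------------------------

@dataclass
class _StepPlan:
    index: int
    time: float  # heel-strike time
    side: str
    stance: float
    label: str | None
    mos_cm: float
    step_len_pctbh: float
    theta_mid_deg: float
    theta_push_deg: float
    ankle_scale: float
    knee_ext_scale: float
    wf: dict | None = None  # per-step template-amplitude multipliers


def _plan_steps(
    profile: ParticipantProfile,
    protocol: BeltProtocol,
    cfg: GeneratorConfig,
    slip_index: int,
    rng: np.random.Generator,
) -> list[_StepPlan]:
    """Lay out heel strikes, labels and per-step targets for one trial."""
    s = slip_index
    nz = cfg.noise_scale
    ant = (
        profile.anticipation_gain
        * (1.0 - np.exp(-(s - 1) / cfg.anticipation_tau_slips))
        if s >= 1
        else 0.0
    )
    decay = profile.adaptation_rate ** (s - 1) if s >= 1 else 0.0
    amp_rel = profile.recovery_amplitude / cfg.recovery_amplitude_mean
    z = profile.proficiency

    normal_len_pctbh = 100.0 * protocol.nominal_speed * cfg.step_time / profile.height

    if s == 0:
        labels: list[str | None] = [None] * 2 + [
            f"Normal{i + 1:02d}" for i in range(cfg.n_normal_steps)
        ]
    else:
        labels = (
            [None] * protocol.washout_steps
            + ["Pre2", "Pre1", "Pert"]
            + [f"Rec{k}" for k in range(1, cfg.n_recovery_steps + 1)]
        )
    # parity: Pert (and Pre2) fall on the perturbed side
    if s >= 1:
        i_pert = labels.index("Pert")
    else:
        i_pert = 0
    other = "left" if profile.perturbed_side == "right" else "right"

    plans: list[_StepPlan] = []
    for i, label in enumerate(labels):
        t_hs = 0.5 + i * cfg.step_time
        side = profile.perturbed_side if (i - i_pert) % 2 == 0 else other
        stance = (
            cfg.pert_stance_time if (s >= 1 and label == "Pert") else cfg.stance_time
        )

        # --- MoS target ---
        noise = rng.normal(0.0, profile.baseline_mos_sd) * nz
        if s == 0:
            mos = profile.baseline_mos_mean + noise
        elif label is not None and label.startswith("Rec"):
            k = int(label[3:])
            mos = float(recovery_mos_model(
                profile, s, k, cfg.anticipation_tau_slips)) + noise
        else:
            # lead-in, Pre2/Pre1 and Pert heel strike precede the disturbance
            mos = profile.baseline_mos_mean + ant + noise
        # --- step length target (% body height) ---
        length = normal_len_pctbh + rng.normal(0.0, cfg.step_len_noise_pctbh) * nz
        theta_mid = 0.0
        theta_push = 0.0
        ankle_scale = 1.0
        knee_scale = 1.0
        if s >= 1 and label == "Pert":
            length *= 1.0 + cfg.pert_step_lengthening * (
                1.0 + cfg.proficiency_theta_loading * z
            ) * (1.0 + rng.normal(0.0, cfg.scale_noise_sd) * nz)
            theta_mid = cfg.theta_mid_shift_deg * (
                1.0 + cfg.proficiency_theta_loading * z
            ) * (1.0 + rng.normal(0.0, cfg.scale_noise_sd) * nz)
            theta_push = cfg.theta_push_shift_deg * (
                1.0 + cfg.proficiency_theta_loading * z
            ) * (1.0 + rng.normal(0.0, cfg.scale_noise_sd) * nz)
            ankle_scale = 1.0 - cfg.pert_ankle_deficit * amp_rel * decay * (
                1.0 + rng.normal(0.0, cfg.scale_noise_sd) * nz
            )
        elif s >= 1 and label == "Rec1":
            length *= 1.0 - cfg.rec1_step_shortening * amp_rel * decay * (
                1.0 + rng.normal(0.0, cfg.scale_noise_sd) * nz
            )
            ankle_scale = 1.0 - cfg.rec1_ankle_deficit * amp_rel * decay * (
                1.0 + rng.normal(0.0, cfg.scale_noise_sd) * nz
            )
            knee_scale = 1.0 + cfg.rec1_knee_gain * amp_rel * decay * (
                1.0 + rng.normal(0.0, cfg.scale_noise_sd) * nz
            )
        wf = {
            key: 1.0 + rng.normal(0.0, cfg.waveform_noise_sd) * nz
            for key in ("theta_amp", "ankle", "knee_ext", "knee_flex",
                        "hip_ext", "hip_flex")
        }
        # smooth additive waveform variability: offset + two mid-stance lobes
        wf["theta_add"] = (
            rng.normal(0.0, cfg.theta_additive_sd, size=3)
            * np.array([0.5, 1.0, 1.0]) * nz
        )
        for key in ("ankle_add", "knee_add", "hip_add"):
            wf[key] = (
                rng.normal(0.0, cfg.moment_additive_sd, size=3)
                * np.array([0.5, 1.0, 1.0]) * nz
            )
        plans.append(
            _StepPlan(
                index=i,
                time=t_hs,
                side=side,
                stance=stance,
                label=label,
                mos_cm=mos,
                step_len_pctbh=length,
                theta_mid_deg=theta_mid,
                theta_push_deg=theta_push,
                ankle_scale=ankle_scale,
                knee_ext_scale=knee_scale,
                wf=wf,
            )
        )
    return plans


def simulate_trial(
    profile: ParticipantProfile,
    protocol: BeltProtocol,
    slip_index: int,
    seed: int,
    config: GeneratorConfig | None = None,
    leg_length_factor: float = 0.53,
    gravity: float = 9.81,
) -> TrialTimeSeries:
    """Synthesize one trial (Normal if ``slip_index`` is 0, else one slip).

    The per-step targets are drawn first, then marker and force channels are
    reconstructed so that the analysis pipeline recovers those targets: foot
    positions satisfy the step-length recursion on the moving belts, and the
    CoM satisfies the XCoM constraint at every heel strike.
    """
    if not (0 <= slip_index <= protocol.n_slips):
        raise ValueError(f"slip_index must be in 0..{protocol.n_slips}")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), slip_index]))

    plans = _plan_steps(profile, protocol, cfg, slip_index, rng)

    # --- belt episodes -----------------------------------------------------
    pert_plan = next((p for p in plans if p.label == "Pert"), None)
    episode = None
    if pert_plan is not None:
        t1 = pert_plan.time + protocol.onset_pct_stance / 100.0 * pert_plan.stance
        t2 = pert_plan.time + protocol.recovery_pct_stance / 100.0 * pert_plan.stance
        episode = (t1, t2)
    belt = {
        side: _belt_speed_fn(
            protocol, episode if side == profile.perturbed_side else None
        )
        for side in SIDES
    }
    t_lo = plans[0].time - 2.0 * cfg.step_time - 0.2
    t_hi = plans[-1].time + 2.0 * cfg.step_time + cfg.stance_time + 0.2
    disp = {side: _BeltDisplacement(belt[side], t_lo, t_hi) for side in SIDES}

    # --- extend with virtual lead-in / tail steps so trajectories cover the
    # emitted window (these carry baseline targets and no labels) -----------
    step_time = cfg.step_time
    head = []
    for j in (2, 1):
        head.append(
            _StepPlan(
                index=-j,
                time=plans[0].time - j * step_time,
                side=plans[0].side if j % 2 == 0 else plans[1].side,
                stance=cfg.stance_time,
                label=None,
                mos_cm=profile.baseline_mos_mean,
                step_len_pctbh=100.0 * protocol.nominal_speed * step_time
                / profile.height,
                theta_mid_deg=0.0,
                theta_push_deg=0.0,
                ankle_scale=1.0,
                knee_ext_scale=1.0,
            )
        )
    tail = []
    for j in (1, 2):
        tail.append(
            _StepPlan(
                index=plans[-1].index + j,
                time=plans[-1].time + j * step_time,
                side=plans[-1].side if j % 2 == 0 else plans[-2].side,
                stance=cfg.stance_time,
                label=None,
                mos_cm=plans[-1].mos_cm,
                step_len_pctbh=100.0 * protocol.nominal_speed * step_time
                / profile.height,
                theta_mid_deg=0.0,
                theta_push_deg=0.0,
                ankle_scale=1.0,
                knee_ext_scale=1.0,
            )
        )
    allsteps = head + plans + tail

    # --- foot-placement recursion ------------------------------------------
    positions = np.empty(len(allsteps))
    positions[0] = 0.0
    for n in range(1, len(allsteps)):
        prev, cur = allsteps[n - 1], allsteps[n]
        trail_at_hs = positions[n - 1] - float(
            disp[prev.side].between(prev.time, cur.time)
        )
        positions[n] = trail_at_hs + cur.step_len_pctbh / 100.0 * profile.height

    # --- per-side foot trajectories ----------------------------------------
    t_end = plans[-1].time + cfg.stance_time + 0.05
    time_m = np.arange(0.0, t_end, 1.0 / cfg.marker_rate)
    time_f = np.arange(0.0, t_end, 1.0 / cfg.force_rate)

    foot = {}
    for side in SIDES:
        own = [(p, positions[i]) for i, p in enumerate(allsteps) if p.side == side]
        x = np.full_like(time_m, np.nan)
        for j, (p, pos) in enumerate(own):
            t_to = p.time + p.stance
            in_stance = (time_m >= p.time) & (time_m < t_to)
            if np.any(in_stance):
                ts = time_m[in_stance]
                x[in_stance] = pos - disp[side].between(p.time, ts)
            if j + 1 < len(own):
                nxt, nxt_pos = own[j + 1]
                # swing polynomial matched to the stance kinematics up to the
                # 4th derivative, so the 8 Hz filter leaves heel-strike
                # positions essentially untouched
                x_to = pos - float(disp[side].between(p.time, t_to))
                v_to = -float(belt[side](t_to))
                v_hs = -float(belt[side](nxt.time))
                poly = BPoly.from_derivatives(
                    [t_to, nxt.time],
                    [[x_to, v_to, 0.0, 0.0, 0.0],
                     [nxt_pos, v_hs, 0.0, 0.0, 0.0]],
                )
                in_swing = (time_m >= t_to) & (time_m < nxt.time)
                x[in_swing] = poly(time_m[in_swing])
        # before first own stance / after last own stance: hold smoothly
        first_t, first_pos = own[0][0].time, own[0][1]
        x[time_m < first_t] = first_pos + (
            first_t - time_m[time_m < first_t]
        ) * float(belt[side](first_t))
        last_p, last_pos = own[-1]
        after = time_m >= last_p.time + last_p.stance
        if np.any(after):
            x_to = last_pos - float(
                disp[side].between(last_p.time, last_p.time + last_p.stance)
            )
            x[after] = x_to - (
                time_m[after] - (last_p.time + last_p.stance)
            ) * float(belt[side](last_p.time))
        foot[side] = x
    toe2 = {side: foot[side] + cfg.toe_offset_m for side in SIDES}

    # --- CoM from the XCoM constraint --------------------------------------
    leg = leg_length_factor * profile.height
    omega0 = np.sqrt(gravity / leg)
    hs_times = np.array([p.time for p in allsteps])
    x_targets = np.array(
        [
            positions[i] + cfg.toe_offset_m - p.mos_cm / 100.0
            for i, p in enumerate(allsteps)
        ]
    )
    xspline = CubicSpline(hs_times, x_targets, bc_type="natural")

    def x_target(t):
        return xspline(np.clip(t, hs_times[0], hs_times[-1]))

    com = np.empty_like(time_m)
    xcom_t = x_target(time_m)
    com[0] = xcom_t[0]
    h = 1.0 / cfg.marker_rate
    decay_f = np.exp(-omega0 * h)
    for i in range(1, len(time_m)):
        a = xcom_t[i - 1]
        b = (xcom_t[i] - xcom_t[i - 1]) / h
        # exact solution of x' = omega0 (X - x) for X linear on [t_{i-1}, t_i]
        com[i] = (
            com[i - 1] * decay_f
            + a * (1.0 - decay_f)
            + b * (h - (1.0 - decay_f) / omega0)
        )
    com_vert = 0.55 * profile.height + 0.015 * np.sin(
        2.0 * np.pi * time_m / (2.0 * step_time)
    )

    # --- force-plate and moment channels ------------------------------------
    bw = profile.mass * gravity
    grf_vert = {side: np.zeros_like(time_f) for side in SIDES}
    grf_ap = {side: np.zeros_like(time_f) for side in SIDES}
    ankle_peak = cfg.ankle_peak_nmkg - (
        cfg.ankle_peak_oa_deficit if profile.age_group == "OA" else 0.0
    )
    mom = {
        name: {side: np.zeros_like(time_m) for side in SIDES}
        for name in ("hip", "knee", "ankle")
    }
    for i, p in enumerate(allsteps):
        wf = p.wf or {}
        t_to = p.time + p.stance
        mask_f = (time_f >= p.time) & (time_f < t_to)
        u = (time_f[mask_f] - p.time) / p.stance
        v = np.maximum(
            _vert_grf_template(u, cfg.grf_peak_bw, cfg.grf_valley_bw) * bw,
            cfg.grf_contact_floor_n,
        )
        theta = (
            _theta_template(u, cfg.theta_amplitude_deg * wf.get("theta_amp", 1.0))
            + p.theta_mid_deg * _bump(u, 0.40, 0.16)
            + p.theta_push_deg * _bump(u, 0.80, 0.08)
            + _additive(u, wf.get("theta_add"))
        )
        grf_vert[p.side][mask_f] += v
        grf_ap[p.side][mask_f] += v * np.tan(np.deg2rad(theta))

        mask_m = (time_m >= p.time) & (time_m < t_to)
        um = (time_m[mask_m] - p.time) / p.stance
        mom["ankle"][p.side][mask_m] += (
            ankle_peak * p.ankle_scale * wf.get("ankle", 1.0)
            * _ankle_template(um)
        ) + _additive(um, wf.get("ankle_add"))
        mom["knee"][p.side][mask_m] += _knee_template(
            um,
            cfg.knee_ext_peak_nmkg * p.knee_ext_scale * wf.get("knee_ext", 1.0),
            cfg.knee_flex_peak_nmkg * wf.get("knee_flex", 1.0),
        ) + _additive(um, wf.get("knee_add"))
        mom["hip"][p.side][mask_m] += _hip_template(
            um,
            cfg.hip_ext_peak_nmkg * wf.get("hip_ext", 1.0),
            cfg.hip_flex_peak_nmkg * wf.get("hip_flex", 1.0),
        ) + _additive(um, wf.get("hip_add"))

    belt_series = {side: belt[side](time_f) for side in SIDES}

    annotations = {
        "steps": [
            {
                "label": p.label,
                "time": p.time,
                "side": p.side,
                "stance": p.stance,
                "mos_cm": p.mos_cm,
                "step_len_pctbh": p.step_len_pctbh,
                "ankle_scale": p.ankle_scale,
                "knee_ext_scale": p.knee_ext_scale,
            }
            for p in plans
        ],
        "omega0": float(omega0),
        "leg_length_factor": leg_length_factor,
        "episode": list(episode) if episode else None,
    }
    return TrialTimeSeries(
        participant=profile.id,
        slip_index=slip_index,
        marker_rate=cfg.marker_rate,
        force_rate=cfg.force_rate,
        time_marker=time_m,
        time_force=time_f,
        com_ap=com,
        com_vert=com_vert,
        foot_com_ap=foot,
        toe2_ap=toe2,
        moment_hip=mom["hip"],
        moment_knee=mom["knee"],
        moment_ankle=mom["ankle"],
        grf_ap=grf_ap,
        grf_vert=grf_vert,
        belt_speed=belt_series,
        pert_hs_time=pert_plan.time if pert_plan is not None else None,
        annotations=annotations,
    )


def simulate_study(config: StudyConfig, seed: int | None = None) -> StudyDataset:
    """Simulate the full study: a cohort, one Normal trial and ``n_slips``
    slip trials per participant.

    Per-participant sub-seeds are drawn from ``SeedSequence(seed)`` in cohort
    order, so the dataset is bit-reproducible under a fixed seed.
    """
    seed = config.seed if seed is None else int(seed)
    gcfg, protocol = config.generator, config.protocol
    profiles = make_cohort(gcfg.n_ya, gcfg.n_oa, seed, gcfg)
    ss = np.random.SeedSequence([int(seed), 0x51EED])
    sub = ss.generate_state(len(profiles)) % (2**31 - 1)
    trials: dict[tuple[str, int], TrialTimeSeries] = {}
    for profile, sub_seed in zip(profiles, sub):
        for s in range(0, protocol.n_slips + 1):
            trials[(profile.id, s)] = simulate_trial(
                profile,
                protocol,
                s,
                int(sub_seed),
                gcfg,
                leg_length_factor=config.analysis.leg_length_factor,
                gravity=config.analysis.gravity,
            )
    return StudyDataset(
        participants=profiles,
        trials=trials,
        config_echo=config.to_dict(),
        seed=seed,
    )
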
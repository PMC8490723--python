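"""Balance and temporo-spatial outcomes per step.

The margin of stability (MoS) follows the inverted-pendulum construction:
the extrapolated centre of mass XCoM = x + v / omega0, with eigenfrequency
omega0 = sqrt(g / l) for pendulum length l, is compared with the anterior
boundary of the base of support (second-toe marker of the leading foot) at
heel strike.  Positive MoS means the XCoM is behind the boundary — the
walker is dynamically stable in the anterior-posterior sense.

``n_steps`` is the recovery criterion: the first of at least three
consecutive recovery steps whose MoS lies within one standard deviation of
the participant's unperturbed baseline; 16 when never reached by Rec15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BaselineStats",
    "RecoveryOutcome",
    "xcom",
    "margin_of_stability",
    "step_length_pct",
    "grf_angle",
    "baseline_stats",
    "n_steps",
    "CAPPED_N_STEPS",
]

CAPPED_N_STEPS = 16


@dataclass
class BaselineStats:
    mos_mean: float  # cm
    mos_sd: float  # cm
    n_cycles: int


@dataclass
class RecoveryOutcome:
    slip_index: int
    n_steps: int
    capped: bool


def xcom(com_ap, com_ap_vel, omega0: float):
    """Extrapolated centre of mass: x + v / omega0 (same units as x)."""
    if omega0 <= 0:
        raise ValueError("omega0 must be positive")
    return np.asarray(com_ap) + np.asarray(com_ap_vel) / omega0


def margin_of_stability(toe2_ap_lead, xcom_ap):
    """MoS in cm: (anterior BoS boundary - XCoM) * 100, positive = stable."""
    return (np.asarray(toe2_ap_lead) - np.asarray(xcom_ap)) * 100.0


def step_length_pct(lead_foot_com_ap, trail_foot_com_ap, height: float):
    """Step length in % body height at heel strike of the leading foot."""
    if height <= 0:
        raise ValueError("height must be positive")
    return 100.0 * (np.asarray(lead_foot_com_ap) - np.asarray(trail_foot_com_ap)) / height


def grf_angle(grf_ap, grf_vert):
    """Sagittal GRF angle to the vertical in degrees, positive = anterior.

    atan(F_ap / F_vert); samples with non-positive vertical force are
    undefined and returned as NaN (masked nodes).
    """
    ap = np.asarray(grf_ap, dtype=float)
    v = np.asarray(grf_vert, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.degrees(np.arctan(ap / v))
    return np.where(v > 0, out, np.nan)


def baseline_stats(mos_cycles) -> BaselineStats:
    """Mean and sample SD of per-cycle baseline MoS values (default five)."""
    vals = np.asarray(mos_cycles, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two baseline cycles")
    return BaselineStats(
        mos_mean=float(np.mean(vals)),
        mos_sd=float(np.std(vals, ddof=1)),
        n_cycles=int(vals.size),
    )


def n_steps(recovery_mos, baseline: BaselineStats, slip_index: int = 0,
            n_recovery: int = 15, window: int = 3) -> RecoveryOutcome:
    """First step opening a run of ``window`` consecutive steps whose MoS is
    inside [mean - SD, mean + SD] (inclusive); 16 (capped) if none by Rec15.
    """
    vals = np.asarray(recovery_mos, dtype=float)
    if vals.size != n_recovery:
        raise ValueError(f"expected exactly {n_recovery} recovery MoS values")
    if not np.all(np.isfinite(vals)):
        raise ValueError("recovery MoS values must be finite")
    lo = baseline.mos_mean - baseline.mos_sd
    hi = baseline.mos_mean + baseline.mos_sd
    inband = (vals >= lo) & (vals <= hi)
    for k in range(0, n_recovery - window + 1):
        if np.all(inband[k : k + window]):
            return RecoveryOutcome(slip_index=slip_index, n_steps=k + 1,
                                   capped=False)
    return RecoveryOutcome(slip_index=slip_index, n_steps=CAPPED_N_STEPS,
                           capped=True)
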
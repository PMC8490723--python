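"""Filtering, gait-event detection and stance-phase time normalization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "GaitEvents",
    "StanceCurve",
    "lowpass_filter",
    "detect_gait_events",
    "normalize_stance",
    "N_NODES",
]

N_NODES = 101  # closed [0, 100] % stance, inclusive endpoints


@dataclass
class StanceCurve:
    """A channel resampled onto 101 equally spaced nodes over stance."""

    values: np.ndarray
    channel: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_NODES,):
            raise ValueError(f"stance curve must have exactly {N_NODES} nodes")


@dataclass
class GaitEvents:
    """Heel-strike / toe-off times per side plus step labels.

    ``contacts[side]`` is an ordered list of (heel_strike, toe_off) tuples;
    ``labels`` maps a step label (e.g. "Pert", "Rec3") to (side, contact
    index) within that side's list.
    """

    contacts: dict[str, list[tuple[float, float]]]
    labels: dict[str, tuple[str, int]] = field(default_factory=dict)

    def heel_strikes(self) -> list[tuple[float, str]]:
        """All heel strikes of both sides, time-ordered, as (time, side)."""
        out = [
            (hs, side)
            for side, cs in self.contacts.items()
            for hs, _ in cs
        ]
        return sorted(out)

    def labelled(self, label: str) -> tuple[float, float, str]:
        """(heel_strike, toe_off, side) of a labelled step."""
        side, idx = self.labels[label]
        hs, to = self.contacts[side][idx]
        return hs, to, side


def lowpass_filter(
    series: np.ndarray,
    cutoff: float = 8.0,
    order: int = 4,
    rate: float = 120.0,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The two passes square the single-pass magnitude response, so the
    effective gain at frequency f is 1 / (1 + (f/cutoff)**(2*order)).
    Reflective padding (``sosfiltfilt`` default) limits edge transients.
    """
    series = np.asarray(series, dtype=float)
    if cutoff >= rate / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if series.size < 3 * (order + 1):
        raise ValueError("series too short for the requested filter order")
    sos = butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sosfiltfilt(sos, series)


def detect_gait_events(
    grf_vert: dict[str, np.ndarray],
    rate: float,
    threshold: float = 20.0,
    min_contact: float = 0.05,
    time: np.ndarray | None = None,
) -> GaitEvents:
    """Kinetic gait-event detection from per-side vertical GRF.

    Heel strike is an upward crossing of ``threshold`` sustained for at
    least ``min_contact``; toe off is the following downward crossing.
    Incomplete contacts at the ends of the record are kept only if both
    events are observed.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    contacts: dict[str, list[tuple[float, float]]] = {}
    for side, f in grf_vert.items():
        f = np.asarray(f, dtype=float)
        t = np.arange(f.size) / rate if time is None else np.asarray(time)
        above = f >= threshold
        rises = np.flatnonzero(~above[:-1] & above[1:]) + 1
        falls = np.flatnonzero(above[:-1] & ~above[1:]) + 1
        if above[0]:
            rises = np.concatenate([[0], rises])
        cs = []
        for r in rises:
            nxt = falls[falls > r]
            if nxt.size == 0:
                continue  # contact unfinished at the end of the record
            to = nxt[0]
            if (to - r) / rate >= min_contact:
                cs.append((float(t[r]), float(t[to])))
        contacts[side] = cs
    if all(len(cs) == 0 for cs in contacts.values()):
        raise ValueError("no contacts found above threshold")
    return GaitEvents(contacts=contacts)


def label_steps(
    events: GaitEvents,
    pert_hs_time: float | None,
    pert_side: str | None,
    n_recovery: int = 15,
    n_pre: int = 2,
) -> GaitEvents:
    """Assign step labels relative to the annotated perturbed step.

    For an unperturbed trial (``pert_hs_time`` is None), consecutive steps
    are labelled Normal01, Normal02, ...  For a slip trial the step whose
    heel strike is nearest the annotation on the perturbed side becomes
    Pert, the two preceding steps Pre1/Pre2 and the following ``n_recovery``
    steps Rec1..RecN.
    """
    strikes = events.heel_strikes()
    labels: dict[str, tuple[str, int]] = {}

    def locate(time: float, side: str) -> tuple[str, int]:
        cs = events.contacts[side]
        idx = int(np.argmin([abs(hs - time) for hs, _ in cs]))
        return side, idx

    if pert_hs_time is None:
        for i, (hs, side) in enumerate(strikes):
            labels[f"Normal{i + 1:02d}"] = locate(hs, side)
    else:
        if pert_side is None:
            raise ValueError("pert_side required when pert_hs_time is given")
        order = [i for i, (hs, side) in enumerate(strikes)]
        i_pert = int(
            np.argmin([abs(hs - pert_hs_time) if side == pert_side else np.inf
                       for hs, side in strikes])
        )
        seq = (
            [(-2, "Pre2"), (-1, "Pre1"), (0, "Pert")]
            + [(k, f"Rec{k}") for k in range(1, n_recovery + 1)]
        )
        for off, label in seq:
            j = i_pert + off
            if j < 0 or j >= len(strikes):
                if label.startswith("Rec"):
                    raise ValueError(
                        f"fewer than {n_recovery} recovery steps after Pert"
                    )
                continue
            hs, side = strikes[j]
            labels[label] = locate(hs, side)
        n_rec_found = sum(1 for lb in labels if lb.startswith("Rec"))
        if n_rec_found < n_recovery:
            raise ValueError(
                f"fewer than {n_recovery} recovery steps after Pert"
            )
    events.labels = labels
    return events


def normalize_stance(
    series: np.ndarray,
    hs: float,
    to: float,
    rate: float,
    t0: float = 0.0,
    channel: str = "",
    units: str = "",
) -> StanceCurve:
    """Linear interpolation of one channel onto 101 nodes spanning [hs, to].

    ``t0`` is the time of the first sample of ``series``.
    """
    if to <= hs:
        raise ValueError("toe-off must follow heel strike")
    series = np.asarray(series, dtype=float)
    t = t0 + np.arange(series.size) / rate
    if hs < t[0] - 1e-9 or to > t[-1] + 1e-9:
        raise ValueError("stance interval outside series support")
    nodes = np.linspace(hs, to, N_NODES)
    f = interp1d(t, series, kind="linear", bounds_error=False,
                 fill_value=(series[0], series[-1]))
    return StanceCurve(values=f(nodes), channel=channel, units=units)
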
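"""Plain-text trial storage: two TSV tables plus a JSON sidecar header.

A trial ``<stem>`` is stored as

* ``<stem>_markers.tsv`` — marker-clock channels, one row per sample:
  time_s, com_ap_m, com_vert_m, foot_com_ap_{left,right}_m,
  toe2_ap_{left,right}_m, moment_{hip,knee,ankle}_{left,right}_nmkg
* ``<stem>_forces.tsv`` — force-clock channels:
  time_s, grf_ap_{left,right}_n, grf_vert_{left,right}_n,
  belt_speed_{left,right}_ms
* ``<stem>.json`` — participant id, slip index, sampling rates, perturbed
  heel-strike time and the generator annotations.

Values are written with 17 significant digits so the round trip is exact;
unknown extra columns are preserved.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SIDES, TrialTimeSeries

__all__ = ["write_trial", "read_trial"]

_FLOAT_FMT = "%.17g"

_MARKER_REQUIRED = (
    ["time_s", "com_ap_m", "com_vert_m"]
    + [f"foot_com_ap_{s}_m" for s in SIDES]
    + [f"toe2_ap_{s}_m" for s in SIDES]
    + [f"moment_{j}_{s}_nmkg" for j in ("hip", "knee", "ankle") for s in SIDES]
)
_FORCE_REQUIRED = (
    ["time_s"]
    + [f"grf_ap_{s}_n" for s in SIDES]
    + [f"grf_vert_{s}_n" for s in SIDES]
    + [f"belt_speed_{s}_ms" for s in SIDES]
)


def write_trial(trial: TrialTimeSeries, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)

    markers = pd.DataFrame({"time_s": trial.time_marker})
    markers["com_ap_m"] = trial.com_ap
    markers["com_vert_m"] = trial.com_vert
    for s in SIDES:
        markers[f"foot_com_ap_{s}_m"] = trial.foot_com_ap[s]
        markers[f"toe2_ap_{s}_m"] = trial.toe2_ap[s]
    for joint, chan in (
        ("hip", trial.moment_hip),
        ("knee", trial.moment_knee),
        ("ankle", trial.moment_ankle),
    ):
        for s in SIDES:
            markers[f"moment_{joint}_{s}_nmkg"] = chan[s]
    markers.to_csv(f"{stem}_markers.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)

    forces = pd.DataFrame({"time_s": trial.time_force})
    for s in SIDES:
        forces[f"grf_ap_{s}_n"] = trial.grf_ap[s]
        forces[f"grf_vert_{s}_n"] = trial.grf_vert[s]
        forces[f"belt_speed_{s}_ms"] = trial.belt_speed[s]
    forces.to_csv(f"{stem}_forces.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)

    header = {
        "participant": trial.participant,
        "slip_index": trial.slip_index,
        "marker_rate_hz": trial.marker_rate,
        "force_rate_hz": trial.force_rate,
        "pert_hs_time_s": trial.pert_hs_time,
        "units": {"positions": "m", "forces": "N", "moments": "N.m/kg",
                  "belt_speed": "m/s", "time": "s"},
        "annotations": trial.annotations,
    }
    with open(f"{stem}.json", "w") as fh:
        json.dump(header, fh, indent=1, sort_keys=True)


def _check_rate(time_s: np.ndarray, rate: float, what: str) -> None:
    if time_s.size >= 2:
        dt = float(np.median(np.diff(time_s)))
        if abs(dt - 1.0 / rate) > 1e-6:
            raise ValueError(
                f"{what} header rate {rate} Hz inconsistent with row spacing "
                f"{dt:.6g} s"
            )


def read_trial(stem: str | Path) -> TrialTimeSeries:
    stem = Path(stem)
    with open(f"{stem}.json") as fh:
        header = json.load(fh)
    markers = pd.read_csv(f"{stem}_markers.tsv", sep="\t",
                          float_precision="round_trip")
    forces = pd.read_csv(f"{stem}_forces.tsv", sep="\t",
                         float_precision="round_trip")
    for col in _MARKER_REQUIRED:
        if col not in markers.columns:
            raise ValueError(f"marker file missing mandatory column '{col}'")
    for col in _FORCE_REQUIRED:
        if col not in forces.columns:
            raise ValueError(f"force file missing mandatory column '{col}'")
    marker_rate = float(header["marker_rate_hz"])
    force_rate = float(header["force_rate_hz"])
    _check_rate(markers["time_s"].to_numpy(), marker_rate, "marker")
    _check_rate(forces["time_s"].to_numpy(), force_rate, "force")
    return TrialTimeSeries(
        participant=header["participant"],
        slip_index=int(header["slip_index"]),
        marker_rate=marker_rate,
        force_rate=force_rate,
        time_marker=markers["time_s"].to_numpy(),
        time_force=forces["time_s"].to_numpy(),
        com_ap=markers["com_ap_m"].to_numpy(),
        com_vert=markers["com_vert_m"].to_numpy(),
        foot_com_ap={s: markers[f"foot_com_ap_{s}_m"].to_numpy() for s in SIDES},
        toe2_ap={s: markers[f"toe2_ap_{s}_m"].to_numpy() for s in SIDES},
        moment_hip={s: markers[f"moment_hip_{s}_nmkg"].to_numpy() for s in SIDES},
        moment_knee={s: markers[f"moment_knee_{s}_nmkg"].to_numpy() for s in SIDES},
        moment_ankle={s: markers[f"moment_ankle_{s}_nmkg"].to_numpy()
                      for s in SIDES},
        grf_ap={s: forces[f"grf_ap_{s}_n"].to_numpy() for s in SIDES},
        grf_vert={s: forces[f"grf_vert_{s}_n"].to_numpy() for s in SIDES},
        belt_speed={s: forces[f"belt_speed_{s}_ms"].to_numpy() for s in SIDES},
        pert_hs_time=header.get("pert_hs_time_s"),
        annotations=header.get("annotations", {}),
    )
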
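"""CSV/JSON interfaces for trial tables, traces and vesicle tables.

Schemas:

- trial tables: ``experiment_id, epoch_label, ca_mM, trial_index, time_s,
  charge_fC``
- vesicle tables: ``az_id, area_um2, vesicle_id, distance_nm``
- traces: ``time_ms, current_pA`` plus a JSON sidecar
  ``{"stimulus_time_ms": ..., "sampling_khz": ...}``
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from synquant.types import (
    ActiveZone,
    Condition,
    Epoch,
    EPSCTrace,
    Experiment,
    Vesicle,
)

__all__ = [
    "experiment_to_frame",
    "frame_to_experiments",
    "write_trial_table",
    "read_trial_table",
    "write_trace",
    "read_trace",
    "write_vesicle_table",
    "read_vesicle_table",
]

TRIAL_COLUMNS = ["experiment_id", "epoch_label", "ca_mM", "trial_index",
                 "time_s", "charge_fC"]
VESICLE_COLUMNS = ["az_id", "area_um2", "vesicle_id", "distance_nm"]


def experiment_to_frame(experiment: Experiment,
                        experiment_id: str = "exp0") -> pd.DataFrame:
    rows = []
    for epoch in experiment.epochs:
        for i, (t, c) in enumerate(zip(epoch.trial_times_s,
                                       epoch.charges_fc)):
            rows.append({
                "experiment_id": experiment_id,
                "epoch_label": epoch.condition.label,
                "ca_mM": epoch.condition.ca_mM,
                "trial_index": i,
                "time_s": t,
                "charge_fC": c,
            })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_experiments(df: pd.DataFrame) -> dict[str, Experiment]:
    """Rebuild Experiments from a trial table (P_r is unknown: set to 0)."""
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    out = {}
    for exp_id, exp_df in df.groupby("experiment_id", sort=False):
        epochs = []
        for (label, ca), ep_df in exp_df.groupby(["epoch_label", "ca_mM"],
                                                 sort=False):
            ep_df = ep_df.sort_values("trial_index")
            cond = Condition(label=str(label), ca_mM=float(ca), p_r=0.0)
            epochs.append(Epoch(
                condition=cond,
                charges_fc=ep_df["charge_fC"].to_numpy(),
                trial_times_s=ep_df["time_s"].to_numpy(),
            ))
        epochs.sort(key=lambda e: e.condition.ca_mM)
        out[str(exp_id)] = Experiment(epochs=epochs)
    return out


def write_trial_table(experiment: Experiment, path: str | Path,
                      experiment_id: str = "exp0") -> None:
    experiment_to_frame(experiment, experiment_id).to_csv(path, index=False)


def read_trial_table(path: str | Path) -> dict[str, Experiment]:
    return frame_to_experiments(pd.read_csv(path))


def write_trace(trace: EPSCTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_ms": trace.time_ms,
                  "current_pA": trace.current_pa}).to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "stimulus_time_ms": trace.stimulus_time_ms,
        "sampling_khz": trace.sampling_khz,
    }))


def read_trace(path: str | Path) -> EPSCTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return EPSCTrace(
        time_ms=df["time_ms"].to_numpy(),
        current_pa=df["current_pA"].to_numpy(),
        stimulus_time_ms=float(meta["stimulus_time_ms"]),
        sampling_khz=float(meta["sampling_khz"]),
    )


def write_vesicle_table(azs: list[ActiveZone], path: str | Path) -> None:
    rows = [
        {"az_id": az.az_id, "area_um2": az.area_um2,
         "vesicle_id": v.vesicle_id, "distance_nm": v.distance_nm}
        for az in azs for v in az.vesicles
    ]
    # AZs with no vesicles still get one row with a null vesicle
    for az in azs:
        if not az.vesicles:
            rows.append({"az_id": az.az_id, "area_um2": az.area_um2,
                         "vesicle_id": None, "distance_nm": None})
    pd.DataFrame(rows, columns=VESICLE_COLUMNS).to_csv(path, index=False)


def read_vesicle_table(path: str | Path) -> list[ActiveZone]:
    df = pd.read_csv(path)
    missing = set(VESICLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"vesicle table missing columns: {sorted(missing)}")
    azs = []
    for az_id, az_df in df.groupby("az_id", sort=False):
        area = float(az_df["area_um2"].iloc[0])
        vesicles = [
            Vesicle(vesicle_id=int(r.vesicle_id),
                    distance_nm=float(r.distance_nm))
            for r in az_df.itertuples()
            if pd.notna(r.vesicle_id)
        ]
        azs.append(ActiveZone(az_id=str(az_id), area_um2=area,
                              vesicles=vesicles))
    return azs
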
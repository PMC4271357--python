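"""Waveform CSV input/output.

Dialect: header row, columns time_s, p_a0..p_a9 (mmHg), r_a0..r_a9 (cm),
q_pump_out (ml/s), p_pump, p_ven; one row per sample (1 kHz for default
simulator settings).  A generic two-column (time_s, value) CSV is accepted
for single external channels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .params import N_SEGMENTS, ModelParameters
from .simulator import SimulationRecord
from .waveforms import PressureWaveform

__all__ = ["record_to_frame", "write_record_csv", "read_record_csv",
           "read_channel_csv"]

_P_COLS = [f"p_a{m}" for m in range(N_SEGMENTS)]
_R_COLS = [f"r_a{m}" for m in range(N_SEGMENTS)]


def record_to_frame(rec: SimulationRecord) -> pd.DataFrame:
    data = {"time_s": rec.sample_times}
    for m, col in enumerate(_P_COLS):
        data[col] = rec.seg_pressure_series[:, m]
    for m, col in enumerate(_R_COLS):
        data[col] = rec.seg_radius_series[:, m]
    data["q_pump_out"] = rec.pump_outflow_series
    data["p_pump"] = rec.pump_pressure_series
    data["p_ven"] = rec.venous_pressure_series
    return pd.DataFrame(data)


def write_record_csv(rec: SimulationRecord, path: str | Path) -> None:
    record_to_frame(rec).to_csv(path, index=False, float_format="%.10g")


def read_record_csv(path: str | Path,
                    params: ModelParameters | None = None) -> SimulationRecord:
    """Load a waveform CSV back into a record.

    The parameter echo is not stored in the CSV; pass ``params`` if
    beat-count-dependent operations (true stroke volume, PWV with the
    default period hint) will be used.
    """
    df = pd.read_csv(path)
    required = ["time_s", *_P_COLS, *_R_COLS, "q_pump_out", "p_pump", "p_ven"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"waveform CSV missing columns: {missing}")
    return SimulationRecord(
        sample_times=df["time_s"].to_numpy(),
        seg_pressure_series=df[_P_COLS].to_numpy(),
        seg_radius_series=df[_R_COLS].to_numpy(),
        pump_outflow_series=df["q_pump_out"].to_numpy(),
        pump_pressure_series=df["p_pump"].to_numpy(),
        venous_pressure_series=df["p_ven"].to_numpy(),
        params=params,
    )


def read_channel_csv(path: str | Path, label: str = "") -> PressureWaveform:
    """Load a generic two-column (time_s, value) CSV as one channel."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("channel CSV needs two columns (time_s, value)")
    return PressureWaveform(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                            label or str(df.columns[1]))
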
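"""Plain-text readers and writers.

All on-disk formats are CSV (UTF-8, decimal point, one record per row) or
JSON.  Readers and writers are exact inverses for well-formed files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibrationWeightSet
from .simulate import DualChannelRecording

RECORDING_COLUMNS = ["time_s", "primary_mmHg", "reference_mmHg"]
REFERENCE_BP_COLUMNS = ["time_s", "sbp_mmHg", "dbp_mmHg"]
BEAT_TABLE_COLUMNS = ["beat_time_s", "sbp_mmHg", "dbp_mmHg", "flag"]
PAIRED_COLUMNS = ["beat_time_s", "device_mmHg", "reference_mmHg"]


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def write_recording_csv(recording: DualChannelRecording, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": recording.time,
            "primary_mmHg": recording.primary,
            "reference_mmHg": recording.reference,
        }
    ).to_csv(path, index=False)


def read_recording_csv(path: str | Path) -> DualChannelRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, RECORDING_COLUMNS, path)
    if len(df) < 2:
        raise ValueError(f"{path}: recording needs at least two samples")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time grid is not uniform")
    return DualChannelRecording(
        time=t,
        primary=df["primary_mmHg"].to_numpy(dtype=float),
        reference=df["reference_mmHg"].to_numpy(dtype=float),
        sample_rate=1.0 / float(dt[0]),
    )


def write_weights_csv(weights: CalibrationWeightSet, path: str | Path) -> None:
    pd.DataFrame(
        {"mass_g": weights.masses, "adc_counts": weights.counts}
    ).to_csv(path, index=False)


def read_weights_csv(path: str | Path, gravity: float = 9.81) -> CalibrationWeightSet:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["mass_g", "adc_counts"], path)
    return CalibrationWeightSet(
        entries=tuple(zip(df["mass_g"], df["adc_counts"])), gravity=gravity
    )


def read_reference_bp_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, REFERENCE_BP_COLUMNS, path)
    return df


def write_beat_table_csv(beat_table: pd.DataFrame, path: str | Path) -> None:
    _require_columns(beat_table, BEAT_TABLE_COLUMNS, "beat table")
    beat_table.to_csv(path, index=False, columns=BEAT_TABLE_COLUMNS)


def read_beat_table_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, BEAT_TABLE_COLUMNS, path)
    return df


def read_paired_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PAIRED_COLUMNS, path)
    bad = df.index[df[PAIRED_COLUMNS].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: unpaired/missing value at row {int(bad[0])}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
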
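"""Reading and writing the package's file formats (WAV, CSV)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .acoustics import CallMeasurement
from .synth import Waveform

MEASUREMENT_COLUMNS = ("call_id", "individual_id", "group", "duration_s",
                       "peak_hz", "q25_hz", "q50_hz", "q75_hz", "entropy",
                       "f0max_hz", "mod_range_hz", "structure")


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a mono float32 PCM WAV."""
    wavfile.write(str(path), w.sampling_rate_hz,
                  np.asarray(w.samples, dtype=np.float32))


def read_wav(path: str | Path) -> Waveform:
    """Read a mono WAV (PCM 16-bit or float32) into a normalised Waveform."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    return Waveform(samples=data, sampling_rate_hz=int(rate))


def measurements_to_frame(measurements: list[CallMeasurement],
                          call_ids: list | None = None,
                          individual_ids: list | None = None,
                          groups: list | None = None) -> pd.DataFrame:
    """Tabulate measurements, one row per call (the analysis input schema)."""
    n = len(measurements)
    rows = []
    for i, m in enumerate(measurements):
        rows.append({
            "call_id": call_ids[i] if call_ids else i,
            "individual_id": individual_ids[i] if individual_ids else "",
            "group": groups[i] if groups else "",
            "duration_s": m.duration_s,
            "peak_hz": m.peak_frequency_hz,
            "q25_hz": m.q25_hz,
            "q50_hz": m.q50_hz,
            "q75_hz": m.q75_hz,
            "entropy": m.entropy,
            "f0max_hz": m.f0max_hz if m.f0max_hz is not None else np.nan,
            "mod_range_hz": (m.modulation_range_hz
                             if m.modulation_range_hz is not None else np.nan),
            "structure": m.structure,
        })
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurements file lacks columns: {sorted(missing)}")
    return df
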
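"""Plain-text readers/writers for traces, markers, and result tables.

Traces travel as two-column CSV (``time_s``, ``ecg_uv``); optional segment
markers come in a sidecar CSV (``segment_id``, ``start_s``, ``end_s``).
EDF input is supported when an EDF-capable reader (``mne``) is importable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EcgSegment, SegmentQuality

__all__ = [
    "read_markers_csv",
    "read_trace",
    "read_trace_csv",
    "slice_segments",
    "write_quality_csv",
    "write_trace_csv",
]


def read_trace_csv(path) -> EcgSegment:
    """Read a two-column (time_s, ecg_uv) CSV; sampling rate is inferred."""
    df = pd.read_csv(path)
    required = {"time_s", "ecg_uv"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trace CSV needs columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time column must be uniformly sampled")
    fs = round(1.0 / dt[0])
    return EcgSegment(
        samples=df["ecg_uv"].to_numpy(dtype=float),
        fs=fs,
        segment_id=Path(path).stem,
        start_s=float(t[0]),
    )


def write_trace_csv(path, seg: EcgSegment) -> None:
    pd.DataFrame({"time_s": seg.times, "ecg_uv": seg.samples}).to_csv(
        path, index=False
    )


def read_trace_edf(path, channel: int = 0) -> EcgSegment:
    """Read one channel from an EDF file (requires the optional mne reader)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF input needs the optional 'mne' package; "
            "convert to CSV (time_s, ecg_uv) otherwise"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    return EcgSegment(samples=data, fs=float(raw.info["sfreq"]),
                      segment_id=Path(path).stem)


def read_trace(path) -> EcgSegment:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_trace_edf(path)
    return read_trace_csv(path)


def read_markers_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"segment_id", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: marker CSV needs columns {sorted(required)}")
    return df


def slice_segments(seg: EcgSegment, markers: pd.DataFrame) -> list[EcgSegment]:
    """Cut a continuous trace into marked segments."""
    out = []
    for row in markers.itertuples():
        a = int(round((row.start_s - seg.start_s) * seg.fs))
        b = int(round((row.end_s - seg.start_s) * seg.fs))
        if not 0 <= a < b <= seg.samples.size:
            raise ValueError(
                f"marker {row.segment_id!r} [{row.start_s}, {row.end_s}] "
                "outside the trace"
            )
        out.append(
            EcgSegment(
                samples=seg.samples[a:b], fs=seg.fs,
                segment_id=str(row.segment_id), start_s=row.start_s,
            )
        )
    return out


def write_quality_csv(path, quals: list[SegmentQuality],
                      threshold_db: float = 5.0) -> None:
    pd.DataFrame(
        {
            "segment_id": [q.segment_id for q in quals],
            "n_beats": [q.n_beats for q in quals],
            "snr_bar_db": [q.snr_bar_db for q in quals],
            "kept": [q.snr_bar_db >= threshold_db for q in quals],
        }
    ).to_csv(path, index=False)
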
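"""Beat detection, duration-normalized epoching, and SNR quality control.

Continuous single-lead ECG is resampled to 1024 Hz, R peaks are picked with
a bandpass-energy detector, and each interior beat is mapped to a 500-sample
normalized window (previous R -> -1, own R -> 0, next R -> +1; 250 samples
per half with the shared R sample belonging to the second half).  Segment
quality is the mean over beats of each beat's SNR against the segment's
mean beat; segments below 5 dB are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "TARGET_FS",
    "BeatEpoch",
    "EcgSegment",
    "SegmentQuality",
    "SegmentRejected",
    "UndefinedSnrError",
    "detect_r_peaks",
    "epoch_beats",
    "filter_segments",
    "resample_to_1024",
    "segment_quality",
    "snr_db",
]

log = logging.getLogger(__name__)

TARGET_FS = 1024
#: Residual power below this fraction of signal power reports the cap.
SNR_CAP_DB = 120.0
_CAP_RATIO = 1e-12


class SegmentRejected(RuntimeError):
    """Segment failed a hard quality rule (e.g., fewer than 20 beats)."""


class UndefinedSnrError(ValueError):
    """SNR is undefined for an all-zero reference signal."""


@dataclass
class EcgSegment:
    """A contiguous stretch of single-lead ECG in microvolts."""

    samples: np.ndarray
    fs: float
    segment_id: str = ""
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.samples.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class BeatEpoch:
    """One beat on the 500-sample normalized grid, with its timing context.

    ``t1``/``t2``/``t3`` are the R-peak times (s) of the previous, own, and
    next beat; ``alpha = (t3 - t1) / 2`` is the seconds-per-normalized-unit
    factor used for parameter denormalization.
    """

    x: np.ndarray
    t1: float
    t2: float
    t3: float
    beat_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (500,):
            raise ValueError(f"epoch must have 500 samples, got {self.x.shape}")
        if not self.t1 < self.t2 < self.t3:
            raise ValueError("R-peak times must be strictly increasing")

    @property
    def alpha(self) -> float:
        return 0.5 * (self.t3 - self.t1)


@dataclass
class SegmentQuality:
    mean_beat: np.ndarray
    snr_per_beat_db: np.ndarray
    snr_bar_db: float
    n_beats: int
    segment_id: str = ""


def resample_to_1024(seg: EcgSegment) -> EcgSegment:
    """Polyphase-resample a segment to 1024 Hz (identity if already there)."""
    if seg.fs == TARGET_FS:
        return seg
    try:
        frac = Fraction(TARGET_FS, int(seg.fs))
    except (ValueError, ZeroDivisionError) as exc:
        raise ValueError(f"unsupported sampling rate {seg.fs}") from exc
    if int(seg.fs) != seg.fs:
        raise ValueError(f"unsupported non-integer sampling rate {seg.fs}")
    out = sps.resample_poly(seg.samples, frac.numerator, frac.denominator)
    return EcgSegment(
        samples=out, fs=TARGET_FS, segment_id=seg.segment_id, start_s=seg.start_s
    )


def _adaptive_threshold(energy: np.ndarray, fs: float) -> np.ndarray:
    """0.5 x 75th percentile of the energy signal over ~2 s blocks."""
    block = max(int(round(2.0 * fs)), 1)
    n = energy.size
    edges = np.arange(0, n, block)
    centers = np.minimum(edges + block // 2, n - 1).astype(float)
    p75 = np.array(
        [np.percentile(energy[i : i + block], 75.0) for i in edges]
    )
    if p75.size == 1:
        return np.full(n, 0.5 * p75[0])
    return 0.5 * np.interp(np.arange(n, dtype=float), centers, p75)


def detect_r_peaks(
    seg: EcgSegment, min_beats: int = 20, refractory_s: float = 0.2
) -> np.ndarray:
    """R-peak times (s), via 5-30 Hz bandpass energy and adaptive threshold.

    Raises :class:`SegmentRejected` when fewer than ``min_beats`` beats are
    found (mirrors the segment-rejection rule of the processing pipeline).
    """
    fs = seg.fs
    if seg.duration_s < 2.0:
        raise SegmentRejected(
            f"segment {seg.segment_id!r}: too short ({seg.duration_s:.2f} s)"
        )
    sos = sps.butter(4, [5.0, 30.0], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, seg.samples)
    energy = band * band
    # Pan-Tompkins-style moving integration over ~120 ms
    win = max(int(round(0.12 * fs)), 1)
    energy = np.convolve(energy, np.ones(win) / win, mode="same")
    thr = _adaptive_threshold(energy, fs)
    distance = max(int(round(refractory_s * fs)), 1)
    locs, _ = sps.find_peaks(energy, height=thr, distance=distance)
    if locs.size:
        # drop low-energy detections (T waves leak through on clean signal)
        gate = 0.2 * np.median(energy[locs])
        locs = locs[energy[locs] >= gate]
    # refine each detection to the raw-signal maximum within +/-50 ms
    half = int(round(0.05 * fs))
    refined = []
    for loc in locs:
        a, b = max(loc - half, 0), min(loc + half + 1, seg.samples.size)
        refined.append(a + int(np.argmax(seg.samples[a:b])))
    refined = np.unique(refined)
    # drop refined duplicates that collapsed within the refractory window
    if refined.size:
        keep = [refined[0]]
        for r in refined[1:]:
            if r - keep[-1] >= distance:
                keep.append(r)
        refined = np.asarray(keep)
    if refined.size < min_beats:
        raise SegmentRejected(
            f"segment {seg.segment_id!r}: detected {refined.size} beats "
            f"(< {min_beats})"
        )
    return seg.start_s + refined / fs


def epoch_beats(seg: EcgSegment, peaks: np.ndarray) -> list[BeatEpoch]:
    """Epoch every interior beat into a 500-sample normalized window.

    Each half is linearly interpolated onto 250 regularly spaced samples;
    halves use a half-open convention so the own R-peak sample appears once,
    as the first sample of the second half (normalized time 0).
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 3:
        return []
    times = seg.times
    epochs = []
    for k in range(1, peaks.size - 1):
        t1, t2, t3 = peaks[k - 1], peaks[k], peaks[k + 1]
        grid1 = t1 + (t2 - t1) * np.arange(250) / 250.0
        grid2 = t2 + (t3 - t2) * np.arange(250) / 250.0
        x = np.interp(np.concatenate([grid1, grid2]), times, seg.samples)
        epochs.append(
            BeatEpoch(
                x=x, t1=t1, t2=t2, t3=t3,
                beat_id=f"{seg.segment_id}:{k}" if seg.segment_id else str(k),
            )
        )
    return epochs


def snr_db(x: np.ndarray, x_ref: np.ndarray, cap_db: float = SNR_CAP_DB) -> float:
    """``10 * log10(sum(x_ref**2) / sum((x - x_ref)**2))`` in dB.

    Capped at ``cap_db`` when the residual power is below 1e-12 of the
    reference power (replaces +inf for perfect fits).
    """
    x = np.asarray(x, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    if x.shape != x_ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_ref.shape}")
    sig = float(np.sum(x_ref * x_ref))
    if sig == 0.0:
        raise UndefinedSnrError("reference signal is all-zero; SNR undefined")
    res = float(np.sum((x - x_ref) ** 2))
    if res < _CAP_RATIO * sig:
        return cap_db
    return min(10.0 * np.log10(sig / res), cap_db)


def segment_quality(
    epochs: list[BeatEpoch], segment_id: str = ""
) -> SegmentQuality:
    """Mean beat and per-beat/mean SNRs for one segment."""
    if not epochs:
        raise ValueError("segment_quality requires at least one epoch")
    mat = np.stack([e.x for e in epochs])
    mean_beat = mat.mean(axis=0)
    snrs = np.array([snr_db(row, mean_beat) for row in mat])
    return SegmentQuality(
        mean_beat=mean_beat,
        snr_per_beat_db=snrs,
        snr_bar_db=float(snrs.mean()),
        n_beats=len(epochs),
        segment_id=segment_id or (epochs[0].beat_id.split(":")[0]),
    )


def filter_segments(
    segs: list[SegmentQuality], threshold_db: float = 5.0
) -> tuple[list[SegmentQuality], list[SegmentQuality]]:
    """Partition segments into (kept, rejected); reject iff mean SNR < threshold."""
    kept = [s for s in segs if s.snr_bar_db >= threshold_db]
    rejected = [s for s in segs if s.snr_bar_db < threshold_db]
    if rejected:
        log.info(
            "rejected %d/%d segments below %.1f dB",
            len(rejected), len(segs), threshold_db,
        )
    return kept, rejected
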
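"""Synthetic single-lead ECG with known lognormal ground truth.

Renders repeated beats from the forward model with per-beat parameter
jitter, per-subject offsets, variable RR intervals, additive noise
calibrated to a target epoched SNR, and an optional age covariate inducing
linear parameter drifts.  Serves both as the test fixture generator and as
the stand-in for the unavailable infant recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bounds import ParameterBounds, load_table_bounds
from .model import (
    GRID,
    NORMALIZED,
    VECTOR_FIELDS,
    SigmaLognormalParams,
    denormalize_params,
    lognormal_density,
    peak_times_vector,
    synthesize_vector,
)
from .preprocess import BeatEpoch, EcgSegment, epoch_beats, segment_quality

__all__ = [
    "SynthSpec",
    "default_age_slopes",
    "generate_study_truth",
    "paper_like_design",
    "random_inbox_params",
    "render_trace",
    "sample_beat_params",
    "vectors_to_epochs",
]


def paper_like_design() -> dict[int, int]:
    """Participants per age level (months) mirroring the published design."""
    return {1: 9, 2: 13, 3: 19, 4: 21, 6: 14, 9: 19, 12: 17, 15: 9}


def default_age_slopes(bounds: ParameterBounds | None = None) -> dict[str, float]:
    """Ten nonzero per-month linear drifts (rest of the 24 are null).

    Each nonzero slope moves its parameter by ~60% of the box width across
    the 1-15 month span, signed to alternate directions.
    """
    if bounds is None:
        bounds = load_table_bounds()
    width = dict(zip(VECTOR_FIELDS, bounds.width()))
    chosen = [
        ("P_D", +1), ("P_mu", -1), ("R_sigma", +1), ("R_D", -1),
        ("S_t0", +1), ("S_D", -1), ("Tp_mu", +1), ("Tp_t0", -1),
        ("Tm_mu", +1), ("Tm_sigma", -1),
    ]
    span = 14.0  # months between the first and last age level
    slopes = {name: 0.0 for name in VECTOR_FIELDS}
    for name, sign in chosen:
        slopes[name] = sign * 0.5 * width[name] / span
    return slopes


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings for a synthetic study."""

    design: dict[int, int] = field(default_factory=paper_like_design)
    beats_per_segment: int = 30
    segments_per_recording: int = 1
    mean_rr_s: float = 0.5
    rr_jitter_s: float = 0.02
    param_age_slopes: dict[str, float] = field(default_factory=dict)
    age_center_months: float = 8.0  # drifts are applied as slope*(age-center)
    subject_sd: float = 0.05  # per-subject offset, fraction of box width
    param_noise_sd: float = 0.01  # per-beat jitter, fraction of box width
    target_snr_db: float | None = None  # None -> noiseless render
    fs: float = 1024.0
    seed: int = 0


def random_inbox_params(
    rng: np.random.Generator,
    bounds: ParameterBounds,
    max_tries: int = 100,
) -> np.ndarray:
    """Uniform draw from the box, rejected until peak-order-valid."""
    for _ in range(max_tries):
        vec = rng.uniform(bounds.lower, bounds.upper)
        tp = peak_times_vector(vec)
        if np.all(tp[:-1] < tp[1:]):
            return vec
    raise RuntimeError(f"no order-valid draw after {max_tries} rejections")


def _order_valid(vec: np.ndarray) -> bool:
    tp = peak_times_vector(vec)
    return bool(np.all(tp[:-1] < tp[1:]))


def sample_beat_params(
    spec: SynthSpec,
    rng: np.random.Generator,
    bounds: ParameterBounds,
    prototype_vec: np.ndarray,
    age_months: float,
    subject_offset: np.ndarray,
    max_tries: int = 100,
) -> np.ndarray:
    """Prototype + age drift + subject offset + beat jitter, clipped in-box.

    Draws are rejected (new jitter) until peak-order-valid.
    """
    width = bounds.width()
    slopes = np.array(
        [spec.param_age_slopes.get(name, 0.0) for name in VECTOR_FIELDS]
    )
    drift = (age_months - spec.age_center_months) * slopes
    base = prototype_vec + drift + subject_offset
    for _ in range(max_tries):
        jitter = rng.normal(0.0, spec.param_noise_sd * width)
        vec = bounds.clip(base + jitter)
        if _order_valid(vec):
            return vec
    raise RuntimeError(
        f"no order-valid beat after {max_tries} jitter rejections"
    )


def _noise(rng: np.random.Generator, n: int, fs: float, power: float) -> np.ndarray:
    """White Gaussian + 0.3 Hz baseline wander, 70/30 power split."""
    white = rng.standard_normal(n) * np.sqrt(0.7 * power)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / fs
    wander = np.sqrt(2.0 * 0.3 * power) * np.sin(2.0 * np.pi * 0.3 * t + phase)
    return white + wander


def _render_clean(
    beat_vecs: np.ndarray, r_times: np.ndarray, fs: float
) -> np.ndarray:
    """Sum denormalized beats onto a continuous time grid."""
    n_beats = beat_vecs.shape[0]
    duration = r_times[-1] + (r_times[-1] - r_times[-2])
    n = int(np.ceil(duration * fs)) + 1
    t = np.arange(n) / fs
    out = np.zeros(n)
    for i in range(n_beats):
        if i == 0:
            alpha = r_times[1] - r_times[0]
        elif i == n_beats - 1:
            alpha = r_times[-1] - r_times[-2]
        else:
            alpha = 0.5 * (r_times[i + 1] - r_times[i - 1])
        params = SigmaLognormalParams.from_vector(beat_vecs[i], NORMALIZED)
        sec = denormalize_params(params, alpha)
        # support of one beat spans about [-alpha, alpha] around its R peak
        a = max(int((r_times[i] - 1.2 * alpha) * fs), 0)
        b = min(int((r_times[i] + 1.2 * alpha) * fs) + 1, n)
        local = t[a:b] - r_times[i]
        for comp in sec.components:
            if comp.D != 0.0:
                out[a:b] += lognormal_density(local, comp)
    return out


def render_trace(
    beat_vecs: np.ndarray,
    spec: SynthSpec,
    rng: np.random.Generator,
    calibration_iters: int = 4,
) -> tuple[EcgSegment, np.ndarray]:
    """Render beats into a continuous trace; returns (segment, true R times).

    RR intervals are ``mean_rr_s`` with Gaussian jitter.  When
    ``spec.target_snr_db`` is set, additive noise is scaled by an iterative
    calibration loop so the epoched segment's mean beat SNR lands within
    about 1 dB of the target.
    """
    beat_vecs = np.atleast_2d(np.asarray(beat_vecs, dtype=float))
    n_beats = beat_vecs.shape[0]
    if n_beats < 3:
        raise ValueError("need at least 3 beats to render a trace")
    rr = spec.mean_rr_s + rng.normal(0.0, spec.rr_jitter_s, n_beats)
    rr = np.clip(rr, 0.3 * spec.mean_rr_s, None)
    r_times = spec.mean_rr_s + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    clean = _render_clean(beat_vecs, r_times, spec.fs)

    if spec.target_snr_db is None:
        return EcgSegment(samples=clean, fs=spec.fs), r_times

    def _measured(noisy: np.ndarray) -> float:
        seg = EcgSegment(samples=noisy, fs=spec.fs)
        return segment_quality(epoch_beats(seg, r_times)).snr_bar_db

    sig_power = float(np.mean(clean**2))
    noise_power = sig_power / 10.0 ** (spec.target_snr_db / 10.0)
    shape = _noise(rng, clean.size, spec.fs, 1.0)
    scale = np.sqrt(noise_power)
    for _ in range(calibration_iters):
        snr = _measured(clean + scale * shape)
        err_db = snr - spec.target_snr_db
        if abs(err_db) < 0.25:
            break
        scale *= 10.0 ** (err_db / 20.0)
    return EcgSegment(samples=clean + scale * shape, fs=spec.fs), r_times


def vectors_to_epochs(
    beat_vecs: np.ndarray, rr_s: float = 1.0, id_prefix: str = "synth"
) -> list[BeatEpoch]:
    """Wrap directly synthesized beats as epochs (no rendering round trip).

    Useful for noiseless fitting experiments: each epoch is the forward
    model evaluated on the canonical grid, with a nominal RR of ``rr_s``.
    """
    beat_vecs = np.atleast_2d(np.asarray(beat_vecs, dtype=float))
    return [
        BeatEpoch(
            x=synthesize_vector(vec, GRID),
            t1=0.0, t2=rr_s, t3=2.0 * rr_s,
            beat_id=f"{id_prefix}:{i}",
        )
        for i, vec in enumerate(beat_vecs)
    ]


def generate_study_truth(
    spec: SynthSpec, bounds: ParameterBounds | None = None
) -> pd.DataFrame:
    """Per-beat ground-truth table for a whole synthetic study.

    One recording per (age level, participant); each recording holds
    ``segments_per_recording x beats_per_segment`` beats.  Seconds-basis
    parameters use a per-beat alpha of ``mean_rr_s`` (RR jitter affects the
    rendering, not the truth records).  Columns: recording/segment/beat ids,
    subject, age_months, and the 24 normalized + 24 seconds parameters.
    """
    if bounds is None:
        bounds = load_table_bounds()
    from .bounds import load_prototype

    proto = load_prototype().params.to_vector()
    rng = np.random.default_rng(spec.seed)
    width = bounds.width()
    rows = []
    for age, n_participants in sorted(spec.design.items()):
        for p in range(n_participants):
            subject = f"sub-{age:02d}-{p:02d}"
            offset = rng.normal(0.0, spec.subject_sd * width)
            rec = f"{subject}_rec"
            for s in range(spec.segments_per_recording):
                seg_id = f"{rec}_seg{s}"
                for b in range(spec.beats_per_segment):
                    vec = sample_beat_params(
                        spec, rng, bounds, proto, age, offset
                    )
                    params = SigmaLognormalParams.from_vector(vec, NORMALIZED)
                    sec = denormalize_params(params, spec.mean_rr_s)
                    row = {
                        "recording_id": rec,
                        "segment_id": seg_id,
                        "beat_id": f"{seg_id}:{b}",
                        "subject": subject,
                        "age_months": age,
                    }
                    row.update(
                        {f"norm_{k}": v
                         for k, v in zip(VECTOR_FIELDS, vec)}
                    )
                    row.update(
                        {f"sec_{k}": v
                         for k, v in zip(VECTOR_FIELDS, sec.to_vector())}
                    )
                    rows.append(row)
    return pd.DataFrame(rows)
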
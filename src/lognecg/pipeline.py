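"""Stage orchestration: synth -> preprocess -> train -> extract -> analyze.

Each stage reads its inputs from and writes its outputs to ``cfg.out_dir``
so a run can be resumed per stage; a missing upstream artifact raises
:class:`StageDependencyError`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import age_correlations, aggregate, filter_age_levels
from .bounds import load_table_bounds
from .config import RunConfig
from .environment import EnvConfig
from .extract import LinearPolicy, batch_extract, fits_to_frame, train_policy
from .io import write_quality_csv, write_trace_csv
from .preprocess import (
    BeatEpoch,
    SegmentRejected,
    detect_r_peaks,
    epoch_beats,
    filter_segments,
    resample_to_1024,
    segment_quality,
)
from .synth import SynthSpec, default_age_slopes, generate_study_truth, render_trace

__all__ = ["StageDependencyError", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("synth", "preprocess", "train", "extract", "analyze")


class StageDependencyError(RuntimeError):
    """A stage's required upstream artifact is missing."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageDependencyError(
            f"stage {stage!r} needs missing artifact {path}"
        )
    return path


def _synth_spec(cfg: RunConfig) -> SynthSpec:
    kw = dict(cfg.synth)
    if "param_age_slopes" not in kw:
        kw["param_age_slopes"] = default_age_slopes()
    kw.setdefault("seed", cfg.seed)
    return SynthSpec(**kw)


def stage_synth(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir) / "synth"
    out.mkdir(parents=True, exist_ok=True)
    spec = _synth_spec(cfg)
    truth = generate_study_truth(spec)
    truth.to_csv(out / "truth.csv", index=False)
    rng = np.random.default_rng(spec.seed + 1)
    norm_cols = [c for c in truth.columns if c.startswith("norm_")]
    r_rows = []
    for seg_id, group in truth.groupby("segment_id", sort=False):
        vecs = group[norm_cols].to_numpy(dtype=float)
        seg, r_times = render_trace(vecs, spec, rng)
        seg.segment_id = str(seg_id)
        write_trace_csv(out / f"trace_{seg_id}.csv", seg)
        r_rows.extend(
            {"segment_id": seg_id, "beat_index": i, "r_time_s": t}
            for i, t in enumerate(r_times)
        )
    pd.DataFrame(r_rows).to_csv(out / "r_times.csv", index=False)
    log.info("synth: %d segments written to %s", truth["segment_id"].nunique(), out)


def stage_preprocess(cfg: RunConfig) -> None:
    root = Path(cfg.out_dir)
    synth_dir = _require(root / "synth", "preprocess")
    out = root / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    from .io import read_trace_csv

    quals, rows = [], []
    for trace_path in sorted(synth_dir.glob("trace_*.csv")):
        seg = resample_to_1024(read_trace_csv(trace_path))
        seg.segment_id = trace_path.stem.removeprefix("trace_")
        try:
            peaks = detect_r_peaks(seg, min_beats=cfg.min_beats_per_segment)
        except SegmentRejected as exc:
            log.info("preprocess: %s", exc)
            continue
        epochs = epoch_beats(seg, peaks)
        if not epochs:
            continue
        quals.append(segment_quality(epochs, segment_id=seg.segment_id))
        for e in epochs:
            rows.append(
                {"beat_id": e.beat_id, "segment_id": seg.segment_id,
                 "t1": e.t1, "t2": e.t2, "t3": e.t3,
                 **{f"x{i}": v for i, v in enumerate(e.x)}}
            )
    kept, _ = filter_segments(quals, cfg.segment_snr_threshold_db)
    write_quality_csv(out / "quality.csv", quals, cfg.segment_snr_threshold_db)
    kept_ids = {q.segment_id for q in kept}
    epochs_df = pd.DataFrame(rows)
    epochs_df = epochs_df[epochs_df["segment_id"].isin(kept_ids)]
    epochs_df.to_csv(out / "epochs.csv", index=False)
    log.info("preprocess: kept %d/%d segments", len(kept), len(quals))


def _load_epochs(path: Path) -> list[BeatEpoch]:
    df = pd.read_csv(path)
    xcols = [f"x{i}" for i in range(500)]
    return [
        BeatEpoch(
            x=row[xcols].to_numpy(dtype=float),
            t1=row["t1"], t2=row["t2"], t3=row["t3"],
            beat_id=str(row["beat_id"]),
        )
        for _, row in df.iterrows()
    ]


def _env_cfg(cfg: RunConfig, beats: np.ndarray, extraction: bool) -> EnvConfig:
    kw = dict(
        action_halfwidth=cfg.action_halfwidth,
        max_steps=cfg.extract_max_steps if extraction else cfg.train_max_steps,
        patience=cfg.extract_patience if extraction else cfg.train_patience,
    )
    base = (EnvConfig.extraction if extraction else EnvConfig.training)(
        load_table_bounds(), **kw
    )
    return base.with_beats(beats) if beats.size else base


def stage_train(cfg: RunConfig) -> None:
    root = Path(cfg.out_dir)
    epochs = _load_epochs(_require(root / "preprocess" / "epochs.csv", "train"))
    out = root / "train"
    out.mkdir(parents=True, exist_ok=True)
    beats = np.stack([e.x for e in epochs])
    env_cfg = _env_cfg(cfg, beats, extraction=False)
    result = train_policy(
        beats, env_cfg, total_steps=cfg.train_total_steps, seed=cfg.seed
    )
    result.history.to_csv(out / "history.csv", index=False)
    if isinstance(result.policy, LinearPolicy):
        result.policy.save(out / "policy.txt")
    log.info("train: %d env steps", result.total_env_steps)


def stage_extract(cfg: RunConfig) -> None:
    root = Path(cfg.out_dir)
    epochs = _load_epochs(_require(root / "preprocess" / "epochs.csv", "extract"))
    policy_path = root / "train" / "policy.txt"
    out = root / "extract"
    out.mkdir(parents=True, exist_ok=True)
    beats = np.stack([e.x for e in epochs])
    env_cfg = _env_cfg(cfg, beats, extraction=True)
    if policy_path.exists():
        policy = LinearPolicy.load(policy_path, cfg.action_halfwidth)
        fits, table = batch_extract(
            policy, epochs, env_cfg,
            exclusion_threshold_db=cfg.beat_exclusion_threshold_db,
        )
    else:
        log.info("extract: no trained policy found, using baseline optimizer")
        fits, table = batch_extract(
            None, epochs, env_cfg, use_baseline=True, seed=cfg.seed,
            exclusion_threshold_db=cfg.beat_exclusion_threshold_db,
        )
    table.to_csv(out / "fits.csv", index=False)
    hist, edges = np.histogram([f.snr_db for f in fits], bins=24, range=(-10, 50))
    pd.DataFrame({"bin_left_db": edges[:-1], "bin_right_db": edges[1:],
                  "count": hist}).to_csv(out / "snr_histogram.csv", index=False)
    log.info("extract: %d beats, %d excluded",
             len(fits), sum(f.excluded for f in fits))


def stage_analyze(cfg: RunConfig) -> None:
    root = Path(cfg.out_dir)
    fits = pd.read_csv(_require(root / "extract" / "fits.csv", "analyze"))
    truth = pd.read_csv(_require(root / "synth" / "truth.csv", "analyze"))
    out = root / "analyze"
    out.mkdir(parents=True, exist_ok=True)
    meta = truth[["recording_id", "subject", "age_months"]].drop_duplicates()
    seg_map = truth[["segment_id", "recording_id"]].drop_duplicates()
    # epoching names beats "<segment_id>:<k>"
    fits["segment_id"] = fits["beat_id"].str.rsplit(":", n=1).str[0]
    fits = fits.merge(seg_map, on="segment_id", how="left")
    agg = aggregate(fits, metadata=meta)
    agg = filter_age_levels(agg, cfg.min_participants_per_age)
    agg.to_csv(out / "aggregated.csv", index=False)
    corr = age_correlations(agg, n_tests=cfg.n_tests, alpha=cfg.alpha)
    corr.to_csv(out / "correlations.csv", index=False)
    log.info("analyze: %d significant parameters", int(corr["significant"].sum()))


_STAGE_FUNCS = {
    "synth": stage_synth,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "extract": stage_extract,
    "analyze": stage_analyze,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages in order; returns the artifact directory."""
    root = Path(cfg.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "stages": list(stages),
    }
    (root / "run.json").write_text(json.dumps(manifest, indent=2))
    cfg.to_yaml(root / "config.yaml")
    for name in stages:
        if name not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
        log.info("running stage %s", name)
        _STAGE_FUNCS[name](cfg)
    return root
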
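"""Downstream statistics: aggregate fitted parameters and test age trends.

Fitted beats (seconds basis, exclusions already flagged) are averaged in
two unweighted stages -- beats within segments, then segments within
recordings -- before each of the 24 parameters is rank-correlated with age
(Kendall tau-b) under a Bonferroni correction for 24 tests at alpha 0.01.
Age levels with fewer than eight distinct participants are dropped first.

The repeated-subjects caveat applies: recordings from the same participant
at different ages all enter the correlation as separate rows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .model import VECTOR_FIELDS

__all__ = ["age_correlations", "aggregate", "filter_age_levels"]

log = logging.getLogger(__name__)

SEC_PARAM_COLS = tuple(f"sec_{name}" for name in VECTOR_FIELDS)
_META_COLS = ("recording_id", "segment_id", "subject", "age_months")


def aggregate(
    fits: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    param_cols: tuple[str, ...] = SEC_PARAM_COLS,
) -> pd.DataFrame:
    """Two-stage unweighted mean: beats -> segments -> recordings.

    ``fits`` needs ``recording_id``/``segment_id``/``excluded`` plus the
    parameter columns; subject and age may come via ``metadata`` (keyed by
    ``recording_id``).  Recordings with no surviving beats are dropped with
    a log entry.
    """
    df = fits
    if metadata is not None:
        df = df.merge(metadata, on="recording_id", how="left",
                      suffixes=("", "_meta"))
    missing = [c for c in ("recording_id", "segment_id") if c not in df.columns]
    if missing:
        raise ValueError(f"fits table missing columns: {missing}")
    n_rec_in = df["recording_id"].nunique()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    dropped = n_rec_in - df["recording_id"].nunique()
    if dropped:
        log.info("dropped %d recording(s) with no surviving beats", dropped)
    cols = list(param_cols)
    keep_meta = [c for c in ("subject", "age_months") if c in df.columns]
    seg = df.groupby(["recording_id", "segment_id"], sort=False).agg(
        {**{c: "mean" for c in cols}, **{c: "first" for c in keep_meta}}
    )
    rec = seg.groupby("recording_id", sort=False).agg(
        {**{c: "mean" for c in cols}, **{c: "first" for c in keep_meta}}
    )
    return rec.reset_index()


def filter_age_levels(
    table: pd.DataFrame, min_n: int = 8
) -> pd.DataFrame:
    """Keep age levels with at least ``min_n`` distinct participants."""
    if table.empty:
        return table
    counts = table.groupby("age_months")["subject"].nunique()
    kept_ages = counts[counts >= min_n].index
    out = table[table["age_months"].isin(kept_ages)]
    if len(kept_ages) < counts.size:
        log.info(
            "dropped age levels %s (fewer than %d participants)",
            sorted(set(counts.index) - set(kept_ages)), min_n,
        )
    return out


def age_correlations(
    table: pd.DataFrame,
    param_cols: tuple[str, ...] = SEC_PARAM_COLS,
    n_tests: int = 24,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Kendall tau-b of each parameter against age, Bonferroni-corrected.

    Returns one row per parameter: ``parameter, tau, p_corrected,
    significant``.  Constant columns yield NA tau and are never flagged.
    """
    if table["age_months"].nunique() < 2:
        raise ValueError("need at least two age levels for correlation")
    age = table["age_months"].to_numpy(dtype=float)
    rows = []
    for col in param_cols:
        vals = table[col].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            rows.append({"parameter": col, "tau": np.nan,
                         "p_corrected": np.nan, "significant": False})
            continue
        res = stats.kendalltau(age, vals)
        p_corr = min(float(res.pvalue) * n_tests, 1.0)
        rows.append(
            {
                "parameter": col,
                "tau": float(res.statistic),
                "p_corrected": p_corr,
                "significant": bool(p_corr < alpha),
            }
        )
    return pd.DataFrame(rows)
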
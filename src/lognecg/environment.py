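"""Sequential-decision environment for constrained beat fitting.

State is the current 24-parameter estimate plus a windowed fitting-error
observation; an action is a small multiplicative parameter update scaled by
the box reference point; the reward is the change in fitting SNR.  Updates
that would invert the order of neighboring component peaks are cancelled
per component, and the estimate is always clipped into the parameter box,
so every reachable state is physiologically admissible.

The environment follows the usual episodic-control contract
(``reset(target) -> obs``, ``step(action) -> (obs, reward, done, info)``)
so any policy-optimization backend can drive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bounds import ParameterBounds, load_table_bounds
from .model import GRID, N_PARAMS, peak_times_vector, synthesize_vector
from .preprocess import SNR_CAP_DB, snr_db

__all__ = [
    "OBS_WINDOW",
    "OBS_WINDOW_SLICE",
    "EnvConfig",
    "EnvState",
    "FittingEnv",
    "error_observation_bounds",
    "flatten_observation",
]

#: Normalized-time observation window [-0.3, 0.7), half-open so exactly
#: 250 of the 500 grid points are selected (indices 175..424).
OBS_WINDOW = (-0.3, 0.7)
OBS_WINDOW_SLICE = slice(175, 425)
N_ERR = 250
#: Ordering-cancellation re-check passes after clipping.
_MAX_CANCEL_PASSES = 6


@dataclass(frozen=True)
class EnvConfig:
    """Environment configuration.

    ``error_obs_lower``/``error_obs_upper`` are per-point residual bounds
    (typically 1.5x the extreme residuals seen at the initial estimate over
    a training corpus) used to min-max-normalize the error observation.
    """

    bounds: ParameterBounds
    error_obs_lower: np.ndarray
    error_obs_upper: np.ndarray
    action_halfwidth: float = 0.01
    max_steps: int = 1000
    patience: int = 100
    snr_cap_db: float = SNR_CAP_DB

    def __post_init__(self) -> None:
        lo = np.asarray(self.error_obs_lower, dtype=float)
        hi = np.asarray(self.error_obs_upper, dtype=float)
        if lo.shape != (N_ERR,) or hi.shape != (N_ERR,):
            raise ValueError(f"error observation bounds must have shape ({N_ERR},)")
        if not np.all(lo < hi):
            raise ValueError("error_obs_lower must be < error_obs_upper pointwise")
        if not 0 < self.patience < self.max_steps:
            raise ValueError("require 0 < patience < max_steps")
        if self.action_halfwidth <= 0:
            raise ValueError("action_halfwidth must be > 0")
        object.__setattr__(self, "error_obs_lower", lo)
        object.__setattr__(self, "error_obs_upper", hi)

    @classmethod
    def training(cls, bounds: ParameterBounds | None = None, **kw) -> "EnvConfig":
        """Training defaults: 1000 max steps, patience 100."""
        kw.setdefault("max_steps", 1000)
        kw.setdefault("patience", 100)
        return cls._make(bounds, **kw)

    @classmethod
    def extraction(cls, bounds: ParameterBounds | None = None, **kw) -> "EnvConfig":
        """Extraction defaults: 2000 max steps, patience 200."""
        kw.setdefault("max_steps", 2000)
        kw.setdefault("patience", 200)
        return cls._make(bounds, **kw)

    @classmethod
    def _make(cls, bounds, **kw) -> "EnvConfig":
        if bounds is None:
            bounds = load_table_bounds()
        if "error_obs_lower" not in kw:
            lo, hi = _fallback_error_bounds(bounds)
            kw["error_obs_lower"], kw["error_obs_upper"] = lo, hi
        return cls(bounds=bounds, **kw)

    def with_beats(self, beats: np.ndarray) -> "EnvConfig":
        """Replace the error-observation bounds with corpus-derived ones."""
        lo, hi = error_observation_bounds(beats, self.bounds)
        return replace(self, error_obs_lower=lo, error_obs_upper=hi)


def error_observation_bounds(
    beats: np.ndarray,
    bounds: ParameterBounds,
    factor: float = 1.5,
    floor: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point residual bounds from a beat corpus at the initial estimate.

    ``factor`` x the pointwise min/max of (beat - reference synthesis) over
    the corpus, windowed to the observed 250 points.  Degenerate per-point
    ranges are widened symmetrically to at least ``floor`` times the global
    residual scale.
    """
    beats = np.atleast_2d(np.asarray(beats, dtype=float))
    if beats.shape[1] != 500:
        raise ValueError("beats must be (n, 500)")
    ref_signal = synthesize_vector(bounds.reference, GRID)[OBS_WINDOW_SLICE]
    resid = beats[:, OBS_WINDOW_SLICE] - ref_signal
    lo = factor * resid.min(axis=0)
    hi = factor * resid.max(axis=0)
    scale = max(np.max(np.abs(resid)), 1.0)
    tiny = (hi - lo) < floor * scale
    pad = 0.5 * floor * scale
    lo[tiny] -= pad
    hi[tiny] += pad
    return lo, hi


def _fallback_error_bounds(bounds: ParameterBounds) -> tuple[np.ndarray, np.ndarray]:
    """Corpus-free default: symmetric bounds from the model envelope band."""
    from .envelope import model_envelopes

    env_lo, env_hi = model_envelopes(GRID, bounds)
    ref_signal = synthesize_vector(bounds.reference, GRID)
    span = 1.5 * np.maximum(
        np.abs(env_hi - ref_signal), np.abs(env_lo - ref_signal)
    )[OBS_WINDOW_SLICE]
    span = np.maximum(span, 1e-3 * max(span.max(), 1.0))
    return -span, span


@dataclass
class EnvState:
    """Mutable per-episode state; ``vec`` is always in-box and order-valid."""

    vec: np.ndarray
    snr_db: float
    best_snr_db: float
    best_vec: np.ndarray
    step_index: int = 0
    steps_since_improvement: int = 0


def flatten_observation(obs: dict) -> np.ndarray:
    """Concatenate the dict observation into a single (274,) vector."""
    return np.concatenate([obs["params"], obs["errors"]])


class FittingEnv:
    """Episodic fitting environment for one target beat at a time."""

    def __init__(self, cfg: EnvConfig, grid: np.ndarray | None = None) -> None:
        self.cfg = cfg
        self.grid = GRID if grid is None else np.asarray(grid, dtype=float)
        self._target: np.ndarray | None = None
        self.state: EnvState | None = None
        b = cfg.bounds
        self._ref = b.reference
        self._param_scale = 2.0 / (b.upper - b.lower)
        self._err_scale = 2.0 / (cfg.error_obs_upper - cfg.error_obs_lower)

    # -- core contract ------------------------------------------------------

    def reset(self, target_beat: np.ndarray) -> dict:
        """Start an episode: estimate at the box reference point."""
        target = np.asarray(target_beat, dtype=float)
        if target.shape != self.grid.shape:
            raise ValueError(
                f"target shape {target.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(target)):
            raise ValueError("target beat contains non-finite values")
        self._target = target
        vec = self._ref.copy()
        snr = self._snr(vec)
        self.state = EnvState(
            vec=vec, snr_db=snr, best_snr_db=snr, best_vec=vec.copy()
        )
        return self._observe(vec)

    def step(self, action: np.ndarray) -> tuple[dict, float, bool, dict]:
        if self.state is None or self._target is None:
            raise RuntimeError("call reset() before step()")
        st = self.state
        new_vec = self.apply_action(st.vec, action)
        new_snr = self._snr(new_vec)
        reward = new_snr - st.snr_db
        st.vec = new_vec
        st.snr_db = new_snr
        st.step_index += 1
        if new_snr > st.best_snr_db:
            st.best_snr_db = new_snr
            st.best_vec = new_vec.copy()
            st.steps_since_improvement = 0
        else:
            st.steps_since_improvement += 1
        done, reason = self.is_terminal(st)
        info = {"snr_db": new_snr, "best_snr_db": st.best_snr_db}
        if done:
            info["termination_reason"] = reason
        return self._observe(new_vec), reward, done, info

    def is_terminal(self, state: EnvState) -> tuple[bool, str]:
        if state.step_index >= self.cfg.max_steps:
            return True, "max_steps"
        if state.steps_since_improvement >= self.cfg.patience:
            return True, "patience"
        return False, ""

    # -- constrained update -------------------------------------------------

    def apply_action(self, prev: np.ndarray, action: np.ndarray) -> np.ndarray:
        """Constrained update ``prev + a * reference`` (elementwise).

        Out-of-box actions are clipped to the action halfwidth.  Any
        component whose updated peak time would invert the ordering against
        either neighbor has its whole 4-parameter sub-update cancelled;
        cancellation is re-checked after box clipping until stable.
        """
        hw = self.cfg.action_halfwidth
        a = np.clip(np.asarray(action, dtype=float), -hw, hw)
        cand = self.cfg.bounds.clip(prev + a * self._ref)
        tp_prev = peak_times_vector(prev)
        tp_cand = peak_times_vector(cand)
        keep = np.ones(6, dtype=bool)
        for j in range(6):
            if j > 0 and tp_cand[j] <= tp_prev[j - 1]:
                keep[j] = False
            if j < 5 and tp_cand[j] >= tp_prev[j + 1]:
                keep[j] = False
        trial = np.where(np.repeat(keep, 4), cand, prev)
        for _ in range(_MAX_CANCEL_PASSES):
            tp = peak_times_vector(trial)
            bad = np.zeros(6, dtype=bool)
            viol = tp[:-1] >= tp[1:]
            if not viol.any():
                return trial
            for j in np.nonzero(viol)[0]:
                bad[j] = bad[j + 1] = True
            revert = bad & keep
            if not revert.any():  # pragma: no cover - prev is always valid
                break
            keep &= ~revert
            trial = np.where(np.repeat(keep, 4), cand, prev)
        return prev.copy()  # pragma: no cover - unreachable for valid prev

    # -- observations and reward pieces ------------------------------------

    def _snr(self, vec: np.ndarray) -> float:
        return snr_db(
            synthesize_vector(vec, self.grid), self._target,
            cap_db=self.cfg.snr_cap_db,
        )

    def error_observation(self, vec: np.ndarray) -> np.ndarray:
        """Windowed residual, min-max normalized per point into [-1, 1]."""
        resid = (self._target - synthesize_vector(vec, self.grid))[OBS_WINDOW_SLICE]
        normed = (resid - self.cfg.error_obs_lower) * self._err_scale - 1.0
        return np.clip(normed, -1.0, 1.0)

    def _observe(self, vec: np.ndarray) -> dict:
        params = np.clip((vec - self.cfg.bounds.lower) * self._param_scale - 1.0,
                         -1.0, 1.0)
        return {"params": params, "errors": self.error_observation(vec)}
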
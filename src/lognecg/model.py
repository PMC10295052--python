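"""Forward model: sums of time-shifted, scaled lognormal components.

A beat profile is modeled as six overlapping lognormal waves
(P, Q, R, S, and a positive/negative pair for the T wave).  Each wave is a
scaled, time-shifted lognormal density ``D * Lambda(t - t0; mu, sigma)``
with support strictly ``t > t0``.  All logs are natural logs.

Parameters live either on the per-beat *normalized* time axis (previous
R-peak at -1, own R-peak at 0, next R-peak at +1) or on the *seconds* axis;
the basis is tracked explicitly and converted with :func:`denormalize_params`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GRID",
    "N_PARAMS",
    "NORMALIZED",
    "PARAM_NAMES",
    "SECONDS",
    "VECTOR_FIELDS",
    "WAVE_LABELS",
    "InvalidParameterError",
    "InvalidScaleError",
    "LognormalComponent",
    "SigmaLognormalParams",
    "denormalize_params",
    "lognormal_density",
    "peak_time",
    "peak_times_vector",
    "synthesize",
    "synthesize_vector",
]

#: Fixed wave order.  ``Tp``/``Tm`` are the positive/negative T-wave halves.
WAVE_LABELS = ("P", "Q", "R", "S", "Tp", "Tm")
POSITIVE_WAVES = frozenset({"P", "R", "Tp"})
NEGATIVE_WAVES = frozenset({"Q", "S", "Tm"})
PARAM_NAMES = ("mu", "sigma", "t0", "D")
N_PARAMS = 24

#: Flat field names for the 24-vector, component-major:
#: ``P_mu, P_sigma, P_t0, P_D, Q_mu, ..., Tm_D``.
VECTOR_FIELDS = tuple(f"{w}_{p}" for w in WAVE_LABELS for p in PARAM_NAMES)

NORMALIZED = "normalized"
SECONDS = "seconds"
_BASES = (NORMALIZED, SECONDS)

#: Canonical 500-sample normalized-time grid.  Each half-beat contributes
#: 250 samples with a half-open convention, so the own R-peak sits exactly
#: at index 250 (normalized time 0) and the grid step is 1/250.
GRID = (np.arange(500) - 250) / 250.0
GRID.setflags(write=False)

_SQRT_2PI = np.sqrt(2.0 * np.pi)


class InvalidParameterError(ValueError):
    """A lognormal parameter violates its domain constraints."""


class InvalidScaleError(ValueError):
    """Time-scale factor must be strictly positive."""


def _unit_density(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Unit-area lognormal density evaluated at shifted time ``x``.

    Zero wherever ``x <= 0`` (causal support convention).
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros(x.shape, dtype=float)
    m = x > 0.0
    if np.any(m):
        xm = x[m]
        z = (np.log(xm) - mu) / sigma
        out[m] = np.exp(-0.5 * z * z) / (sigma * xm * _SQRT_2PI)
    return out


@dataclass(frozen=True)
class LognormalComponent:
    """One wave's parameter vector ``{mu, sigma, t0, D}`` plus its label.

    ``mu``/``sigma`` are the log-time location and spread, ``t0`` the onset
    time (support starts strictly after it) and ``D`` the signed
    amplitude-integral.  The sign of ``D`` is fixed by the label: positive
    for P, R, Tp; negative for Q, S, Tm (zero is allowed).
    """

    label: str
    mu: float
    sigma: float
    t0: float
    D: float

    def __post_init__(self) -> None:
        if self.label not in WAVE_LABELS:
            raise InvalidParameterError(
                f"unknown wave label {self.label!r}; expected one of {WAVE_LABELS}"
            )
        for name in ("mu", "sigma", "t0", "D"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{self.label}.{name} is not finite")
        if self.sigma <= 0.0:
            raise InvalidParameterError(
                f"{self.label}.sigma must be > 0, got {self.sigma}"
            )
        if self.label in POSITIVE_WAVES and self.D < 0.0:
            raise InvalidParameterError(
                f"{self.label}.D must be >= 0, got {self.D}"
            )
        if self.label in NEGATIVE_WAVES and self.D > 0.0:
            raise InvalidParameterError(
                f"{self.label}.D must be <= 0, got {self.D}"
            )


def lognormal_density(t, comp: LognormalComponent) -> np.ndarray:
    """Evaluate ``D * Lambda(t - t0; mu, sigma)`` on a time grid.

    Returns exactly 0 wherever ``t <= t0`` and is finite everywhere.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidParameterError("time grid contains non-finite values")
    return comp.D * _unit_density(t - comp.t0, comp.mu, comp.sigma)


def peak_time(comp: LognormalComponent) -> float:
    """Mode abscissa ``t0 + exp(mu - sigma**2)`` of the component."""
    return comp.t0 + np.exp(comp.mu - comp.sigma**2)


@dataclass(frozen=True)
class SigmaLognormalParams:
    """Ordered six-component parameter set for one beat (24 free scalars).

    Construction enforces the canonical wave order and strictly increasing
    component peak times; equal peak times are rejected as degenerate.
    """

    components: tuple[LognormalComponent, ...]
    time_basis: str = NORMALIZED

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) != 6:
            raise InvalidParameterError(
                f"expected 6 components, got {len(comps)}"
            )
        labels = tuple(c.label for c in comps)
        if labels != WAVE_LABELS:
            raise InvalidParameterError(
                f"components must be ordered {WAVE_LABELS}, got {labels}"
            )
        if self.time_basis not in _BASES:
            raise InvalidParameterError(
                f"time_basis must be one of {_BASES}, got {self.time_basis!r}"
            )
        tp = [peak_time(c) for c in comps]
        for a, b, la, lb in zip(tp, tp[1:], labels, labels[1:]):
            if not a < b:
                raise InvalidParameterError(
                    f"peak times must be strictly increasing: "
                    f"t_p({la})={a:.6g} !< t_p({lb})={b:.6g}"
                )

    # -- flat-vector and record interchange ---------------------------------

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical 24-vector (component-major)."""
        return np.array(
            [getattr(c, p) for c in self.components for p in PARAM_NAMES],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, vec, time_basis: str = NORMALIZED) -> "SigmaLognormalParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_PARAMS,):
            raise InvalidParameterError(
                f"expected shape ({N_PARAMS},), got {vec.shape}"
            )
        comps = tuple(
            LognormalComponent(label, *vec[4 * i : 4 * i + 4])
            for i, label in enumerate(WAVE_LABELS)
        )
        return cls(components=comps, time_basis=time_basis)

    def to_record(self) -> dict:
        """Flat mapping with the 24 named fields plus ``time_basis``."""
        rec = {
            name: float(v) for name, v in zip(VECTOR_FIELDS, self.to_vector())
        }
        rec["time_basis"] = self.time_basis
        return rec

    @classmethod
    def from_record(cls, rec: Mapping) -> "SigmaLognormalParams":
        missing = [k for k in VECTOR_FIELDS if k not in rec]
        if missing:
            raise InvalidParameterError(f"record missing fields: {missing}")
        vec = np.array([float(rec[k]) for k in VECTOR_FIELDS])
        return cls.from_vector(vec, time_basis=rec.get("time_basis", NORMALIZED))

    def peak_times(self) -> np.ndarray:
        return np.array([peak_time(c) for c in self.components])


def synthesize(params: SigmaLognormalParams, t=None) -> np.ndarray:
    """Pointwise sum of the six ``D * Lambda`` terms on grid ``t``.

    Defaults to the canonical 500-sample normalized grid.
    """
    if t is None:
        t = GRID
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape, dtype=float)
    for comp in params.components:
        out += lognormal_density(t, comp)
    return out


def denormalize_params(
    params: SigmaLognormalParams, alpha: float
) -> SigmaLognormalParams:
    """Rescale normalized-basis parameters to seconds with factor ``alpha``.

    Applies ``{mu + ln(alpha), sigma, alpha * t0, alpha * D}`` per component,
    which keeps the profile numerically identical under ``t* = alpha * t``.
    """
    if not (np.isfinite(alpha) and alpha > 0.0):
        raise InvalidScaleError(f"alpha must be > 0, got {alpha}")
    if params.time_basis != NORMALIZED:
        raise InvalidParameterError(
            f"denormalize_params expects normalized basis, got {params.time_basis!r}"
        )
    log_a = float(np.log(alpha))
    comps = tuple(
        replace(c, mu=c.mu + log_a, t0=alpha * c.t0, D=alpha * c.D)
        for c in params.components
    )
    return SigmaLognormalParams(components=comps, time_basis=SECONDS)


# -- fast flat-vector kernels (used by the fitting environment) -------------


def synthesize_vector(vec: np.ndarray, t=None) -> np.ndarray:
    """Like :func:`synthesize` but on a raw 24-vector, skipping validation."""
    if t is None:
        t = GRID
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape, dtype=float)
    for i in range(6):
        mu, sigma, t0, D = vec[4 * i : 4 * i + 4]
        if D != 0.0:
            out += D * _unit_density(t - t0, mu, sigma)
    return out


def peak_times_vector(vec: np.ndarray) -> np.ndarray:
    """Component peak times ``t0 + exp(mu - sigma**2)`` from a raw 24-vector."""
    v = np.asarray(vec, dtype=float).reshape(6, 4)
    return v[:, 2] + np.exp(v[:, 0] - v[:, 1] ** 2)
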
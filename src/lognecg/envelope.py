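"""Closed-form pointwise envelopes of lognormal components over a parameter box.

For a single unit-amplitude component with parameters constrained to a box,
the lower envelope is the pointwise minimum over five corner evaluations and
the upper envelope is an explicit ten-branch piecewise curve whose interior
branches maximize over one parameter at a time (sigma* = mu - ln x on the
rising edge, mu* = ln x across the peak plateau, sigma* = ln x - mu on the
falling edge).  Signed sums over the six components give the band containing
every beat profile producible from in-box parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import _unit_density
from .bounds import ParameterBounds
from .model import WAVE_LABELS

__all__ = [
    "ComponentBox",
    "component_boxes",
    "component_lower_envelope",
    "component_upper_envelope",
    "model_envelopes",
]


@dataclass(frozen=True)
class ComponentBox:
    """Scalar lower/upper bounds for one component's four parameters."""

    mu_lo: float
    mu_hi: float
    sigma_lo: float
    sigma_hi: float
    t0_lo: float
    t0_hi: float
    D_lo: float
    D_hi: float

    def __post_init__(self) -> None:
        for p in ("mu", "sigma", "t0", "D"):
            lo, hi = getattr(self, f"{p}_lo"), getattr(self, f"{p}_hi")
            if not lo <= hi:
                raise ValueError(f"{p}_lo={lo} > {p}_hi={hi}")
        if self.sigma_lo <= 0.0:
            raise ValueError(f"sigma_lo must be > 0, got {self.sigma_lo}")
        if self.sigma_hi >= 1.0:
            # breakpoint ordering below relies on sigma**2 < sigma
            raise ValueError("upper envelope requires sigma_hi < 1")


def component_boxes(bounds: ParameterBounds) -> dict[str, ComponentBox]:
    """Split a 24-parameter box into the six per-component boxes."""
    out = {}
    for i, label in enumerate(WAVE_LABELS):
        lo = bounds.lower[4 * i : 4 * i + 4]
        hi = bounds.upper[4 * i : 4 * i + 4]
        out[label] = ComponentBox(
            mu_lo=lo[0], mu_hi=hi[0],
            sigma_lo=lo[1], sigma_hi=hi[1],
            t0_lo=lo[2], t0_hi=hi[2],
            D_lo=lo[3], D_hi=hi[3],
        )
    return out


def component_lower_envelope(t, box: ComponentBox) -> np.ndarray:
    """Pointwise minimum over the five corner evaluations (unit amplitude)."""
    t = np.asarray(t, dtype=float)
    return np.minimum.reduce(
        [
            _unit_density(t - box.t0_hi, box.mu_hi, box.sigma_lo),
            _unit_density(t - box.t0_hi, box.mu_hi, box.sigma_hi),
            _unit_density(t - box.t0_lo, box.mu_hi, box.sigma_hi),
            _unit_density(t - box.t0_lo, box.mu_lo, box.sigma_hi),
            _unit_density(t - box.t0_lo, box.mu_lo, box.sigma_lo),
        ]
    )


def component_upper_envelope(t, box: ComponentBox) -> np.ndarray:
    """Exact piecewise upper envelope of the unit-amplitude density.

    Branch intervals are left-open/right-closed between the nine printed
    breakpoints; the curve is continuous across them.
    """
    t = np.asarray(t, dtype=float)
    mu_lo, mu_hi = box.mu_lo, box.mu_hi
    s_lo, s_hi = box.sigma_lo, box.sigma_hi
    t0_lo, t0_hi = box.t0_lo, box.t0_hi

    b = np.array(
        [
            t0_lo,
            t0_lo + np.exp(mu_lo - s_hi),
            t0_lo + np.exp(mu_lo - s_lo),
            t0_lo + np.exp(mu_lo - s_lo**2),
            t0_hi + np.exp(mu_lo - s_lo**2),
            t0_hi + np.exp(mu_lo),
            t0_hi + np.exp(mu_hi),
            t0_hi + np.exp(mu_hi + s_lo),
            t0_hi + np.exp(mu_hi + s_hi),
        ]
    )
    x_lo = t - t0_lo
    x_hi = t - t0_hi
    out = np.zeros(t.shape, dtype=float)

    def _between(a: float, bb: float) -> np.ndarray:
        return (t > a) & (t <= bb)

    m = _between(b[0], b[1])  # rising tail, earliest onset, widest spread
    out[m] = _unit_density(x_lo[m], mu_lo, s_hi)

    m = _between(b[1], b[2])  # rising edge: maximize over sigma at fixed x
    if np.any(m):
        sig = mu_lo - np.log(x_lo[m])
        z = (np.log(x_lo[m]) - mu_lo) / sig
        out[m] = np.exp(-0.5 * z * z) / (sig * x_lo[m] * np.sqrt(2.0 * np.pi))

    m = _between(b[2], b[3])  # approach to the mode with narrowest spread
    out[m] = _unit_density(x_lo[m], mu_lo, s_lo)

    m = _between(b[3], b[4])  # peak plateau: mode value, t0 sliding across
    out[m] = _unit_density(np.exp(mu_lo - s_lo**2), mu_lo, s_lo)

    m = _between(b[4], b[5])  # just past the mode, latest onset
    out[m] = _unit_density(x_hi[m], mu_lo, s_lo)

    m = _between(b[5], b[6])  # maximize over mu at fixed x (mu* = ln x, z = 0)
    if np.any(m):
        out[m] = 1.0 / (s_lo * x_hi[m] * np.sqrt(2.0 * np.pi))

    m = _between(b[6], b[7])  # falling edge, largest mu, narrowest spread
    out[m] = _unit_density(x_hi[m], mu_hi, s_lo)

    m = _between(b[7], b[8])  # falling edge: maximize over sigma at fixed x
    if np.any(m):
        sig = np.log(x_hi[m]) - mu_hi
        z = (np.log(x_hi[m]) - mu_hi) / sig
        out[m] = np.exp(-0.5 * z * z) / (sig * x_hi[m] * np.sqrt(2.0 * np.pi))

    m = t > b[8]  # far tail, widest spread
    out[m] = _unit_density(x_hi[m], mu_hi, s_hi)

    return out


def model_envelopes(
    t, bounds: ParameterBounds
) -> tuple[np.ndarray, np.ndarray]:
    """Signed lower/upper envelope sums over the six components.

    Each component contributes ``D_lo * (lower if D_lo > 0 else upper)`` to
    the lower sum and ``D_hi * (upper if D_hi > 0 else lower)`` to the upper
    sum; a zero amplitude bound contributes nothing.
    """
    t = np.asarray(t, dtype=float)
    lower = np.zeros(t.shape, dtype=float)
    upper = np.zeros(t.shape, dtype=float)
    for box in component_boxes(bounds).values():
        env_lo = component_lower_envelope(t, box)
        env_hi = component_upper_envelope(t, box)
        lower += box.D_lo * (env_lo if box.D_lo > 0.0 else env_hi)
        upper += box.D_hi * (env_hi if box.D_hi > 0.0 else env_lo)
    return lower, upper
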
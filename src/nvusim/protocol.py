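"""Smoothed step-like perturbation protocol for the pressure drive.

The cerebral-blood-flow change is imposed by multiplying both boundary
pressures by a shift function f(t): identically 1 before the smoothing
window, 1 -/+ a after it (decrease/increase), with a C1 cosine ramp of
width ``dt_smooth`` centred on the shift time ``t0`` (the mid-point of
the transition, where f = 1 -/+ a/2).
"""

from __future__ import annotations

import numpy as np

from .config import ValidationError


def smooth_step(t, t0: float, dt_smooth: float, a: float,
                direction: str = "decrease"):
    """Shift multiplier f(t).  Accepts scalar or array ``t``.

    ``direction`` is ``baseline`` (f == 1), ``decrease`` (f -> 1-a) or
    ``increase`` (f -> 1+a).  The terminal amplitude must satisfy
    0.5 <= a < 1 for a non-baseline protocol.
    """
    if direction == "baseline":
        return np.ones_like(np.asarray(t, dtype=float)) if np.ndim(t) else 1.0
    if direction not in ("decrease", "increase"):
        raise ValidationError(f"unknown protocol direction '{direction}'")
    if not (0.5 <= a < 1.0):
        raise ValidationError("protocol amplitude must satisfy 0.5 <= a < 1")
    if dt_smooth <= 0.0:
        raise ValidationError("dt_smooth must be positive")
    t_arr = np.asarray(t, dtype=float)
    t_lo = t0 - dt_smooth / 2.0
    phase = np.clip((t_arr - t_lo) / dt_smooth, 0.0, 1.0)
    delta = a * (1.0 - np.cos(np.pi * phase)) / 2.0
    f = 1.0 - delta if direction == "decrease" else 1.0 + delta
    return float(f) if np.ndim(t) == 0 else f
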
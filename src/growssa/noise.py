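"""Multiplicative Ornstein-Uhlenbeck extrinsic noise.

A single mean-reverting process eta(t) is shared across all flagged rate
constants; the effective rate is ``k * exp(eta)`` so positivity is automatic.
The process is advanced with the exact OU transition at every engine event,
i.e. eta is piecewise constant between events.
"""

from __future__ import annotations

import math

import numpy as np

from .model import OUParams

__all__ = ["OUParams", "ou_step", "apply_noise"]


def ou_step(eta: float, dt: float, params: OUParams, rng) -> float:
    """Exact OU transition over an interval of length ``dt`` seconds.

    ``eta' = eta * exp(-dt/tau_c) + sigma * sqrt(1 - exp(-2*dt/tau_c)) * z``
    with ``z`` standard normal.  The stationary law is Normal(0, sigma^2).
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0.0:
        return eta
    decay = math.exp(-dt / params.tau_c)
    if params.sigma == 0.0:
        # still draw so the noise stream stays aligned across configurations
        rng.standard_normal()
        return eta * decay
    z = rng.standard_normal()
    return eta * decay + params.sigma * math.sqrt(1.0 - decay * decay) * z


def apply_noise(rates: dict, eta: float, params: OUParams | None = None) -> dict:
    """Scale flagged rate constants by exp(eta).

    If ``params`` is given only rates named in ``params.applied_to`` are
    scaled; otherwise all are.
    """
    if not math.isfinite(eta):
        raise ValueError("eta must be finite")
    factor = math.exp(eta)
    targets = None if params is None else set(params.applied_to)
    return {
        name: (k * factor if targets is None or name in targets else k)
        for name, k in rates.items()
    }
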
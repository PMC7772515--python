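"""Independent reference implementations used as test oracles.

These deliberately avoid the package's code paths: MI by explicit joint-
table enumeration, LIF by fixed-step integration, aggregates by brute-
force re-summation.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def mi_table(x, y) -> float:
    """Mutual information (bits) by explicit enumeration of the 2x2 joint."""
    n = len(x)
    joint = Counter(zip(map(int, x), map(int, y)))
    px = Counter(map(int, x))
    py = Counter(map(int, y))
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log2(p_ab / ((px[a] / n) * (py[b] / n)))
    return mi


def entropy(x) -> float:
    n = len(x)
    return -sum((c / n) * math.log2(c / n) for c in Counter(map(int, x)).values())


def lif_fixed_step(
    event_steps: np.ndarray,
    event_jumps: np.ndarray,
    n_steps: int,
    dt: float,
    v_rest: float,
    v_reset: float,
    theta: float,
    tau: float,
    refractory: float,
) -> np.ndarray:
    """Fixed-step LIF reference: exact per-step decay factor e^(-dt/tau),
    events applied at their grid step, strict threshold check each step,
    absolute refractory lockout without reset.  Returns spike times."""
    jumps = np.zeros(n_steps)
    np.add.at(jumps, event_steps, event_jumps)
    alpha = math.exp(-dt / tau)
    v = v_rest
    last_spike = -math.inf
    spikes = []
    hot = np.flatnonzero(jumps != 0.0)  # V can only cross theta at event steps
    prev = 0
    for k in hot:
        v = v_rest + (v - v_rest) * alpha ** (k - prev)
        v += jumps[k]
        t = k * dt
        if v > theta and (t - last_spike) >= refractory:
            spikes.append(t)
            v = v_reset
            last_spike = t
        prev = k
    return np.array(spikes)


def lif_forward_euler(
    event_steps: np.ndarray,
    event_jumps: np.ndarray,
    n_steps: int,
    dt: float,
    v_rest: float,
    v_reset: float,
    theta: float,
    tau: float,
    refractory: float,
) -> np.ndarray:
    """Plain forward-Euler LIF (first-order decay each step)."""
    jumps = np.zeros(n_steps)
    np.add.at(jumps, event_steps, event_jumps)
    v = v_rest
    last_spike = -math.inf
    spikes = []
    for k in range(n_steps):
        v += -(v - v_rest) * dt / tau
        if jumps[k] != 0.0:
            v += jumps[k]
        t = k * dt
        if v > theta and (t - last_spike) >= refractory:
            spikes.append(t)
            v = v_reset
            last_spike = t
    return np.array(spikes)
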
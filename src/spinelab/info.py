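"""Mutual information between binarized, binned input and spike sequences.

Spike trains are binned into 5-ms intervals and binarized (1 if at least
one event falls in the bin).  Information transfer is the plug-in mutual
information over the empirical 2x2 joint distribution,

    MI = sum_{x,y} p(x, y) log2 p(x, y) / (p(x) p(y)),

with the 0 log 0 = 0 convention, reported in bits per bin.  The analysis
targets the strongest synapse of each branch: MI(DS; SI) between that
synapse's input sequence and the branch's dendritic spikes, and
MI(SS; SI) against the somatic spike sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spinelab.twolayer import ModelParams, SimulationResult, run_simulation

__all__ = [
    "BIN_MS",
    "binarize",
    "mutual_information",
    "binary_entropy",
    "mi_vs_dendrite",
    "mi_vs_soma",
    "MICurve",
    "tuning_curve",
]

BIN_MS = 5.0


def binarize(
    event_times: np.ndarray, duration_ms: float, bin_ms: float = BIN_MS
) -> np.ndarray:
    """Binary occupancy of consecutive ``bin_ms`` bins anchored at t = 0.

    Bit k is 1 iff at least one event lies in [k*bin, (k+1)*bin).  A
    trailing partial bin is dropped.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be > 0")
    n_bins = int(duration_ms // bin_ms)
    bits = np.zeros(n_bins, dtype=np.uint8)
    if n_bins == 0:
        return bits
    t = np.asarray(event_times, dtype=float)
    idx = (t // bin_ms).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    bits[idx] = 1
    return bits


def _joint_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    c = np.zeros((2, 2), dtype=np.int64)
    xi = x.astype(np.int64)
    yi = y.astype(np.int64)
    np.add.at(c, (xi, yi), 1)
    return c


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two binary sequences."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError(f"sequence lengths differ: {x.size} != {y.size}")
    if x.size == 0:
        raise ValueError("sequences must be non-empty")
    joint = _joint_counts(x, y) / x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for a in range(2):
        for b in range(2):
            p = joint[a, b]
            if p > 0:
                mi += p * np.log2(p / (px[a] * py[b]))
    return max(float(mi), 0.0)  # clamp -0.0 from rounding


def binary_entropy(x: np.ndarray) -> float:
    """Plug-in entropy (bits) of a binary sequence."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("sequence must be non-empty")
    p = float(np.mean(x))
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0:
            h -= q * np.log2(q)
    return h


def mi_vs_dendrite(result: SimulationResult, bin_ms: float = BIN_MS) -> np.ndarray:
    """Per-branch MI(DS; SI): strongest-synapse input bits versus the same
    branch's dendritic spike bits."""
    duration = result.params.duration
    out = np.empty(result.params.n_branch)
    for j in range(result.params.n_branch):
        si = binarize(result.strongest_inputs[j], duration, bin_ms)
        ds = binarize(result.dendritic_trains[j], duration, bin_ms)
        out[j] = mutual_information(si, ds)
    return out


def mi_vs_soma(result: SimulationResult, bin_ms: float = BIN_MS) -> np.ndarray:
    """Per-branch MI(SS; SI): strongest-synapse input bits versus the
    somatic spike bits."""
    duration = result.params.duration
    ss = binarize(result.somatic_train, duration, bin_ms)
    out = np.empty(result.params.n_branch)
    for j in range(result.params.n_branch):
        si = binarize(result.strongest_inputs[j], duration, bin_ms)
        out[j] = mutual_information(si, ss)
    return out


@dataclass
class MICurve:
    """MI tuning curve over input frequency (branch-averaged, across trials)."""

    frequencies: np.ndarray  # Hz
    mi_dend_mean: np.ndarray  # bits per bin
    mi_dend_sd: np.ndarray
    mi_soma_mean: np.ndarray
    mi_soma_sd: np.ndarray
    n_trials: int
    case: int
    params: ModelParams

    @property
    def optimal_frequency_dend(self) -> float:
        return float(self.frequencies[int(np.argmax(self.mi_dend_mean))])

    @property
    def optimal_frequency_soma(self) -> float:
        return float(self.frequencies[int(np.argmax(self.mi_soma_mean))])


def tuning_curve(
    params: ModelParams,
    case: int,
    freqs: np.ndarray,
    n_trials: int,
    rng: np.random.Generator,
    bin_ms: float = BIN_MS,
) -> MICurve:
    """MI versus input frequency: for each frequency, ``n_trials``
    independent simulations; per trial the branch-mean MI is taken, and
    mean +/- SD across trials is reported for the dendritic and somatic
    comparisons.  Frequencies outside the studied 0.5-10 Hz band are
    accepted with a warning.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be > 0")
    if np.any((freqs < 0.5) | (freqs > 10.0)):
        import warnings

        warnings.warn("frequency outside the studied 0.5-10 Hz band", stacklevel=2)
    dend = np.empty((freqs.size, n_trials))
    soma = np.empty((freqs.size, n_trials))
    for fi, f in enumerate(freqs):
        for t in range(n_trials):
            res = run_simulation(params.with_(input_freq=float(f)), case, rng)
            dend[fi, t] = mi_vs_dendrite(res, bin_ms).mean()
            soma[fi, t] = mi_vs_soma(res, bin_ms).mean()
    return MICurve(
        frequencies=freqs,
        mi_dend_mean=dend.mean(axis=1),
        mi_dend_sd=dend.std(axis=1, ddof=1) if n_trials > 1 else np.zeros(freqs.size),
        mi_soma_mean=soma.mean(axis=1),
        mi_soma_sd=soma.std(axis=1, ddof=1) if n_trials > 1 else np.zeros(freqs.size),
        n_trials=n_trials,
        case=case,
        params=params,
    )
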
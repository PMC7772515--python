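"""Synthetic morphometry, contour-stack, and uncaging-trace generation.

The generator emulates the region-level summary statistics of FIB/SEM
spine reconstructions (per-region spine density, lognormal head volumes,
truncated-Gaussian neck metrics, a linear-with-noise PSD/head-volume
coupling, diameter scaling of PSD-area density, axon-coupled spine pairs,
and ER-containing spine enrichment) so that every downstream pipeline
stage is testable without imaging data.

Distributional choices
----------------------
* Head volumes are lognormal: the measured distributions are strongly
  right-skewed with 11- to 204-fold max/min ranges, which a lognormal
  reproduces from the printed mean/SD alone.
* Neck lengths, neck diameters, and per-dendrite spine densities are
  truncated Gaussians with a positive floor.  The underlying location and
  scale are MOMENT-MATCHED numerically so the truncated distribution has
  exactly the configured mean and SD (naive truncation of, e.g.,
  N(0.46, 0.246^2) at zero would bias the mean by ~4%, which is larger
  than the Monte-Carlo error at the sample sizes used for recovery checks).
* PSD area = slope x head volume + Gaussian noise, truncated at a small
  positive floor; the noise SD controls the induced PSD/head-volume rank
  correlation.
* ER-positive spines get a multiplicative head-volume boost; all head
  volumes are then rescaled by 1/(1 - p + p*boost) so the configured
  overall mean head volume is preserved exactly.
* Axon-coupled spines are realised as randomly paired same-dendrite
  spines sharing an axon ID; pair members receive PSD areas redrawn
  around the pair mean with reduced intra-pair variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, stats

from spinelab.uncaging import UncagingTraceSet

__all__ = [
    "ConfigError",
    "RegionConfig",
    "SyntheticDataset",
    "generate_region",
    "generate_contour_stack",
    "generate_uncaging_traces",
    "lognormal_params",
    "REGION_PRESETS",
]

PSD_FLOOR = 1e-3  # um^2, smallest representable PSD after additive noise


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Location/shape (mu, sigma) of the lognormal with given mean and SD."""
    if mean <= 0 or sd < 0:
        raise ValueError("lognormal moments require mean > 0 and sd >= 0")
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _truncnorm_match(
    mean: float, sd: float, floor: float = 0.0
) -> tuple[float, float]:
    """Underlying (mu, sigma) of a Gaussian truncated at ``floor`` whose
    truncated mean and SD equal the requested values."""
    if sd == 0:
        return mean, 0.0
    z = (mean - floor) / sd
    if z > 8.0:  # truncation numerically irrelevant
        return mean, sd

    def resid(p: np.ndarray) -> np.ndarray:
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a = (floor - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return np.array([m - mean, math.sqrt(v) - sd])

    sol = optimize.fsolve(resid, np.array([mean, math.log(sd)]), full_output=False)
    mu, sigma = float(sol[0]), math.exp(float(sol[1]))
    return mu, sigma


def _sample_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, size: int, floor: float = 0.0
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    mu, sigma = _truncnorm_match(mean, sd, floor)
    a = (floor - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=size, random_state=rng)


@dataclass(frozen=True)
class RegionConfig:
    """Generator configuration for one brain region.

    ``head_volume_logmu``/``head_volume_logsigma`` parametrise the
    lognormal head-volume distribution (log um^3); ``psd_per_volume_slope``
    (um^2/um^3) and ``psd_noise_sd`` (um^2) set the PSD/head-volume
    coupling; ``psd_density_slope`` (um^2/um per um of diameter) scales
    per-dendrite PSD-area density with dendritic diameter;
    ``axon_coupling_rate`` is the fraction of spines sharing an axon with
    a same-dendrite partner; ``er_fraction``/``er_size_boost`` control the
    ER-positive subpopulation.
    """

    region_label: str
    spine_density_mean: float
    spine_density_sd: float
    head_volume_logmu: float
    head_volume_logsigma: float
    neck_length_mean: float
    neck_length_sd: float
    neck_diameter_mean: float
    neck_diameter_sd: float
    psd_per_volume_slope: float
    psd_noise_sd: float
    diameter_range: tuple[float, float]
    psd_density_slope: float = 0.0
    axon_coupling_rate: float = 0.0
    er_fraction: float = 0.0
    er_size_boost: float = 1.0
    dendrite_length_range: tuple[float, float] = (5.0, 25.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("axon_coupling_rate", "er_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "spine_density_mean",
            "neck_length_mean",
            "neck_diameter_mean",
            "psd_per_volume_slope",
            "er_size_boost",
        ):
            v = getattr(self, name)
            if v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        for name in (
            "spine_density_sd",
            "head_volume_logsigma",
            "neck_length_sd",
            "neck_diameter_sd",
            "psd_noise_sd",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if self.spine_density_sd >= self.spine_density_mean:
            raise ConfigError(
                "spine_density_sd must be smaller than spine_density_mean "
                f"({self.spine_density_sd} >= {self.spine_density_mean})"
            )
        for name in ("diameter_range", "dendrite_length_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")

    @classmethod
    def from_moments(
        cls, head_volume_mean: float, head_volume_sd: float, **kwargs
    ) -> "RegionConfig":
        """Build a config from the natural-unit head-volume mean/SD."""
        mu, sigma = lognormal_params(head_volume_mean, head_volume_sd)
        return cls(head_volume_logmu=mu, head_volume_logsigma=sigma, **kwargs)

    def with_seed(self, seed: int) -> "RegionConfig":
        return replace(self, seed=int(seed))

    @property
    def head_volume_mean(self) -> float:
        return math.exp(self.head_volume_logmu + self.head_volume_logsigma**2 / 2.0)


@dataclass
class SyntheticDataset:
    """Generated spine and dendrite tables plus their provenance."""

    spines: pd.DataFrame
    dendrites: pd.DataFrame
    provenance: RegionConfig

    def __len__(self) -> int:
        return len(self.spines)


# ---------------------------------------------------------------------------
# region-level morphometry presets
#
# Configured from the published per-region summary tables: spine density and
# head/neck dimensions (mean +/- SD), dendritic diameter, PSD-area density
# (which fixes the PSD-per-head-volume slope via mean PSD = density slope x
# mean head volume), axon-coupled spine frequency, and ER-containing spine
# frequency with the ER+/ER- head-volume contrast as the size boost.  PSD
# noise SDs were calibrated once so the induced head-volume/PSD Spearman
# correlations match the reported region values (0.42-0.89).

def _preset(
    label: str,
    density: tuple[float, float],
    head_volume: tuple[float, float],
    neck_length: tuple[float, float],
    neck_diameter: tuple[float, float],
    diameter: tuple[float, float],
    psd_slope: float,
    psd_noise_sd: float,
    psd_density_slope: float,
    axon_rate: float,
    er_fraction: float,
    er_boost: float,
) -> RegionConfig:
    mu, sigma = lognormal_params(*head_volume)
    d_mean, d_sd = diameter
    half = d_sd * math.sqrt(3.0)  # uniform with matching SD
    return RegionConfig(
        region_label=label,
        spine_density_mean=density[0],
        spine_density_sd=density[1],
        head_volume_logmu=mu,
        head_volume_logsigma=sigma,
        neck_length_mean=neck_length[0],
        neck_length_sd=neck_length[1],
        neck_diameter_mean=neck_diameter[0],
        neck_diameter_sd=neck_diameter[1],
        psd_per_volume_slope=psd_slope,
        psd_noise_sd=psd_noise_sd,
        diameter_range=(d_mean - half, d_mean + half),
        psd_density_slope=psd_density_slope,
        axon_coupling_rate=axon_rate,
        er_fraction=er_fraction,
        er_size_boost=er_boost,
    )


REGION_PRESETS: dict[str, RegionConfig] = {
    "CA1_PSR": _preset(
        "CA1_PSR",
        density=(3.04, 0.825),
        head_volume=(0.05, 0.045),
        neck_length=(0.46, 0.246),
        neck_diameter=(0.20, 0.087),
        diameter=(0.59, 0.104),
        psd_slope=1.18,
        psd_noise_sd=0.022,
        psd_density_slope=0.41,
        axon_rate=0.047,
        er_fraction=0.136,
        er_boost=2.75,
    ),
    "CA1_SLM": _preset(
        "CA1_SLM",
        density=(0.75, 0.360),
        head_volume=(0.12, 0.086),
        neck_length=(0.49, 0.289),
        neck_diameter=(0.25, 0.127),
        diameter=(0.58, 0.097),
        psd_slope=0.89,
        psd_noise_sd=0.020,
        psd_density_slope=0.0,
        axon_rate=0.257,
        er_fraction=0.157,
        er_boost=1.64,
    ),
    "cortex": _preset(
        "cortex",
        density=(1.14, 0.723),
        head_volume=(0.08, 0.101),
        neck_length=(1.09, 0.561),
        neck_diameter=(0.23, 0.121),
        diameter=(0.65, 0.141),
        psd_slope=1.21,
        psd_noise_sd=0.025,
        psd_density_slope=0.19,
        axon_rate=0.054,
        er_fraction=0.403,
        er_boost=3.75,
    ),
    "striatum": _preset(
        "striatum",
        density=(1.94, 0.621),
        head_volume=(0.07, 0.109),
        neck_length=(1.12, 0.556),
        neck_diameter=(0.26, 0.104),
        diameter=(0.77, 0.096),
        psd_slope=1.10,
        psd_noise_sd=0.025,
        psd_density_slope=0.0,
        axon_rate=0.089,
        er_fraction=0.551,
        er_boost=5.0,
    ),
    "CB": _preset(
        "CB",
        density=(7.10, 1.693),
        head_volume=(0.13, 0.035),
        neck_length=(0.74, 0.300),
        neck_diameter=(0.27, 0.054),
        diameter=(1.02, 0.226),
        psd_slope=0.83,
        psd_noise_sd=0.065,
        psd_density_slope=0.74,
        axon_rate=0.261,
        er_fraction=1.0,
        er_boost=1.0,
    ),
}


# ---------------------------------------------------------------------------


def generate_region(config: RegionConfig, n_dendrites: int) -> SyntheticDataset:
    """Generate spine and dendrite tables for one region.

    Per dendrite: a length and diameter are drawn, a spine count is set
    from a truncated-Gaussian density draw times the length, and spine
    dimensions are drawn from the configured distributions.  PSD areas
    couple linearly to head volume with additive Gaussian noise and a
    diameter-dependent scaling of the dendrite's PSD budget; ER-positive
    spines are upweighted in head volume (overall mean preserved); a
    configured fraction of spines is paired into axon-coupled doublets.
    """
    if n_dendrites < 1:
        raise ConfigError(f"n_dendrites must be >= 1, got {n_dendrites}")
    config.validate()
    rng = np.random.default_rng(config.seed)

    diam_lo, diam_hi = config.diameter_range
    diam_mid = 0.5 * (diam_lo + diam_hi)
    # baseline PSD-area density sets the scale of the diameter modulation
    base_psd_density = (
        config.spine_density_mean
        * config.psd_per_volume_slope
        * config.head_volume_mean
    )
    er_scale = 1.0 / (1.0 - config.er_fraction + config.er_fraction * config.er_size_boost)

    dend_rows = []
    spine_frames = []
    axon_counter = 0
    for d in range(n_dendrites):
        did = f"{config.region_label}_d{d:04d}"
        length = rng.uniform(*config.dendrite_length_range)
        diameter = rng.uniform(diam_lo, diam_hi)
        density = float(
            _sample_truncnorm(rng, config.spine_density_mean, config.spine_density_sd, 1)[0]
        )
        n = int(round(density * length))
        dend_rows.append(
            {
                "dendrite_id": did,
                "region": config.region_label,
                "length_um": length,
                "diameter_um": diameter,
            }
        )
        if n == 0:
            continue

        position = np.sort(rng.uniform(0.0, length, n))
        head_volume = rng.lognormal(
            config.head_volume_logmu, config.head_volume_logsigma, n
        )
        er = rng.random(n) < config.er_fraction
        head_volume = head_volume * er_scale
        head_volume[er] *= config.er_size_boost
        neck_length = _sample_truncnorm(
            rng, config.neck_length_mean, config.neck_length_sd, n, floor=0.01
        )
        neck_diameter = _sample_truncnorm(
            rng, config.neck_diameter_mean, config.neck_diameter_sd, n, floor=0.01
        )

        # diameter modulation of the dendrite's PSD budget
        if config.psd_density_slope != 0.0 and base_psd_density > 0:
            f_d = 1.0 + config.psd_density_slope * (diameter - diam_mid) / base_psd_density
            f_d = max(f_d, 0.05)
        else:
            f_d = 1.0
        psd = config.psd_per_volume_slope * head_volume * f_d
        if config.psd_noise_sd > 0:
            psd = psd + rng.normal(0.0, config.psd_noise_sd, n)
        psd = np.maximum(psd, PSD_FLOOR)

        # axon coupling: pair 2*k randomly chosen spines, unbiased rounding
        axon_id = np.array(
            [f"ax{axon_counter + i:07d}" for i in range(n)], dtype=object
        )
        axon_counter += n
        expected_pairs = config.axon_coupling_rate * n / 2.0
        k = int(math.floor(expected_pairs))
        if rng.random() < expected_pairs - k:
            k += 1
        k = min(k, n // 2)
        if k > 0:
            chosen = rng.choice(n, size=2 * k, replace=False)
            intra_sd = 0.5 * config.psd_noise_sd
            for p in range(k):
                i, j = chosen[2 * p], chosen[2 * p + 1]
                axon_id[j] = axon_id[i]
                m = 0.5 * (psd[i] + psd[j])
                delta = rng.normal(0.0, intra_sd) if intra_sd > 0 else 0.0
                psd[i] = max(m + 0.5 * delta, PSD_FLOOR)
                psd[j] = max(m - 0.5 * delta, PSD_FLOOR)

        spine_frames.append(
            pd.DataFrame(
                {
                    "dendrite_id": did,
                    "spine_id": [f"{did}_s{i:04d}" for i in range(n)],
                    "position_um": position,
                    "head_volume_um3": head_volume,
                    "neck_length_um": neck_length,
                    "neck_diameter_um": neck_diameter,
                    "psd_area_um2": psd,
                    "perforated": psd > np.quantile(psd, 0.9) if n >= 10 else False,
                    "branched": False,
                    "er": er,
                    "axon_id": axon_id,
                }
            )
        )

    dendrites = pd.DataFrame(dend_rows)
    if spine_frames:
        spines = pd.concat(spine_frames, ignore_index=True)
    else:
        spines = pd.DataFrame(
            columns=[
                "dendrite_id",
                "spine_id",
                "position_um",
                "head_volume_um3",
                "neck_length_um",
                "neck_diameter_um",
                "psd_area_um2",
                "perforated",
                "branched",
                "er",
                "axon_id",
            ]
        )
    return SyntheticDataset(spines=spines, dendrites=dendrites, provenance=config)


def generate_region_spines(config: RegionConfig, n_spines: int) -> SyntheticDataset:
    """Generate dendrites until at least ``n_spines`` spines exist."""
    mean_len = sum(config.dendrite_length_range) / 2.0
    n_dend = max(1, int(math.ceil(n_spines / (config.spine_density_mean * mean_len))) + 2)
    ds = generate_region(config, n_dend)
    while len(ds) < n_spines:
        n_dend = int(n_dend * 1.5) + 1
        ds = generate_region(config, n_dend)
    return ds


def generate_contour_stack(
    target_volume: float,
    thickness: float,
    n_sections: int,
    rng: np.random.Generator,
    target_psd_area: float | None = None,
):
    """Random per-section contour areas whose summed volume equals
    ``target_volume`` (areas x thickness) exactly up to representation.

    Section areas are a Dirichlet split of the total area, mimicking the
    varying cross-sections of a spine head through the block.  When
    ``target_psd_area`` is given, PSD trace lengths with the analogous
    property (sum x thickness == area) are attached.
    """
    from spinelab.morphometry import ContourStack

    if target_volume <= 0:
        raise ValueError(f"target_volume must be > 0, got {target_volume}")
    if thickness <= 0:
        raise ValueError(f"thickness must be > 0, got {thickness}")
    if n_sections < 1:
        raise ValueError(f"n_sections must be >= 1, got {n_sections}")
    total_area = target_volume / thickness
    if n_sections == 1:
        areas = np.array([total_area])
    else:
        areas = rng.dirichlet(np.ones(n_sections)) * total_area
    traces = None
    if target_psd_area is not None:
        if target_psd_area <= 0:
            raise ValueError(f"target_psd_area must be > 0, got {target_psd_area}")
        total_len = target_psd_area / thickness
        if n_sections == 1:
            traces = np.array([total_len])
        else:
            traces = rng.dirichlet(np.ones(n_sections)) * total_len
    return ContourStack(areas=areas, thickness=thickness, psd_trace_lengths=traces)


def generate_uncaging_traces(
    amplitude: float,
    n_trials: int,
    rise_ms: float,
    decay_ms: float,
    noise_sd: float,
    pulse_time: float,
    rng: np.random.Generator,
    duration_ms: float = 200.0,
    dt_ms: float = 0.1,
    baseline: float = -65.0,
    units: str = "mV",
) -> UncagingTraceSet:
    """Repeated uncaging-response traces: baseline + difference-of-
    exponentials transient peaking at ``amplitude``, plus Gaussian noise.

    The transient follows (e^(-t/decay) - e^(-t/rise)), normalised so its
    analytic peak equals the programmed amplitude.
    """
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    if decay_ms <= rise_ms:
        raise ValueError(
            f"decay ({decay_ms} ms) must exceed rise ({rise_ms} ms): "
            "kinetics are ill-defined otherwise"
        )
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    t = np.arange(0.0, duration_ms, dt_ms)
    rel = t - pulse_time
    kernel = np.zeros_like(t)
    on = rel >= 0
    kernel[on] = np.exp(-rel[on] / decay_ms) - np.exp(-rel[on] / rise_ms)
    t_peak = rise_ms * decay_ms / (decay_ms - rise_ms) * math.log(decay_ms / rise_ms)
    peak = math.exp(-t_peak / decay_ms) - math.exp(-t_peak / rise_ms)
    transient = amplitude * kernel / peak
    traces = baseline + np.tile(transient, (n_trials, 1))
    if noise_sd > 0:
        traces = traces + rng.normal(0.0, noise_sd, traces.shape)
    return UncagingTraceSet(
        time_ms=t, traces=traces, pulse_time_ms=pulse_time, units=units
    )
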
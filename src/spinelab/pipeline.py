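"""End-to-end orchestration: generate -> measure -> test -> simulate -> MI
-> uncage -> report, with seeded, byte-reproducible outputs.

Every stage derives its own RNG seed by stable hashing of (global seed,
stage name), so inserting or removing a stage never reshuffles the
randomness of the others.  Stages write plain CSV into the output
directory; downstream stages read those files and raise a dependency
error naming the missing stage when run out of order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from spinelab import info, morphometry, stats, synthetic, twolayer, uncaging

__all__ = ["RunConfig", "DependencyError", "derive_seed", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("spinelab.pipeline")

ALL_STAGES = ("generate", "morphometry", "stats", "simulate", "mi_curve", "uncage", "report")


class DependencyError(RuntimeError):
    """A stage's upstream output is missing; the message names the stage."""


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable sub-seed (< 2^31) from the global seed and the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    outdir: str | Path
    seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    regions: Sequence[str] = ("CA1_PSR", "CB")
    n_dendrites: int = 40
    mi_case: int = 1
    mi_freqs: Sequence[float] = tuple(np.arange(1.0, 10.5, 1.0))
    mi_trials: int = 3
    mi_duration_ms: float = 20_000.0
    uncaging_n_spines: int = 35
    uncaging_long_mv: tuple[float, float] = (0.92, 0.54)
    uncaging_short_mv: tuple[float, float] = (1.66, 0.94)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        order = [s for s in ALL_STAGES if s in self.stages]
        if list(self.stages) != order:
            raise ValueError(
                f"stages must follow dependency order {ALL_STAGES}, got {tuple(self.stages)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("mi_freqs", "stages", "regions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        for key in ("uncaging_long_mv", "uncaging_short_mv"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing {path.name}: run the '{producer}' stage first or provide the file"
        )
    return path


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the configured stages; returns a name -> path map of outputs."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    produced: dict[str, Path] = {}

    if "generate" in config.stages:
        rng_seed = derive_seed(config.seed, "generate")
        spine_frames, dend_frames = [], []
        for k, region in enumerate(config.regions):
            cfg = synthetic.REGION_PRESETS[region].with_seed(rng_seed + k)
            ds = synthetic.generate_region(cfg, config.n_dendrites)
            spine_frames.append(ds.spines)
            dend_frames.append(ds.dendrites)
            log.info("generate: %s -> %d spines / %d dendrites", region, len(ds.spines), len(ds.dendrites))
        _write_csv(pd.concat(spine_frames, ignore_index=True), out / "spines.csv")
        _write_csv(pd.concat(dend_frames, ignore_index=True), out / "dendrites.csv")
        produced["spines"] = out / "spines.csv"
        produced["dendrites"] = out / "dendrites.csv"

    if "morphometry" in config.stages:
        spines = pd.read_csv(_require(out / "spines.csv", "generate"))
        dendrites = pd.read_csv(_require(out / "dendrites.csv", "generate"))
        per_dend = morphometry.summarize_dendrites(spines, dendrites)
        per_region = morphometry.summarize_region(spines, dendrites)
        _write_csv(per_dend, out / "dendrite_summary.csv")
        _write_csv(per_region, out / "region_summary.csv")
        produced["dendrite_summary"] = out / "dendrite_summary.csv"
        produced["region_summary"] = out / "region_summary.csv"

    if "stats" in config.stages:
        spines = pd.read_csv(_require(out / "spines.csv", "generate"))
        per_dend = pd.read_csv(_require(out / "dendrite_summary.csv", "morphometry"))
        rows = []
        for region, grp in spines.groupby(
            spines["dendrite_id"].str.rsplit("_d", n=1).str[0], sort=False
        ):
            r = stats.choose_and_correlate(grp["head_volume_um3"], grp["psd_area_um2"])
            rows.append(
                {
                    "comparison": f"{region}: head_volume vs psd_area",
                    "test": r.test_name,
                    "statistic": r.statistic,
                    "p_raw": r.p_value,
                    "p_adjusted": r.p_final,
                    "stars": r.stars,
                }
            )
        for region, grp in per_dend.groupby("region", sort=False):
            if len(grp) >= 4 and grp["diameter_um"].nunique() > 1:
                r = stats.choose_and_correlate(grp["diameter_um"], grp["psd_area_density"])
                rows.append(
                    {
                        "comparison": f"{region}: diameter vs psd_area_density",
                        "test": r.test_name,
                        "statistic": r.statistic,
                        "p_raw": r.p_value,
                        "p_adjusted": r.p_final,
                        "stars": r.stars,
                    }
                )
        groups = [g["head_volume_um3"].to_numpy() for _, g in spines.groupby(
            spines["dendrite_id"].str.rsplit("_d", n=1).str[0], sort=False
        )]
        labels = list(spines["dendrite_id"].str.rsplit("_d", n=1).str[0].unique())
        if len(groups) >= 2:
            cmp = stats.choose_and_compare(groups, labels)
            rows.append(
                {
                    "comparison": "head_volume across regions (omnibus)",
                    "test": cmp.omnibus.test_name,
                    "statistic": cmp.omnibus.statistic,
                    "p_raw": cmp.omnibus.p_value,
                    "p_adjusted": cmp.omnibus.p_final,
                    "stars": cmp.omnibus.stars,
                }
            )
            for pw in cmp.pairwise:
                rows.append(
                    {
                        "comparison": f"head_volume {pw.direction}",
                        "test": pw.test_name,
                        "statistic": pw.statistic,
                        "p_raw": pw.p_value,
                        "p_adjusted": pw.p_final,
                        "stars": pw.stars,
                    }
                )
        _write_csv(pd.DataFrame(rows), out / "stats.csv")
        produced["stats"] = out / "stats.csv"

    if "simulate" in config.stages:
        rng = np.random.default_rng(derive_seed(config.seed, "simulate"))
        params = twolayer.ModelParams(duration=config.mi_duration_ms)
        res = twolayer.run_simulation(params, config.mi_case, rng)
        rows = []
        for j, train in enumerate(res.dendritic_trains):
            rows.extend({"train_id": f"dend_{j:02d}", "time_ms": t} for t in train)
        rows.extend({"train_id": "soma", "time_ms": t} for t in res.somatic_train)
        _write_csv(pd.DataFrame(rows, columns=["train_id", "time_ms"]), out / "spike_trains.csv")
        produced["spike_trains"] = out / "spike_trains.csv"

    if "mi_curve" in config.stages:
        rng = np.random.default_rng(derive_seed(config.seed, "mi_curve"))
        params = twolayer.ModelParams(duration=config.mi_duration_ms)
        curve = info.tuning_curve(
            params, config.mi_case, np.asarray(config.mi_freqs), config.mi_trials, rng
        )
        _write_csv(
            pd.DataFrame(
                {
                    "freq_hz": curve.frequencies,
                    "mi_dend_mean": curve.mi_dend_mean,
                    "mi_dend_sd": curve.mi_dend_sd,
                    "mi_soma_mean": curve.mi_soma_mean,
                    "mi_soma_sd": curve.mi_soma_sd,
                }
            ),
            out / "mi_curve.csv",
        )
        produced["mi_curve"] = out / "mi_curve.csv"

    if "uncage" in config.stages:
        rng = np.random.default_rng(derive_seed(config.seed, "uncage"))
        rows = []
        for group, (mean, sd) in (
            ("long", config.uncaging_long_mv),
            ("short", config.uncaging_short_mv),
        ):
            for i in range(config.uncaging_n_spines):
                amp = max(rng.normal(mean, sd), 0.0)
                traces = synthetic.generate_uncaging_traces(
                    amplitude=amp,
                    n_trials=int(rng.integers(5, 11)),
                    rise_ms=2.0,
                    decay_ms=20.0,
                    noise_sd=0.1,
                    pulse_time=50.0,
                    rng=rng,
                )
                measured = uncaging.response_amplitude(traces)
                length = rng.uniform(0.9, 1.8) if group == "long" else rng.uniform(0.2, 0.9)
                width = rng.uniform(0.5, 0.9)
                rows.append(
                    {
                        "spine": f"{group}_{i:02d}",
                        "group": group,
                        "amplitude_mv": measured,
                        "lw_ratio": uncaging.lw_ratio(length, width),
                        "normalized_intensity": uncaging.normalized_intensity(
                            rng.uniform(50, 150), rng.uniform(80, 120, 4)
                        ),
                    }
                )
        _write_csv(pd.DataFrame(rows), out / "uncaging.csv")
        produced["uncaging"] = out / "uncaging.csv"

    if "report" in config.stages:
        report: dict[str, object] = {"seed": config.seed, "stages": list(config.stages)}
        if (out / "region_summary.csv").exists():
            reg = pd.read_csv(out / "region_summary.csv")
            report["regions"] = reg.set_index("region")[
                ["n_spines", "spine_density_mean", "head_volume_mean", "psd_area_density_mean"]
            ].round(4).to_dict("index")
        if (out / "mi_curve.csv").exists():
            curve = pd.read_csv(out / "mi_curve.csv")
            best = curve.iloc[int(curve["mi_dend_mean"].idxmax())]
            report["mi_optimal_freq_hz"] = float(best["freq_hz"])
            report["mi_dend_peak_bits"] = float(best["mi_dend_mean"])
        if (out / "uncaging.csv").exists():
            unc = pd.read_csv(out / "uncaging.csv")
            cmp = stats.choose_and_compare(
                [
                    unc.loc[unc["group"] == "long", "amplitude_mv"],
                    unc.loc[unc["group"] == "short", "amplitude_mv"],
                ],
                labels=("long", "short"),
            )
            report["uncaging_test"] = cmp.omnibus.test_name
            report["uncaging_p"] = cmp.omnibus.p_final
            report["uncaging_direction"] = cmp.omnibus.direction
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        produced["report"] = out / "report.json"

    return produced
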
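"""Per-dendrite and per-region morphometry summaries.

Reads the generated spine/dendrite tables and computes the study's
dendrite-level quantities (spine density, PSD-area density, neck-length
density, total PSD/neck ratio) and region-level summary statistics
(mean +/- SD dimensions, fold ranges, CVs, axon-coupled and ER fractions).
"""

from pathlib import Path

import pandas as pd

from spinelab import morphometry as mm

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    spines = pd.read_csv(OUT / "spines.csv")
    dendrites = pd.read_csv(OUT / "dendrites.csv")

    per_dend = mm.summarize_dendrites(spines, dendrites)
    per_region = mm.summarize_region(spines, dendrites)
    per_dend.to_csv(OUT / "dendrite_summary.csv", index=False)
    per_region.to_csv(OUT / "region_summary.csv", index=False)

    cols = [
        "region",
        "n_spines",
        "spine_density_mean",
        "head_volume_mean",
        "neck_length_mean",
        "psd_area_density_mean",
        "total_ratio_mean",
        "axon_coupled_fraction",
        "er_fraction",
    ]
    print(per_region[cols].round(3).to_string(index=False))
    print(f"\nwrote {OUT / 'dendrite_summary.csv'} and {OUT / 'region_summary.csv'}")


if __name__ == "__main__":
    main()
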
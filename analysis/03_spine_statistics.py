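"""Correlation and group-comparison statistics on the generated regions.

Reproduces the study's statistical workflow: normality-gated correlation
of head volume with PSD area (per region) and of dendritic diameter with
PSD-area density, plus a cross-region comparison of head volumes with
Bonferroni-corrected pairwise tests.
"""

from pathlib import Path

import pandas as pd

from spinelab import stats as ss

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    spines = pd.read_csv(OUT / "spines.csv")
    dendrites = pd.read_csv(OUT / "dendrites.csv")
    per_dend = pd.read_csv(OUT / "dendrite_summary.csv")
    spines = spines.merge(dendrites[["dendrite_id", "region"]], on="dendrite_id")

    rows = []
    for region, grp in spines.groupby("region", sort=False):
        r = ss.choose_and_correlate(grp["head_volume_um3"], grp["psd_area_um2"])
        rows.append(("head_volume~psd_area", region, r))
    for region, grp in per_dend.groupby("region", sort=False):
        if len(grp) >= 4:
            r = ss.choose_and_correlate(grp["diameter_um"], grp["psd_area_density"])
            rows.append(("diameter~psd_area_density", region, r))

    records = [
        {
            "comparison": name,
            "region": region,
            "test": r.test_name,
            "r": round(r.statistic, 3),
            "p": r.p_value,
            "stars": r.stars,
        }
        for name, region, r in rows
    ]
    for rec in records:
        print(
            f"{rec['comparison']:26s} {rec['region']:10s} {rec['test']:9s} "
            f"r={rec['r']:+.3f} {rec['stars']}"
        )

    groups = [g["head_volume_um3"].to_numpy() for _, g in spines.groupby("region", sort=False)]
    labels = list(spines["region"].unique())
    cmp = ss.choose_and_compare(groups, labels)
    print(f"\nhead volume across regions: {cmp.omnibus.test_name} p={cmp.omnibus.p_value:.3g}")
    pair_records = []
    for pw in cmp.pairwise:
        pair_records.append(
            {
                "comparison": f"head_volume {pw.direction}",
                "test": pw.test_name,
                "p_raw": pw.p_value,
                "p_adjusted": pw.p_adjusted,
                "stars": pw.stars,
            }
        )
        print(f"  {pw.direction:22s} p_adj={pw.p_adjusted:.3g} {pw.stars}")

    pd.DataFrame(records + pair_records).to_csv(OUT / "statistics.csv", index=False)
    print(f"\nwrote {OUT / 'statistics.csv'}")


if __name__ == "__main__":
    main()
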
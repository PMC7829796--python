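#!/usr/bin/env python
"""Integrate incident light per plant and derive the efficiencies.

Combines daily PCS with each plant's measured photon flux densities
into daily and cumulative incident doses (400-700 and 400-800 nm), then
divides shoot dry weight by the cumulative doses to obtain LUE_PPFD and
LUE_TOTAL, and computes the leaf overlap ratio and specific leaf area.
"""

from pathlib import Path

import pandas as pd

from canopyflux import budget, stats

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    for name in ("study1", "study2"):
        out = RESULTS / name
        daily = pd.read_csv(out / "daily_pcs.csv")
        light = pd.read_csv(out / "light_map.csv")
        harvest = pd.read_csv(out / "harvest.csv")
        table = budget.light_budget_table(daily, light, harvest)
        table.to_csv(out / "light_budget.csv", index=False)
        merged = table.merge(harvest[["plant_id", "harvest"]], on="plant_id")
        print(f"{name}:")
        for label, grp in merged.groupby("harvest"):
            c = stats.correlate(grp["sla_cm2_g"], grp["lue_total_g_mol"])
            print(
                f"  {label:5s} harvest: LUE_TOTAL {grp['lue_total_g_mol'].min():.3f}-"
                f"{grp['lue_total_g_mol'].max():.3f} g/mol, "
                f"LUE_PPFD {grp['lue_ppfd_g_mol'].min():.3f}-{grp['lue_ppfd_g_mol'].max():.3f}, "
                f"overlap {grp['overlap_ratio'].mean():.2f}, "
                f"SLA~LUE_TOTAL r = {c.pearson_r:+.2f} (p = {c.p_value:.3f})"
            )


if __name__ == "__main__":
    main()
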
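#!/usr/bin/env python
"""Far-red vs PPFD efficacy: stepwise models, slope ratios, correlations.

Study 2 (perpendicular gradients): fits backwards-stepwise OLS models of
dry weight, cumulative incident light and leaf morphology on FR and
PPFD per harvest, and converts retained slope pairs into slope-ratio
efficacies.  Also evaluates the efficacies implied by the shipped
published reference coefficients (57% early / 183% late for incident
light) and the Study-1 single-gradient per-unit FR slopes.  Saves a
dry-weight vs incident-light figure.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from canopyflux import pipeline, stats
from canopyflux.reference import reference_efficacy

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def study2_models() -> None:
    out = RESULTS / "study2"
    light = pd.read_csv(out / "light_map.csv")
    harvest = pd.read_csv(out / "harvest.csv")
    bud = pd.read_csv(out / "light_budget.csv")
    daily = pd.read_csv(out / "daily_pcs.csv")
    merged = pipeline.merged_table(light, harvest, bud, daily)
    models, efficacy, correlations = pipeline.stats_tables(merged)
    models.to_csv(out / "models.csv", index=False)
    efficacy.to_csv(out / "efficacy.csv", index=False)
    correlations.to_csv(out / "correlations.csv", index=False)
    print("study2 slope-ratio efficacies (far-red vs PPFD):")
    for rec in efficacy.itertuples(index=False):
        print(
            f"  {rec.response:15s} {rec.harvest:5s}: "
            f"FR {rec.slope_fr:.5f} / PPFD {rec.slope_ppfd:.5f} "
            f"-> {rec.percent_more_effective:+.0f}%"
        )

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, grp in merged.groupby("harvest"):
        ax.scatter(grp["cum_total_mol"], grp["dry_weight_g"], s=14, label=f"{label} harvest")
    ax.set_xlabel("cumulative incident light, 400-800 nm (mol/plant)")
    ax.set_ylabel("shoot dry weight (g)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig_dir = RESULTS / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    fig.savefig(fig_dir / "dry_weight_vs_incident_light.png", dpi=150)
    print(f"  figure -> {fig_dir / 'dry_weight_vs_incident_light.png'}")


def study1_slopes() -> None:
    out = RESULTS / "study1"
    light = pd.read_csv(out / "light_map.csv")
    harvest = pd.read_csv(out / "harvest.csv")
    merged = harvest.merge(light, on="plant_id")
    print("study1 per-unit far-red slopes (single-gradient reporting):")
    for label, grp in merged.groupby("harvest"):
        for resp in ("leaf_length_cm", "leaf_width_cm"):
            slope, p = stats.per_unit_slope(grp, resp, "fr_umol_m2_s")
            print(f"  {resp:15s} {label:5s}: {10 * slope:.2f} mm per umol m-2 s-1 (p = {p:.2g})")


def reference_ratios() -> None:
    print("published-coefficient efficacies (incident light):")
    for harvest in ("early", "late"):
        eff = reference_efficacy("incident_light", harvest)
        print(
            f"  {harvest:5s}: FR {eff.slope_fr:.5f} / PPFD {eff.slope_ppfd:.5f}"
            f" -> {eff.percent_more_effective:.1f}% (reported as {eff.percent_rounded}%)"
        )


def main() -> None:
    reference_ratios()
    study2_models()
    study1_slopes()


if __name__ == "__main__":
    main()
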
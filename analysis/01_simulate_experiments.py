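#!/usr/bin/env python
"""Generate the two synthetic growth-chamber studies.

Study 1: far-red gradient (4.9-28.0 umol m-2 s-1) under near-uniform
PPFD (207 +/- 13).  Study 2: perpendicular far-red (4.7-32.8) and PPFD
(111-245) gradients.  Both use 60 plants, imaging on days 2-25 and
harvests at 16 / 25 days after germination.  Writes the light map,
harvest table, hidden ground truth and the measured PCS series per
study under results/.  Images for a verification subset are rendered by
the next script; the tabulated PCS series is what downstream stages
consume.
"""

from pathlib import Path

from canopyflux import synth

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

STUDIES = {
    "study1": (synth.STUDY1_FR_GRADIENT, 101),
    "study2": (synth.STUDY2_PERPENDICULAR, 102),
}


def main() -> None:
    for name, (gradient, seed) in STUDIES.items():
        out = RESULTS / name
        exp = synth.simulate_experiment(gradient=gradient, seed=seed)
        synth.write_experiment(exp, out, write_images=False)
        exp.pcs_series().to_csv(out / "pcs_series.csv", index=False)
        fr = exp.light_field["fr_umol_m2_s"]
        ppfd = exp.light_field["ppfd_umol_m2_s"]
        print(
            f"{name}: {len(exp.light_field)} plants | "
            f"PPFD {ppfd.min():.0f}-{ppfd.max():.0f}, FR {fr.min():.1f}-{fr.max():.1f} "
            f"umol m-2 s-1 | dry weight {exp.harvest['dry_weight_g'].min():.2f}-"
            f"{exp.harvest['dry_weight_g'].max():.2f} g -> {out}"
        )


if __name__ == "__main__":
    main()
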
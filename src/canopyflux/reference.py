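"""Published reference regression coefficients for the perpendicular
light-gradient lettuce study.

The shipped CSV holds the printed intercepts and per-unit-flux slopes of
dry weight (g/plant), cumulative incident light (mol/plant) and leaf
length/width (cm) against far-red and PPFD (both umol m-2 s-1), for the
early (16 d) and late (25 d) harvests, together with their R^2.  They
serve as fixed fixtures for the slope-ratio efficacy computation and as
the default generating morphology coefficients of the synthetic module.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import EfficacyResult

__all__ = ["load_reference_coefficients", "reference_efficacy"]


def load_reference_coefficients() -> pd.DataFrame:
    """The reference coefficient table (trait, harvest, intercept, fr,
    ppfd, r_squared)."""
    with resources.files("canopyflux.data").joinpath("reference_coefficients.csv").open() as fh:
        return pd.read_csv(fh)


def reference_efficacy(trait: str, harvest: str) -> EfficacyResult:
    """Slope-ratio efficacy computed from the published coefficients."""
    table = load_reference_coefficients()
    row = table[(table["trait"] == trait) & (table["harvest"] == harvest)]
    if row.empty:
        raise KeyError(f"no reference row for ({trait}, {harvest})")
    slope_fr = float(row["fr"].iloc[0])
    slope_ppfd = float(row["ppfd"].iloc[0])
    return EfficacyResult(
        response=f"{trait}_{harvest}",
        slope_fr=slope_fr,
        slope_ppfd=slope_ppfd,
        percent_more_effective=100.0 * (slope_fr / slope_ppfd - 1.0),
    )
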
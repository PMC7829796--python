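"""Per-plant incident-light budgets and light use efficiency.

Incident light is the photon dose landing on the projected canopy:
for each day,

    mol = PCS[cm^2] * 1e-4 [m^2/cm^2] * flux[umol m^-2 s^-1] * 1e-6
          * photoperiod[h] * 3600 [s/h]

computed once for the 400-700 nm band (PPFD) and once for the full
400-800 nm band (PPFD + far-red).  Cumulative dose is the plain sum of
daily values from germination up to (by default, excluding) the harvest
day.  Light use efficiency divides shoot dry mass by the cumulative
dose: LUE_PPFD uses the 400-700 nm dose, LUE_TOTAL the 400-800 nm dose,
both in g mol^-1.  PCS is the light-*collecting* area as seen from
above; no absorptance or angular correction is applied, so these are
incident (not absorbed) doses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "daily_incident",
    "cumulative_incident",
    "compute_lue",
    "overlap_ratio",
    "specific_leaf_area",
    "light_budget_table",
]

DEFAULT_PHOTOPERIOD_H = 18.0

LIGHT_BUDGET_COLUMNS = [
    "plant_id",
    "cum_ppfd_mol",
    "cum_total_mol",
    "lue_ppfd_g_mol",
    "lue_total_g_mol",
    "overlap_ratio",
    "sla_cm2_g",
]

_CM2_TO_M2 = 1e-4
_UMOL_TO_MOL = 1e-6


def daily_incident(pcs_cm2, ppfd, fr, photoperiod_h: float = DEFAULT_PHOTOPERIOD_H):
    """Daily incident dose (mol) for one day: ``(mol_ppfd, mol_total)``.

    Vectorized over any broadcastable combination of inputs.
    """
    pcs_cm2 = np.asarray(pcs_cm2, dtype=float)
    ppfd = np.asarray(ppfd, dtype=float)
    fr = np.asarray(fr, dtype=float)
    if np.any(pcs_cm2 < 0) or np.any(ppfd < 0) or np.any(fr < 0):
        raise ValueError("pcs, ppfd and fr must be non-negative")
    if not 0 < photoperiod_h <= 24:
        raise ValueError("photoperiod must be in (0, 24] hours")
    seconds = photoperiod_h * 3600.0
    base = pcs_cm2 * _CM2_TO_M2 * _UMOL_TO_MOL * seconds
    return base * ppfd, base * (ppfd + fr)


def cumulative_incident(days, mol_ppfd, mol_total):
    """Sum daily doses into cumulative ``(mol_ppfd, mol_total)``.

    ``days`` must be a gap-free run of distinct integer days; duplicates
    or missing days are schema errors upstream and are rejected here.
    """
    days = np.asarray(days)
    if days.size == 0:
        raise ValueError("no daily values to accumulate")
    d = np.sort(days)
    if np.unique(d).size != d.size:
        raise ValueError("duplicate days in daily light series")
    if not np.array_equal(d, np.arange(d[0], d[-1] + 1)):
        raise ValueError("missing days in daily light series")
    return float(np.sum(mol_ppfd)), float(np.sum(mol_total))


def compute_lue(dry_weight_g: float, cumulative_ppfd: float, cumulative_total: float):
    """``(lue_ppfd, lue_total)`` in g per mol of incident photons."""
    if cumulative_ppfd <= 0 or cumulative_total <= 0:
        raise ValueError("cumulative light must be positive")
    return dry_weight_g / cumulative_ppfd, dry_weight_g / cumulative_total


def overlap_ratio(leaf_area_cm2: float, pcs_cm2: float) -> float:
    """Total leaf area over PCS: ~1 for flat young rosettes, >1 once
    leaves start shading each other."""
    if pcs_cm2 <= 0:
        raise ValueError("pcs_cm2 must be positive")
    return leaf_area_cm2 / pcs_cm2


def specific_leaf_area(leaf_area_cm2: float, dry_weight_g: float) -> float:
    """SLA, cm^2 of leaf per g of shoot dry mass (high SLA = thin leaves)."""
    if dry_weight_g <= 0:
        raise ValueError("dry_weight_g must be positive")
    return leaf_area_cm2 / dry_weight_g


def light_budget_table(
    daily_pcs: pd.DataFrame,
    light_map: pd.DataFrame,
    harvest: pd.DataFrame,
    photoperiod_h: float = DEFAULT_PHOTOPERIOD_H,
    include_harvest_day: bool = False,
) -> pd.DataFrame:
    """Full per-plant budget: cumulative doses, LUEs, overlap ratio, SLA.

    Parameters
    ----------
    daily_pcs
        ``plant_id, day, pcs_cm2`` at every integer day from germination.
    light_map
        ``plant_id, ppfd_umol_m2_s, fr_umol_m2_s`` measured at each
        plant position.
    harvest
        ``plant_id, harvest_day, leaf_area_cm2, dry_weight_g`` (extra
        columns pass through untouched).
    include_harvest_day
        Whether the harvest day itself contributes to the cumulative
        dose.  Default False: plants are removed at the start of the
        harvest day.
    """
    field = light_map.set_index("plant_id")
    rows = []
    for rec in harvest.itertuples(index=False):
        pid = rec.plant_id
        h_day = int(rec.harvest_day)
        last = h_day if include_harvest_day else h_day - 1
        sub = daily_pcs[(daily_pcs["plant_id"] == pid) & (daily_pcs["day"] <= last)]
        if sub.empty:
            raise ValueError(f"no daily PCS for plant {pid} up to day {last}")
        if pid not in field.index:
            raise ValueError(f"plant {pid} missing from the light map")
        ppfd = field.at[pid, "ppfd_umol_m2_s"]
        fr = field.at[pid, "fr_umol_m2_s"]
        mol_p, mol_t = daily_incident(sub["pcs_cm2"].to_numpy(), ppfd, fr, photoperiod_h)
        cum_p, cum_t = cumulative_incident(sub["day"].to_numpy(), mol_p, mol_t)
        lue_p, lue_t = compute_lue(rec.dry_weight_g, cum_p, cum_t)
        pcs_h = daily_pcs[(daily_pcs["plant_id"] == pid) & (daily_pcs["day"] == h_day)]
        pcs_at_harvest = float(pcs_h["pcs_cm2"].iloc[0]) if not pcs_h.empty else float(sub["pcs_cm2"].iloc[-1])
        rows.append(
            (
                pid,
                cum_p,
                cum_t,
                lue_p,
                lue_t,
                overlap_ratio(rec.leaf_area_cm2, pcs_at_harvest),
                specific_leaf_area(rec.leaf_area_cm2, rec.dry_weight_g),
            )
        )
    return pd.DataFrame(rows, columns=LIGHT_BUDGET_COLUMNS)
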
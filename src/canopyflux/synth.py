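"""Synthetic growth-chamber experiments with known ground truth.

Emulates two sole-source-lighting lettuce studies in a 0.8 m x 1.8 m
chamber with 60 plants on a 6 x 10 grid:

* a far-red gradient study: near-uniform PPFD (207 +/- 13 umol m-2 s-1)
  with far-red ranging 4.9-28.0 umol m-2 s-1 along the long chamber axis;
* a perpendicular-gradient study: PPFD 111-245 along the columns,
  far-red 4.7-32.8 along the rows, orthogonal by construction.

Each plant follows a log-quadratic canopy growth law

    ln PCS_i(t) = a + b_i * t + c * t**2,
    b_i = b0 + beta_fr * FR_i + beta_ppfd * PPFD_i + eta_i,

where ``eta_i`` is a plant-level "vigor" deviation.  Morphology (length
and width of the longest leaf) is linear in FR and PPFD, leaf area is a
configurable overlap multiple of the canopy area, and shoot dry weight
is generated as ``true_lue_total`` times the plant's cumulative incident
400-800 nm photon dose — so every downstream estimate has an exact
generating truth to be checked against.

Fluorescence frames are rendered as lobed rosettes (or plain disks) on a
dim noisy background with a bright scale bar; the rasterized canopy
pixel count matches the requested area to sub-pixel accuracy, which
makes zero-noise pipeline round trips exact up to pixel quantization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import budget as _budget
from .imaging import FluorescenceImage, ImageGeometry

__all__ = [
    "GradientSpec",
    "TruePlantParams",
    "SyntheticExperiment",
    "STUDY1_FR_GRADIENT",
    "STUDY2_PERPENDICULAR",
    "make_light_field",
    "simulate_growth",
    "assign_harvests",
    "simulate_harvest",
    "render_fluorescence_image",
    "simulate_experiment",
    "write_experiment",
]

LIGHT_MAP_COLUMNS = ["plant_id", "row", "col", "ppfd_umol_m2_s", "fr_umol_m2_s"]
HARVEST_COLUMNS = [
    "plant_id",
    "harvest",
    "harvest_day",
    "leaf_length_cm",
    "leaf_width_cm",
    "leaf_area_cm2",
    "dry_weight_g",
]
TRUTH_COLUMNS = [
    "plant_id",
    "b_plant",
    "pcs_at_harvest_cm2",
    "cum_ppfd_mol",
    "cum_total_mol",
    "lue_total_g_mol",
]

#: measurement / biological noise defaults (see docs/methods.md)
DEFAULT_NOISE = {
    "pcs_log": 0.02,        # log-scale sd of a measured PCS point
    "length_cm": 0.8,       # leaf length measurement sd
    "width_cm": 0.4,        # leaf width measurement sd
    "dry_weight_g": 0.03,   # balance + handling sd
    "growth_vigor": 0.003,  # plant-level sd of the linear growth coefficient
}

#: reference linear morphology responses (cm) to FR and PPFD
#: (intercept, per-unit-FR, per-unit-PPFD), per trait and harvest
DEFAULT_MORPHOLOGY = {
    ("length", "early"): (13.68, 0.1478, -0.0126),
    ("length", "late"): (19.40, 0.1305, -0.0315),
    ("width", "early"): (3.276, 0.0966, 0.0152),
    ("width", "late"): (8.774, 0.1385, -0.0025),
}

DEFAULT_IMAGING_DAYS = (2, 5, 9, 12, 16, 19, 23, 25)
DEFAULT_HARVEST_DAYS = (16, 25)

_MEASUREMENT_FLOOR = 1e-6


@dataclass(frozen=True)
class GradientSpec:
    """Light-field layout of one study.

    ``uniform_ppfd_fr_gradient``: PPFD is the range midpoint plus
    Gaussian position noise; far-red varies linearly along the columns
    (the long chamber axis).  ``perpendicular_gradients``: PPFD varies
    linearly along the columns and far-red along the rows, so the two
    are uncorrelated across the grid by construction.
    """

    mode: str
    ppfd_range: tuple[float, float]
    fr_range: tuple[float, float]
    grid: tuple[int, int] = (6, 10)
    ppfd_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("uniform_ppfd_fr_gradient", "perpendicular_gradients"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name, rng in (("ppfd_range", self.ppfd_range), ("fr_range", self.fr_range)):
            if rng[0] <= 0 and name == "ppfd_range":
                raise ValueError(f"{name} must be positive")
            if rng[0] < 0:
                raise ValueError(f"{name} must be non-negative")
            if rng[0] > rng[1]:
                raise ValueError(f"{name} min must not exceed max")
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ValueError("grid must have positive dimensions")
        if self.ppfd_noise_sd < 0:
            raise ValueError("ppfd_noise_sd must be >= 0")

    @property
    def n_plants(self) -> int:
        return self.grid[0] * self.grid[1]


STUDY1_FR_GRADIENT = GradientSpec(
    mode="uniform_ppfd_fr_gradient",
    ppfd_range=(207.0, 207.0),
    fr_range=(4.9, 28.0),
    ppfd_noise_sd=13.0,
)

STUDY2_PERPENDICULAR = GradientSpec(
    mode="perpendicular_gradients",
    ppfd_range=(111.0, 245.0),
    fr_range=(4.7, 32.8),
)


@dataclass
class TruePlantParams:
    """Generating parameters shared by every plant in an experiment.

    ``pcs_curve`` holds (a, b0, c) of the log-quadratic growth law;
    ``fr_pcs_slope`` / ``ppfd_pcs_slope`` are the additive per-unit-flux
    effects on the linear coefficient.  Defaults were calibrated once to
    the chamber scale of the emulated studies (seedling ~0.35 cm2,
    ~85 cm2 at day 16 and ~300 cm2 at day 25 at the gradient center; see
    docs/methods.md) and a constant light use efficiency of 0.60 g per
    mol of incident 400-800 nm photons.
    """

    pcs_curve: tuple[float, float, float] = (-1.05, 0.425, -0.0081)
    fr_pcs_slope: float = 7.0e-4
    ppfd_pcs_slope: float = 2.0e-4
    morphology: dict = field(default_factory=lambda: dict(DEFAULT_MORPHOLOGY))
    true_lue_total: float = 0.60
    noise_sds: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))

    def __post_init__(self) -> None:
        if not 0 < self.true_lue_total < 2:
            raise ValueError("true_lue_total must be in (0, 2) g/mol")
        if any(v < 0 for v in self.noise_sds.values()):
            raise ValueError("noise sds must be >= 0")

    def without_noise(self) -> "TruePlantParams":
        """Copy with every noise source switched off."""
        return replace(self, noise_sds={k: 0.0 for k in self.noise_sds})


def make_light_field(spec: GradientSpec, seed: int) -> pd.DataFrame:
    """One (PPFD, far-red) pair per plant position.

    Returns the light-map table with columns ``plant_id, row, col,
    ppfd_umol_m2_s, fr_umol_m2_s``; plant ids run row-major from 1.
    """
    n_rows, n_cols = spec.grid
    rows, cols = np.divmod(np.arange(spec.n_plants), n_cols)

    def _axis(rng_pair, idx, n):
        lo, hi = rng_pair
        if n == 1:
            return np.full_like(idx, (lo + hi) / 2, dtype=float)
        return lo + (hi - lo) * idx / (n - 1)

    if spec.mode == "perpendicular_gradients":
        ppfd = _axis(spec.ppfd_range, cols, n_cols)
        fr = _axis(spec.fr_range, rows, n_rows)
    else:  # uniform PPFD, FR gradient along the long (column) axis
        rng = np.random.default_rng(seed)
        mean_ppfd = (spec.ppfd_range[0] + spec.ppfd_range[1]) / 2
        ppfd = mean_ppfd + rng.normal(0.0, spec.ppfd_noise_sd, spec.n_plants)
        ppfd = np.maximum(ppfd, 1.0)  # photon flux cannot go non-positive
        fr = _axis(spec.fr_range, cols, n_cols)
    return pd.DataFrame(
        {
            "plant_id": np.arange(1, spec.n_plants + 1),
            "row": rows,
            "col": cols,
            "ppfd_umol_m2_s": ppfd,
            "fr_umol_m2_s": fr,
        }
    )


def simulate_growth(
    light_field: pd.DataFrame,
    params: TruePlantParams,
    days: np.ndarray | range,
    seed: int,
    max_pcs_cm2: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True (noise-free) daily canopy trajectories for every plant.

    Returns ``(trajectories, plant_effects)``: trajectories has columns
    ``plant_id, day, pcs_cm2``; plant_effects records each plant's
    realized linear coefficient ``b_plant`` (including the vigor draw).
    """
    a, b0, c = params.pcs_curve
    t = np.asarray(list(days), dtype=float)
    if t.size == 0 or t.min() < 0:
        raise ValueError("days must be a non-empty range starting at >= 0")
    rng = np.random.default_rng(seed)
    vigor_sd = params.noise_sds.get("growth_vigor", 0.0)
    eta = rng.normal(0.0, vigor_sd, len(light_field)) if vigor_sd > 0 else np.zeros(len(light_field))
    b_plant = (
        b0
        + params.fr_pcs_slope * light_field["fr_umol_m2_s"].to_numpy()
        + params.ppfd_pcs_slope * light_field["ppfd_umol_m2_s"].to_numpy()
        + eta
    )
    log_pcs = a + np.outer(b_plant, t) + c * t**2  # plants x days
    pcs = np.exp(log_pcs)
    if max_pcs_cm2 is not None and pcs.max() > max_pcs_cm2:
        raise ValueError(
            f"growth parameters produce PCS {pcs.max():.0f} cm2 exceeding "
            f"the available area per plant ({max_pcs_cm2:.0f} cm2)"
        )
    plant_ids = light_field["plant_id"].to_numpy()
    traj = pd.DataFrame(
        {
            "plant_id": np.repeat(plant_ids, t.size),
            "day": np.tile(t.astype(int), plant_ids.size),
            "pcs_cm2": pcs.ravel(),
        }
    )
    effects = pd.DataFrame({"plant_id": plant_ids, "b_plant": b_plant})
    return traj, effects


def assign_harvests(
    light_field: pd.DataFrame,
    harvest_days: tuple[int, int],
    seed: int,
) -> pd.DataFrame:
    """Split plants between the early and late harvest, stratified
    across the light gradient.

    Plants are ordered by (FR, PPFD) and consecutive pairs are split at
    random, so both harvests span the full gradient.  Odd leftovers go
    to the early harvest.
    """
    early_day, late_day = harvest_days
    if not early_day < late_day:
        raise ValueError("early harvest day must precede the late one")
    rng = np.random.default_rng(seed)
    order = light_field.sort_values(
        ["fr_umol_m2_s", "ppfd_umol_m2_s", "plant_id"]
    )["plant_id"].to_numpy()
    early = []
    for i in range(0, order.size - 1, 2):
        pick = rng.integers(0, 2)
        early.append(order[i + pick])
    if order.size % 2 == 1:
        early.append(order[-1])
    early = set(int(p) for p in early)
    rows = [
        (int(pid), "early" if int(pid) in early else "late",
         early_day if int(pid) in early else late_day)
        for pid in light_field["plant_id"]
    ]
    return pd.DataFrame(rows, columns=["plant_id", "harvest", "harvest_day"])


def _truncate(values: np.ndarray, what: str) -> np.ndarray:
    neg = values < _MEASUREMENT_FLOOR
    if np.any(neg):
        warnings.warn(
            f"{int(neg.sum())} simulated {what} value(s) fell below zero; "
            f"truncated at {_MEASUREMENT_FLOOR}"
        )
        values = np.where(neg, _MEASUREMENT_FLOOR, values)
    return values


def simulate_harvest(
    light_field: pd.DataFrame,
    trajectories: pd.DataFrame,
    assignment: pd.DataFrame,
    params: TruePlantParams,
    seed: int,
    photoperiod_h: float = _budget.DEFAULT_PHOTOPERIOD_H,
    overlap_true: tuple[float, float] = (1.05, 1.4),
    include_harvest_day: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Destructive measurements at each plant's harvest day.

    Leaf length/width come from the linear morphology model plus noise;
    leaf area is ``overlap_true`` (early, late) times the true canopy
    area at harvest; dry weight is ``true_lue_total`` times the true
    cumulative incident 400-800 nm dose plus noise.  Negative draws are
    truncated at a small positive floor with a warning.  Returns
    ``(harvest_table, truth_table)``.
    """
    rng = np.random.default_rng(seed)
    field_idx = light_field.set_index("plant_id")
    merged = assignment.merge(light_field, on="plant_id").set_index("plant_id")
    n = len(merged)
    noise = params.noise_sds
    eps_len = rng.normal(0.0, noise.get("length_cm", 0.0), n) if noise.get("length_cm", 0.0) > 0 else np.zeros(n)
    eps_wid = rng.normal(0.0, noise.get("width_cm", 0.0), n) if noise.get("width_cm", 0.0) > 0 else np.zeros(n)
    eps_dw = rng.normal(0.0, noise.get("dry_weight_g", 0.0), n) if noise.get("dry_weight_g", 0.0) > 0 else np.zeros(n)

    harvest_rows, truth_rows = [], []
    for k, (pid, rec) in enumerate(merged.iterrows()):
        h_day = int(rec["harvest_day"])
        label = rec["harvest"]
        fr = field_idx.at[pid, "fr_umol_m2_s"]
        ppfd = field_idx.at[pid, "ppfd_umol_m2_s"]
        li, lf, lp = params.morphology[("length", label)]
        wi, wf, wp = params.morphology[("width", label)]
        length = li + lf * fr + lp * ppfd + eps_len[k]
        width = wi + wf * fr + wp * ppfd + eps_wid[k]

        sub = trajectories[(trajectories["plant_id"] == pid)]
        last = h_day if include_harvest_day else h_day - 1
        dose = sub[sub["day"] <= last]
        mol_p, mol_t = _budget.daily_incident(
            dose["pcs_cm2"].to_numpy(), ppfd, fr, photoperiod_h
        )
        cum_p, cum_t = _budget.cumulative_incident(dose["day"].to_numpy(), mol_p, mol_t)
        pcs_h = float(sub.loc[sub["day"] == h_day, "pcs_cm2"].iloc[0])
        overlap = overlap_true[0] if label == "early" else overlap_true[1]
        leaf_area = overlap * pcs_h
        dw = params.true_lue_total * cum_t + eps_dw[k]

        harvest_rows.append((pid, label, h_day, length, width, leaf_area, dw))
        truth_rows.append((pid, np.nan, pcs_h, cum_p, cum_t, params.true_lue_total))

    harvest = pd.DataFrame(harvest_rows, columns=HARVEST_COLUMNS)
    for col in ("leaf_length_cm", "leaf_width_cm", "dry_weight_g"):
        harvest[col] = _truncate(harvest[col].to_numpy(), col)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return harvest, truth


def render_fluorescence_image(
    pcs_cm2: float,
    geometry: ImageGeometry,
    seed: int | tuple,
    mode: str = "rosette",
    lobes: int | None = None,
    lobe_depth: float = 0.15,
    plant_id: int | None = None,
    day: int | None = None,
) -> FluorescenceImage:
    """Render one fluorescence frame for a canopy of the requested area.

    The canopy is a cosine-lobed rosette (``mode='rosette'``; a plain
    ``'disk'`` is available for analytic tests) whose rasterized pixel
    count equals ``round(pcs_cm2 / cm_per_pixel**2)``: the lobed outline
    is scaled so that exactly that many pixel centers fall inside, so
    the area error is below one pixel.  Background pixels are drawn well
    below, foreground pixels well above, the nominal segmentation
    threshold, and the scale bar is drawn in the reserved marker strip.
    Bit-identical for identical inputs and seed.
    """
    if pcs_cm2 < 0:
        raise ValueError("pcs_cm2 must be >= 0")
    if mode not in ("rosette", "disk"):
        raise ValueError(f"unknown canopy mode {mode!r}")
    rng = np.random.default_rng(seed)
    H, W = geometry.height, geometry.width
    img = rng.normal(1500.0, 400.0, (H, W)).clip(0, 5000)

    # scale bar: full-intensity horizontal run of known physical length
    mk_len = geometry.marker_length_px
    r0, r1 = geometry.marker_rows
    c0 = geometry.marker_col_start
    img[r0 + 2 : r1 - 2, c0 : c0 + mk_len] = geometry.max_intensity * 0.9

    target_px = int(round(pcs_cm2 / geometry.cm_per_pixel**2))
    if target_px > 0:
        eps = lobe_depth if mode == "rosette" else 0.0
        if mode == "rosette" and lobes is None:
            lobes = int(rng.integers(6, 13))
        k = lobes or 0
        jitter = rng.integers(-4, 5, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        R0 = np.sqrt(pcs_cm2 / np.pi) / geometry.cm_per_pixel
        norm = np.sqrt(1 + eps**2 / 2)
        box = int(np.ceil(1.35 * R0 * (1 + eps))) + 3
        usable_h = geometry.marker_rows[0] - 2
        cy = usable_h // 2 + int(jitter[0])
        cx = W // 2 + int(jitter[1])
        if cy - box < 0 or cy + box >= usable_h or cx - box < 0 or cx + box >= W:
            raise ValueError(
                f"canopy of {pcs_cm2:.0f} cm2 does not fit the field of view"
            )
        yy, xx = np.mgrid[cy - box : cy + box + 1, cx - box : cx + box + 1]
        dy = yy - cy
        dx = xx - cx
        dist = np.hypot(dy, dx)
        if eps > 0:
            theta = np.arctan2(dy, dx)
            radius = R0 * (1 + eps * np.cos(k * theta + phase)) / norm
        else:
            radius = R0
        u = (dist / radius).ravel()
        kth = np.partition(u, target_px - 1)[target_px - 1]
        inside = (u <= kth).reshape(dist.shape)
        fg = rng.normal(40000.0, 3000.0, int(inside.sum())).clip(20000, geometry.max_intensity)
        block = img[cy - box : cy + box + 1, cx - box : cx + box + 1]
        block[inside] = fg
    return FluorescenceImage(
        pixels=np.round(img).astype(np.uint16),
        plant_id=plant_id,
        day=day,
        geometry=geometry,
    )


@dataclass
class SyntheticExperiment:
    """A complete generated experiment with its hidden ground truth."""

    gradient: GradientSpec
    params: TruePlantParams
    imaging_days: tuple[int, ...]
    harvest_days: tuple[int, int]
    photoperiod_h: float
    seed: int
    light_field: pd.DataFrame
    trajectories: pd.DataFrame
    plant_effects: pd.DataFrame
    assignment: pd.DataFrame
    harvest: pd.DataFrame
    truth: pd.DataFrame
    geometry: ImageGeometry = field(default_factory=ImageGeometry)

    def pcs_series(self, seed_offset: int = 3) -> pd.DataFrame:
        """Measured PCS series without rendering: true daily PCS at the
        imaging days with multiplicative log-normal measurement noise."""
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, seed_offset)))
        sched = self._schedule()
        true_pcs = (
            self.trajectories.merge(sched, on=["plant_id", "day"])
            .sort_values(["plant_id", "day"], ignore_index=True)
        )
        sd = self.params.noise_sds.get("pcs_log", 0.0)
        noise = rng.normal(0.0, sd, len(true_pcs)) if sd > 0 else 0.0
        out = true_pcs[["plant_id", "day"]].copy()
        out["pcs_cm2"] = true_pcs["pcs_cm2"].to_numpy() * np.exp(noise)
        return out

    def _schedule(self) -> pd.DataFrame:
        """(plant_id, day) pairs actually imaged: every imaging day up to
        and including each plant's harvest day."""
        rows = [
            (int(rec.plant_id), d)
            for rec in self.assignment.itertuples(index=False)
            for d in self.imaging_days
            if d <= rec.harvest_day
        ]
        return pd.DataFrame(rows, columns=["plant_id", "day"])

    def iter_images(self, mode: str = "rosette") -> Iterator[FluorescenceImage]:
        """Render the fluorescence frame for every scheduled (plant, day).

        The measured PCS log-noise is applied to the rendered area, so
        segmentation of these frames is equivalent to :meth:`pcs_series`
        up to pixel quantization.
        """
        series = self.pcs_series()
        for rec in series.itertuples(index=False):
            yield render_fluorescence_image(
                rec.pcs_cm2,
                self.geometry,
                seed=np.random.SeedSequence((self.seed, int(rec.plant_id), int(rec.day))),
                mode=mode,
                plant_id=int(rec.plant_id),
                day=int(rec.day),
            )


def simulate_experiment(
    gradient: GradientSpec = STUDY2_PERPENDICULAR,
    params: TruePlantParams | None = None,
    imaging_days: tuple[int, ...] = DEFAULT_IMAGING_DAYS,
    harvest_days: tuple[int, int] = DEFAULT_HARVEST_DAYS,
    photoperiod_h: float = _budget.DEFAULT_PHOTOPERIOD_H,
    seed: int = 0,
    geometry: ImageGeometry | None = None,
    overlap_true: tuple[float, float] = (1.05, 1.4),
    include_harvest_day: bool = False,
) -> SyntheticExperiment:
    """Generate a full experiment: light field, trajectories, harvest
    tables and (lazily rendered) images, all reproducible from ``seed``."""
    params = params if params is not None else TruePlantParams()
    geometry = geometry if geometry is not None else ImageGeometry()
    if max(imaging_days) < harvest_days[1]:
        raise ValueError("imaging schedule must reach the late harvest day")
    ss = np.random.SeedSequence(seed)
    s_field, s_growth, s_assign, s_harv = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))
    field = make_light_field(gradient, s_field)
    days = range(0, harvest_days[1] + 1)
    # largest canopy the frame can hold, as the chamber-capacity guard
    usable_half = min(geometry.marker_rows[0] // 2, geometry.width // 2) - 12
    # 1.56 ~ the renderer's bounding-box margin for the lobed outline
    max_pcs = np.pi * (usable_half * geometry.cm_per_pixel / 1.56) ** 2
    traj, effects = simulate_growth(field, params, days, s_growth, max_pcs_cm2=max_pcs)
    assignment = assign_harvests(field, harvest_days, s_assign)
    harvest, truth = simulate_harvest(
        field,
        traj,
        assignment,
        params,
        s_harv,
        photoperiod_h=photoperiod_h,
        overlap_true=overlap_true,
        include_harvest_day=include_harvest_day,
    )
    truth = truth.merge(effects, on="plant_id", suffixes=("_drop", ""))
    truth = truth[TRUTH_COLUMNS]
    return SyntheticExperiment(
        gradient=gradient,
        params=params,
        imaging_days=tuple(imaging_days),
        harvest_days=tuple(harvest_days),
        photoperiod_h=photoperiod_h,
        seed=seed,
        light_field=field,
        trajectories=traj,
        plant_effects=effects,
        assignment=assignment,
        harvest=harvest,
        truth=truth,
        geometry=geometry,
    )


def write_experiment(
    exp: SyntheticExperiment,
    out_dir: str | Path,
    write_images: bool = True,
    mode: str = "rosette",
) -> Path:
    """Write light_map.csv, harvest.csv, truth.csv, experiment.yaml and
    16-bit grayscale PNG frames ``images/plant{ID}_day{D}.png``."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp.light_field.to_csv(out / "light_map.csv", index=False)
    exp.harvest.to_csv(out / "harvest.csv", index=False)
    exp.truth.to_csv(out / "truth.csv", index=False)
    cfg = {
        "study": exp.gradient.mode,
        "seed": exp.seed,
        "photoperiod_h": exp.photoperiod_h,
        "imaging_days": list(exp.imaging_days),
        "harvest_days": list(exp.harvest_days),
        "cm_per_pixel": exp.geometry.cm_per_pixel,
        "marker_length_cm": exp.geometry.marker_length_cm,
    }
    (out / "experiment.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    if write_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for im in exp.iter_images(mode=mode):
            iio.imwrite(img_dir / f"plant{im.plant_id}_day{im.day}.png", im.pixels)
    return out
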
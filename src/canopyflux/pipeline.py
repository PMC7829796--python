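"""Configuration, table validation and orchestration of the analysis.

The pipeline chains the stage modules over plain-CSV intermediates —

    simulate -> segment -> fit -> budget -> stats

— so every stage can be rerun from the previous stage's files, and a
(config, seed) pair fully determines every output byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import budget as _budget
from . import growth as _growth
from . import imaging as _imaging
from . import stats as _stats
from . import synth as _synth

__all__ = [
    "ExperimentConfig",
    "AnalysisReport",
    "ValidationReport",
    "run_pipeline",
    "validate_tables",
    "merged_table",
    "stats_tables",
]

log = logging.getLogger("canopyflux")

MODEL_RESPONSES = [
    ("dry_weight_g", "dry_weight"),
    ("cum_total_mol", "incident_light"),
    ("leaf_length_cm", "length"),
    ("leaf_width_cm", "width"),
]


@dataclass
class ExperimentConfig:
    """Everything needed to (re)run one experiment end to end."""

    study: str = "perpendicular"  # or "fr-gradient"
    seed: int = 0
    photoperiod_h: float = 18.0
    imaging_days: tuple[int, ...] = _synth.DEFAULT_IMAGING_DAYS
    harvest_days: tuple[int, int] = _synth.DEFAULT_HARVEST_DAYS
    germination_day: int = 0
    threshold: float | None = 10000
    min_object_px: int = 0
    cm_per_pixel: float | None = 0.06
    marker_length_cm: float = 3.0
    include_harvest_day: bool = False
    zero_noise: bool = False
    alpha: float = 0.05
    image_size: tuple[int, int] = (896, 896)

    def __post_init__(self) -> None:
        if not self.harvest_days[0] < self.harvest_days[1]:
            raise ValueError("early harvest day must precede the late one")
        if self.harvest_days[1] > max(self.imaging_days):
            raise ValueError("harvest days must lie within the imaging window")

    @property
    def gradient(self) -> _synth.GradientSpec:
        if self.study == "perpendicular":
            return _synth.STUDY2_PERPENDICULAR
        if self.study == "fr-gradient":
            return _synth.STUDY1_FR_GRADIENT
        raise ValueError(f"unknown study {self.study!r}")

    @property
    def geometry(self) -> _imaging.ImageGeometry:
        h, w = self.image_size
        return _imaging.ImageGeometry(
            height=h,
            width=w,
            cm_per_pixel=self.cm_per_pixel if self.cm_per_pixel else 0.06,
            marker_length_cm=self.marker_length_cm,
            marker_rows=(h - 18, h - 8),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["imaging_days"] = list(self.imaging_days)
        d["harvest_days"] = list(self.harvest_days)
        d["image_size"] = list(self.image_size)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("imaging_days", "harvest_days", "image_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class AnalysisReport:
    """All result tables of one pipeline run plus provenance."""

    per_plant: pd.DataFrame
    models: pd.DataFrame
    efficacy: pd.DataFrame
    correlations: pd.DataFrame
    provenance: dict = field(default_factory=dict)


@dataclass
class ValidationReport:
    passed: bool
    issues: list


def merged_table(
    light_map: pd.DataFrame,
    harvest: pd.DataFrame,
    budget_table: pd.DataFrame,
    daily_pcs: pd.DataFrame,
) -> pd.DataFrame:
    """One row per harvested plant with light, harvest and budget data."""
    pcs_h = harvest[["plant_id", "harvest_day"]].merge(
        daily_pcs, left_on=["plant_id", "harvest_day"], right_on=["plant_id", "day"]
    )[["plant_id", "pcs_cm2"]].rename(columns={"pcs_cm2": "pcs_harvest_cm2"})
    out = (
        harvest.merge(light_map[["plant_id", "ppfd_umol_m2_s", "fr_umol_m2_s"]], on="plant_id")
        .merge(budget_table, on="plant_id")
        .merge(pcs_h, on="plant_id")
    )
    return out.sort_values("plant_id", ignore_index=True)


def stats_tables(
    merged: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fit the response models per harvest and derive efficacy ratios
    and the standard correlation set."""
    model_rows, efficacy_rows, corr_rows = [], [], []
    for label, grp in merged.groupby("harvest"):
        for response, name in MODEL_RESPONSES:
            fit = _stats.fit_response_model(grp, response, alpha=alpha)
            for term in ("intercept", *fit.terms):
                model_rows.append(
                    (
                        name,
                        label,
                        term,
                        fit.coef[term],
                        fit.se[term],
                        fit.p_values[term],
                        fit.r_squared,
                        fit.n,
                    )
                )
            if "fr" in fit.terms and "ppfd" in fit.terms and fit.coef["ppfd"] != 0:
                eff = _stats.efficacy_ratio(fit)
                efficacy_rows.append(
                    (name, label, eff.slope_fr, eff.slope_ppfd, eff.percent_more_effective)
                )
        pairs = [
            ("leaf_width_cm", "leaf_area_cm2"),
            ("leaf_width_cm", "pcs_harvest_cm2"),
            ("cum_total_mol", "dry_weight_g"),
            ("sla_cm2_g", "lue_total_g_mol"),
        ]
        for x, y in pairs:
            c = _stats.correlate(grp[x], grp[y], x_name=x, y_name=y)
            corr_rows.append((x, y, label, c.pearson_r, c.p_value, c.slope, c.intercept, c.n))
    models = pd.DataFrame(
        model_rows,
        columns=["response", "harvest", "term", "coefficient", "se", "p", "r_squared", "n"],
    )
    efficacy = pd.DataFrame(
        efficacy_rows,
        columns=["response", "harvest", "slope_fr", "slope_ppfd", "percent_more_effective"],
    )
    correlations = pd.DataFrame(
        corr_rows,
        columns=["x", "y", "harvest", "pearson_r", "p", "slope", "intercept", "n"],
    )
    return models, efficacy, correlations


def run_pipeline(
    config: ExperimentConfig,
    out_dir: str | Path,
    simulate: bool = True,
    write_images: bool = True,
) -> AnalysisReport:
    """Execute simulate -> segment -> fit -> budget -> stats.

    With ``simulate=True`` a synthetic experiment is generated first;
    otherwise ``out_dir`` must already contain ``images/``,
    ``light_map.csv`` and ``harvest.csv``.  All intermediate CSVs are
    written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = config.geometry

    if simulate:
        log.info("stage simulate: %s study, seed %d", config.study, config.seed)
        params = _synth.TruePlantParams()
        if config.zero_noise:
            params = params.without_noise()
        exp = _synth.simulate_experiment(
            gradient=config.gradient,
            params=params,
            imaging_days=config.imaging_days,
            harvest_days=config.harvest_days,
            photoperiod_h=config.photoperiod_h,
            seed=config.seed,
            geometry=geometry,
            include_harvest_day=config.include_harvest_day,
        )
        _synth.write_experiment(exp, out, write_images=write_images)

    log.info("stage segment")
    if write_images or not simulate:
        pcs_series = _imaging.segment_directory(
            out / "images",
            config.threshold,
            geometry=geometry,
            min_object_px=config.min_object_px,
            calibrate=config.cm_per_pixel is None,
        )
    else:  # imageless run: generator's measured series stands in for segmentation
        pcs_series = exp.pcs_series()
        pcs_series["pixel_count"] = np.round(
            pcs_series["pcs_cm2"] / geometry.cm_per_pixel**2
        ).astype(int)
        pcs_series["cm_per_pixel"] = geometry.cm_per_pixel
        pcs_series["threshold"] = config.threshold
    pcs_series.to_csv(out / "pcs_series.csv", index=False)

    log.info("stage fit")
    curves = _growth.fit_growth_curves(pcs_series)
    curves.to_csv(out / "growth_curves.csv", index=False)
    light_map = pd.read_csv(out / "light_map.csv")
    harvest = pd.read_csv(out / "harvest.csv")
    harvest_day = harvest.set_index("plant_id")["harvest_day"]
    daily = _growth.daily_pcs_table(curves, harvest_day, first_day=config.germination_day)
    daily.to_csv(out / "daily_pcs.csv", index=False)

    log.info("stage budget")
    budget_table = _budget.light_budget_table(
        daily,
        light_map,
        harvest,
        photoperiod_h=config.photoperiod_h,
        include_harvest_day=config.include_harvest_day,
    )
    budget_table.to_csv(out / "light_budget.csv", index=False)

    log.info("stage stats")
    merged = merged_table(light_map, harvest, budget_table, daily)
    merged.to_csv(out / "merged.csv", index=False)
    models, efficacy, correlations = stats_tables(merged, alpha=config.alpha)
    models.to_csv(out / "models.csv", index=False)
    efficacy.to_csv(out / "efficacy.csv", index=False)
    correlations.to_csv(out / "correlations.csv", index=False)

    return AnalysisReport(
        per_plant=merged,
        models=models,
        efficacy=efficacy,
        correlations=correlations,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        },
    )


# ---------------------------------------------------------------------------
# table validation

_SCHEMAS = {
    "pcs_series": {
        "required": ["plant_id", "day", "pcs_cm2"],
        "unique": ["plant_id", "day"],
        "non_negative": ["pcs_cm2"],
    },
    "light_map": {
        "required": ["plant_id", "ppfd_umol_m2_s", "fr_umol_m2_s"],
        "unique": ["plant_id"],
        "positive": ["ppfd_umol_m2_s"],
        "non_negative": ["fr_umol_m2_s"],
    },
    "harvest": {
        "required": [
            "plant_id",
            "harvest_day",
            "leaf_length_cm",
            "leaf_width_cm",
            "leaf_area_cm2",
            "dry_weight_g",
        ],
        "unique": ["plant_id"],
        "non_negative": ["leaf_length_cm", "leaf_width_cm", "leaf_area_cm2", "dry_weight_g"],
    },
}


def validate_tables(paths: dict[str, str | Path]) -> ValidationReport:
    """Check table schemas: required columns, key uniqueness, positivity.

    ``paths`` maps a schema name (``pcs_series``, ``light_map``,
    ``harvest``) to a CSV file.  Returns pass/fail with row-level
    diagnostics.
    """
    issues = []
    for name, path in paths.items():
        if name not in _SCHEMAS:
            issues.append((name, None, f"unknown table kind {name!r}"))
            continue
        schema = _SCHEMAS[name]
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # unreadable file is itself a finding
            issues.append((name, None, f"unreadable: {exc}"))
            continue
        missing = [c for c in schema["required"] if c not in df.columns]
        if missing:
            issues.append((name, None, f"missing columns {missing}"))
            continue
        key = schema["unique"]
        dup = df[df.duplicated(subset=key, keep=False)]
        for idx in dup.index:
            issues.append((name, int(idx), f"duplicate key {tuple(dup.loc[idx, key])}"))
        for col in schema.get("positive", []):
            bad = df.index[df[col] <= 0]
            for idx in bad:
                issues.append((name, int(idx), f"{col} must be > 0 (got {df.loc[idx, col]})"))
        for col in schema.get("non_negative", []):
            bad = df.index[df[col] < 0]
            for idx in bad:
                issues.append((name, int(idx), f"{col} must be >= 0 (got {df.loc[idx, col]})"))
    return ValidationReport(passed=not issues, issues=issues)
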
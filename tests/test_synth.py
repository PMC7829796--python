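"""Generator: light fields, growth trajectories, harvests, rendering."""

import numpy as np
import pandas as pd
import pytest

from canopyflux import imaging, synth
from canopyflux.synth import (
    STUDY1_FR_GRADIENT,
    STUDY2_PERPENDICULAR,
    GradientSpec,
    TruePlantParams,
)


class TestLightField:
    def test_perpendicular_gradients_span_and_orthogonality(self):
        field = synth.make_light_field(STUDY2_PERPENDICULAR, seed=0)
        assert len(field) == 60
        by_col = field.groupby("col")["ppfd_umol_m2_s"].first()
        assert by_col.min() == pytest.approx(111.0)
        assert by_col.max() == pytest.approx(245.0)
        by_row = field.groupby("row")["fr_umol_m2_s"].first()
        assert by_row.min() == pytest.approx(4.7)
        assert by_row.max() == pytest.approx(32.8)
        # orthogonal gradients are uncorrelated across the full grid
        r = np.corrcoef(field["ppfd_umol_m2_s"], field["fr_umol_m2_s"])[0, 1]
        assert abs(r) < 1e-12

    def test_uniform_mode_zero_noise_is_exact(self):
        spec = GradientSpec(
            mode="uniform_ppfd_fr_gradient",
            ppfd_range=(207.0, 207.0),
            fr_range=(4.9, 28.0),
            ppfd_noise_sd=0.0,
        )
        field = synth.make_light_field(spec, seed=3)
        assert (field["ppfd_umol_m2_s"] == 207.0).all()
        assert field["fr_umol_m2_s"].min() == pytest.approx(4.9)
        assert field["fr_umol_m2_s"].max() == pytest.approx(28.0)

    def test_uniform_mode_noise_moments(self):
        field = synth.make_light_field(STUDY1_FR_GRADIENT, seed=202)
        ppfd = field["ppfd_umol_m2_s"]
        assert abs(ppfd.mean() - 207.0) < 5.0
        assert 8.0 <= ppfd.std() <= 18.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GradientSpec(mode="perpendicular_gradients", ppfd_range=(-5, 100), fr_range=(1, 2))
        with pytest.raises(ValueError):
            GradientSpec(mode="perpendicular_gradients", ppfd_range=(245, 111), fr_range=(1, 2))
        with pytest.raises(ValueError):
            GradientSpec(mode="sideways", ppfd_range=(1, 2), fr_range=(1, 2))


class TestGrowth:
    def test_no_light_dependence_gives_identical_trajectories(self):
        field = synth.make_light_field(STUDY2_PERPENDICULAR, seed=0)
        params = TruePlantParams(fr_pcs_slope=0.0, ppfd_pcs_slope=0.0).without_noise()
        traj, _ = synth.simulate_growth(field, params, range(0, 26), seed=1)
        per_day = traj.groupby("day")["pcs_cm2"].nunique()
        assert (per_day == 1).all()

    def test_closed_form_at_germination(self):
        field = synth.make_light_field(STUDY2_PERPENDICULAR, seed=0)
        params = TruePlantParams(
            pcs_curve=(1.0, 0.2, -0.004), fr_pcs_slope=0.0, ppfd_pcs_slope=0.0
        ).without_noise()
        traj, _ = synth.simulate_growth(field, params, range(0, 5), seed=1)
        day0 = traj[traj["day"] == 0]["pcs_cm2"]
        assert np.allclose(day0, np.e)

    def test_far_red_monotonicity(self):
        field = synth.make_light_field(STUDY2_PERPENDICULAR, seed=0)
        params = TruePlantParams().without_noise()
        traj, _ = synth.simulate_growth(field, params, range(0, 26), seed=1)
        merged = traj.merge(field, on="plant_id")
        same_ppfd = merged[merged["col"] == 4]
        lo = same_ppfd[same_ppfd["row"] == 0].set_index("day")["pcs_cm2"]
        hi = same_ppfd[same_ppfd["row"] == 5].set_index("day")["pcs_cm2"]
        days = [d for d in lo.index if d > 0]
        assert all(hi.loc[d] > lo.loc[d] for d in days)

    def test_capacity_guard(self):
        field = synth.make_light_field(STUDY2_PERPENDICULAR, seed=0)
        params = TruePlantParams().without_noise()
        with pytest.raises(ValueError, match="exceed"):
            synth.simulate_growth(field, params, range(0, 26), seed=1, max_pcs_cm2=100.0)


@pytest.fixture(scope="module")
def zero_noise_parts():
    params = TruePlantParams().without_noise()
    field = synth.make_light_field(STUDY2_PERPENDICULAR, seed=0)
    traj, _ = synth.simulate_growth(field, params, range(0, 26), seed=1)
    assign = synth.assign_harvests(field, (16, 25), seed=2)
    return field, traj, assign, params


class TestHarvest:
    def test_zero_noise_leaf_area_equals_pcs(self, zero_noise_parts):
        field, traj, assign, params = zero_noise_parts
        harvest, truth = synth.simulate_harvest(
            field, traj, assign, params, seed=3, overlap_true=(1.0, 1.0)
        )
        joined = harvest.merge(truth, on="plant_id")
        assert np.allclose(joined["leaf_area_cm2"], joined["pcs_at_harvest_cm2"])

    def test_zero_noise_dry_weight_inverts_to_lue(self, zero_noise_parts):
        field, traj, assign, params = zero_noise_parts
        harvest, truth = synth.simulate_harvest(field, traj, assign, params, seed=3)
        joined = harvest.merge(truth, on="plant_id")
        recovered = joined["dry_weight_g"] / joined["cum_total_mol"]
        assert np.allclose(recovered, params.true_lue_total)

    def test_reference_width_arithmetic(self, zero_noise_parts):
        # width = 3.276 + 0.0966*10 + 0.0152*200 = 7.282 cm
        field, traj, assign, params = zero_noise_parts
        field = field.copy()
        field["fr_umol_m2_s"] = 10.0
        field["ppfd_umol_m2_s"] = 200.0
        harvest, _ = synth.simulate_harvest(field, traj, assign, params, seed=3)
        early = harvest[harvest["harvest"] == "early"]
        assert np.allclose(early["leaf_width_cm"], 7.282)

    def test_stratified_split_spans_gradient(self, zero_noise_parts):
        field, traj, assign, params = zero_noise_parts
        merged = assign.merge(field, on="plant_id")
        for label in ("early", "late"):
            sub = merged[merged["harvest"] == label]
            assert len(sub) == 30
            assert sub["fr_umol_m2_s"].min() == pytest.approx(4.7)
            assert sub["fr_umol_m2_s"].max() == pytest.approx(32.8)

    def test_negative_measurements_truncated_with_warning(self, zero_noise_parts):
        field, traj, assign, _ = zero_noise_parts
        params = TruePlantParams(
            morphology={k: (0.0, 0.0, 0.0) for k in synth.DEFAULT_MORPHOLOGY},
            noise_sds={**synth.DEFAULT_NOISE, "width_cm": 5.0, "length_cm": 5.0},
        )
        with pytest.warns(UserWarning, match="truncated"):
            harvest, _ = synth.simulate_harvest(field, traj, assign, params, seed=4)
        assert (harvest["leaf_width_cm"] > 0).all()

    def test_determinism(self, zero_noise_parts):
        field, traj, assign, params = zero_noise_parts
        h1, _ = synth.simulate_harvest(field, traj, assign, params, seed=9)
        h2, _ = synth.simulate_harvest(field, traj, assign, params, seed=9)
        pd.testing.assert_frame_equal(h1, h2)


class TestRendering:
    def test_empty_canopy_renders_marker_only(self, geometry):
        im = synth.render_fluorescence_image(0.0, geometry, seed=0)
        rec = imaging.measure_pcs(im, 10000)
        assert rec.pixel_count == 0

    def test_area_matches_request(self):
        geom = imaging.ImageGeometry(cm_per_pixel=0.05)
        im = synth.render_fluorescence_image(100.0, geom, seed=1)
        rec = imaging.measure_pcs(im, 10000)
        assert abs(rec.pixel_count - 40000) <= 0.02 * 40000

    def test_bit_identical_for_same_seed(self, geometry):
        a = synth.render_fluorescence_image(77.7, geometry, seed=42)
        b = synth.render_fluorescence_image(77.7, geometry, seed=42)
        assert np.array_equal(a.pixels, b.pixels)

    def test_oversized_canopy_rejected(self, geometry):
        with pytest.raises(ValueError, match="field of view"):
            synth.render_fluorescence_image(5e4, geometry, seed=0)


def test_experiment_schedule_respects_harvest(zero_noise_experiment):
    exp = zero_noise_experiment
    sched = exp._schedule().merge(exp.assignment, on="plant_id")
    assert (sched["day"] <= sched["harvest_day"]).all()
    counts = sched.groupby("plant_id")["day"].count()
    merged = counts.rename("n").reset_index().merge(exp.assignment, on="plant_id")
    assert (merged.loc[merged["harvest"] == "early", "n"] == 5).all()
    assert (merged.loc[merged["harvest"] == "late", "n"] == 8).all()


def test_write_experiment_round_trip(tmp_path, zero_noise_experiment):
    out = synth.write_experiment(zero_noise_experiment, tmp_path, write_images=False)
    light = pd.read_csv(out / "light_map.csv")
    harvest = pd.read_csv(out / "harvest.csv")
    assert len(light) == 60 and len(harvest) == 60
    assert (out / "experiment.yaml").exists()
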
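"""Synthetic generator: growth model, death process, rendering, fixtures."""

import numpy as np
import pytest
from scipy import stats as sps

from rosettescreen.growth_traits import GrowthSeries, mean_rgr
from rosettescreen.plate_imaging import SegmentationParams, build_grid, measure_wells, segment_green
from rosettescreen.synthetic_data import (
    SyntheticScenario,
    VariantSpec,
    default_layout,
    render_plates,
    simulate_growth,
    two_group_scenario,
    write_fixture,
)


def noiseless_variant(**kw):
    kw.setdefault("substance", "S")
    kw.setdefault("dose", 0.001)
    kw.setdefault("condition", 0)
    kw.setdefault("initial_area_sigma", 0.0)
    kw.setdefault("growth_rate_sd", 0.0)
    return VariantSpec(**kw)


def plant_series(truth, plant_id):
    grp = truth.areas[truth.areas["plant_id"] == plant_id].sort_values("time_days")
    return GrowthSeries(
        plant_id=plant_id,
        variant_id="v",
        timestamps=grp["time_days"].to_numpy(),
        areas=grp["area_px"].to_numpy().astype(float),
    )


class TestSimulateGrowth:
    def test_noiseless_log_area_is_exactly_linear(self):
        sc = SyntheticScenario(
            variants=[noiseless_variant(growth_rate=0.3)], plates_per_variant=1
        )
        truth = simulate_growth(sc)
        for plant_id, grp in truth.areas.groupby("plant_id"):
            # r_eff drawn with sd 0 ⇒ exactly the configured rate
            row = truth.plants.set_index("plant_id").loc[plant_id]
            assert row["r_eff"] == pytest.approx(0.3, abs=1e-15)
            t = grp["time_days"].to_numpy()
            a = row["initial_area"] * np.exp(0.3 * t)
            assert np.allclose(grp["blob_px"], np.round(a))

    def test_fifteen_timepoints_twice_daily_over_seven_days(self):
        sc = SyntheticScenario(variants=[noiseless_variant()])
        times = sc.imaging_times()
        assert times.size == 15
        assert times[0] == 0.0 and times[-1] == 7.0
        assert 1.25 in times  # p.m. image as fractional day

    def test_death_process_matches_geometric_expectation(self):
        """Daily death prob 0.1 over 7 days → survival ~ Binomial(n, 0.9⁷);
        the realized rate must fall in the 95% CI around 47.83%."""
        sc = SyntheticScenario(
            variants=[
                noiseless_variant(condition=150, daily_death_prob=0.1, growth_rate=0.2)
            ],
            plates_per_variant=10,  # n = 480 for a tight check
            rng_seed=11,
        )
        truth = simulate_growth(sc)
        expected = 0.9**7
        assert truth.expected_survival(sc.variants[0].variant_id) == pytest.approx(
            100 * expected
        )
        final = truth.areas[truth.areas["time_days"] == 7.0]
        n = len(final)
        observed = final["alive"].mean()
        half = 1.96 * np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= half

    def test_dead_plants_have_non_increasing_blob_and_zero_green_area(self):
        sc = SyntheticScenario(
            variants=[noiseless_variant(condition=150, daily_death_prob=0.5)],
            plates_per_variant=1,
            rng_seed=2,
        )
        truth = simulate_growth(sc)
        died = truth.plants.dropna(subset=["death_day"])
        assert len(died) > 0
        for rec in died.itertuples():
            grp = truth.areas[truth.areas["plant_id"] == rec.plant_id].sort_values(
                "time_days"
            )
            dead_part = grp[grp["time_days"] >= rec.death_day]
            assert (dead_part["area_px"] == 0).all()
            assert (np.diff(dead_part["blob_px"]) <= 0).all()

    def test_determinism_under_fixed_seed(self):
        sc = two_group_scenario(seed=5)
        t1 = simulate_growth(sc)
        t2 = simulate_growth(sc)
        assert t1.plants.equals(t2.plants) and t1.areas.equals(t2.areas)

    def test_different_seeds_differ(self):
        a = simulate_growth(two_group_scenario(seed=1))
        b = simulate_growth(two_group_scenario(seed=2))
        assert not np.allclose(
            a.plants["initial_area"].to_numpy(), b.plants["initial_area"].to_numpy()
        )


class TestRenderPlates:
    def test_rendered_blob_count_matches_truth_through_segmentation(self):
        """A 314-px rosette renders to 314 green-criterion pixels."""
        v = noiseless_variant(initial_area_mean=314.0, growth_rate=0.0)
        sc = SyntheticScenario(variants=[v], plates_per_variant=1, n_days=0)
        truth = simulate_growth(sc)
        images = render_plates(truth)
        grid = build_grid(sc.layout)
        mask = segment_green(images[0], SegmentationParams())
        records = measure_wells(mask, grid)
        for r in records:
            assert abs(r.area_px - 314) <= 6

    def test_zero_area_renders_an_empty_well(self):
        v = noiseless_variant(initial_area_mean=1e-9, growth_rate=0.0)
        sc = SyntheticScenario(variants=[v], plates_per_variant=1, n_days=0)
        images = render_plates(simulate_growth(sc))
        mask = segment_green(images[0], SegmentationParams())
        assert mask.mask.sum() == 0

    def test_dead_plants_do_not_match_the_green_criterion(self):
        v = noiseless_variant(condition=150, daily_death_prob=1.0, growth_rate=0.2)
        sc = SyntheticScenario(variants=[v], plates_per_variant=1, rng_seed=3)
        truth = simulate_growth(sc)
        final = [im for im in render_plates(truth) if im.time_days == 7.0]
        mask = segment_green(final[0], SegmentationParams())
        assert mask.mask.sum() == 0  # everything died on day 1 and browned

    def test_end_to_end_recovery_within_five_percent(self, stress_scenario):
        """Pipeline areas from rendered plates track ground truth within ±5%
        for rosettes above the survival threshold."""
        sc = stress_scenario
        truth = simulate_growth(sc)
        images = render_plates(truth)
        grid = build_grid(sc.layout)
        measured = {}
        for img in images:
            for r in measure_wells(segment_green(img, SegmentationParams()), grid):
                measured[(r.plate_id, r.row, r.col, r.time_days)] = r.area_px
        checked = 0
        for rec in truth.areas.itertuples():
            if rec.area_px >= 100:
                got = measured[(rec.plate_id, rec.row, rec.col, rec.time_days)]
                assert abs(got - rec.area_px) <= 0.05 * rec.area_px
                checked += 1
        assert checked > 1000

    def test_oversized_rosette_is_clipped_to_the_well(self, caplog):
        v = noiseless_variant(initial_area_mean=10_000.0, growth_rate=0.0)
        layout = default_layout(pitch=40)
        sc = SyntheticScenario(
            variants=[v], plates_per_variant=1, n_days=0, layout=layout
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="rosettescreen.synthetic_data"):
            images = render_plates(simulate_growth(sc))
        assert any("clipped" in m for m in caplog.messages)
        mask = segment_green(images[0], SegmentationParams())
        assert mask.mask.sum() == 48 * 40 * 40  # every well fully green


class TestWriteFixture:
    def test_same_seed_gives_identical_fixture_bytes(self, tmp_path):
        sc = two_group_scenario(seed=9, include_control_condition=False)
        sc.plates_per_variant = 1
        sc.n_days = 2
        p1 = write_fixture(sc, tmp_path / "a")
        p2 = write_fixture(sc, tmp_path / "b")
        for key in ("manifest", "plants", "areas", "scenario"):
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()
        import pandas as pd

        m = pd.read_csv(p1["manifest"])
        f = m["filename"].iloc[0]
        assert (
            open(tmp_path / "a" / f, "rb").read() == open(tmp_path / "b" / f, "rb").read()
        )

    def test_default_scenario_counts(self, tmp_path):
        sc = two_group_scenario(seed=0, include_control_condition=False)
        paths = write_fixture(sc, tmp_path)
        import pandas as pd

        manifest = pd.read_csv(paths["manifest"])
        # 2 variants × 2 plates × 15 timepoints
        assert len(manifest) == 2 * 2 * 15
        areas = pd.read_csv(paths["areas"])
        assert len(areas) == 2 * 2 * 48 * 15

    def test_parameter_recovery_from_simulated_areas(self):
        """mean RGR over 96 plants recovers r_eff within ±10%."""
        sc = two_group_scenario(seed=21, include_control_condition=False)
        truth = simulate_growth(sc)
        for spec in sc.variants:
            plants = truth.plants[truth.plants["variant_id"] == spec.variant_id]
            rates = [
                mean_rgr(plant_series(truth, pid))
                for pid in plants["plant_id"].head(96)
            ]
            rates = [r for r in rates if np.isfinite(r)]
            assert np.mean(rates) == pytest.approx(spec.r_eff, rel=0.10)
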
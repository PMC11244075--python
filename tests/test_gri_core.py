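import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gri_toolkit import gri_core as gc
from gri_toolkit.gri_core import (
    AnnualGRIMap,
    AnomalyEvent,
    annual_gri_series,
    climatology,
    detect_anomalies,
    detect_anomalies_series,
    monthly_aggregate,
    normalize_gri,
    steps_to_months,
)
from gri_toolkit.raster_io import Grid, LAIStack
from gri_toolkit.synthetic_scene import SceneConfig, generate_scene


def _one_pixel_stack(steps_per_year, per_step_values, years):
    grid = Grid(0, 1, 1, 1, (1, 1))
    vals = np.asarray(per_step_values, dtype=float).reshape(
        len(years), steps_per_year, 1, 1
    )
    return LAIStack(grid, np.asarray(years), steps_per_year, vals)


class TestMonthlyAggregate:
    def test_composites_map_to_five_months_of_four(self):
        months = steps_to_months(20)
        np.testing.assert_array_equal(np.unique(months), [5, 6, 7, 8, 9])
        for m in (5, 6, 7, 8, 9):
            assert np.sum(months == m) == 4

    def test_month_mean_of_valid_composites(self):
        # one year, 20 steps; May composites 1.0,1.2,1.4 and one NaN
        vals = np.full(20, 2.0)
        vals[:4] = [1.0, 1.2, 1.4, np.nan]
        stack = _one_pixel_stack(20, vals, [2000])
        monthly = monthly_aggregate(stack)
        assert monthly.values[0, 0, 0, 0] == pytest.approx(1.2)

    def test_all_invalid_month_is_nodata(self):
        vals = np.full(20, 1.5)
        vals[4:8] = np.nan  # June entirely missing
        monthly = monthly_aggregate(_one_pixel_stack(20, vals, [2000]))
        assert np.isnan(monthly.values[0, 1, 0, 0])
        assert np.isfinite(monthly.values[0, 0, 0, 0])


class TestClimatology:
    def test_mean_and_population_std(self):
        grid = Grid(0, 1, 1, 1, (1, 1))
        monthly = gc.MonthlyCube(
            grid, np.array([2000, 2001]), (5,),
            np.array([1.0, 3.0]).reshape(2, 1, 1, 1),
        )
        clim = climatology(monthly, beta=1.0)
        assert clim.mean_j[0, 0, 0] == pytest.approx(2.0)
        assert clim.std_j[0, 0, 0] == pytest.approx(1.0)  # divide by N
        assert clim.band_floor[0, 0, 0] == pytest.approx(1.0)

    def test_sample_std_option(self):
        grid = Grid(0, 1, 1, 1, (1, 1))
        monthly = gc.MonthlyCube(
            grid, np.array([2000, 2001]), (5,),
            np.array([1.0, 3.0]).reshape(2, 1, 1, 1),
        )
        clim = climatology(monthly, std_mode="sample")
        assert clim.std_j[0, 0, 0] == pytest.approx(np.sqrt(2.0))

    def test_single_valid_year_is_nodata(self):
        grid = Grid(0, 1, 1, 1, (1, 1))
        monthly = gc.MonthlyCube(
            grid, np.array([2000, 2001]), (5,),
            np.array([1.0, np.nan]).reshape(2, 1, 1, 1),
        )
        clim = climatology(monthly)
        assert np.isnan(clim.mean_j[0, 0, 0])


class TestDetectAnomalies:
    def test_single_event_depth_and_recovery(self):
        # band floor 1.6 (mean 2.0, std 0.4, beta 1); months 2-3 below band
        floor = np.full(4, 1.6)
        series = np.array([2.0, 1.1, 1.5, 1.9])
        events = detect_anomalies_series(series, floor, np.array([2000]),
                                         (5, 6, 7, 8))
        assert len(events) == 1
        ev = events[0]
        assert ev.lai_lowest == pytest.approx(1.1)
        assert ev.ms == pytest.approx(0.5)
        assert ev.rt == 2
        assert ev.resolved and ev.start_month == 6

    def test_series_inside_band_yields_no_events(self):
        floor = np.full(5, 1.0)
        events = detect_anomalies_series(np.full(5, 1.5), floor,
                                         np.array([2000]), (5, 6, 7, 8, 9))
        assert events == []

    def test_rt_counts_from_trough_not_run_start(self):
        # below band at months 1-3, minimum at month 2: Rt = 2
        floor = np.full(5, 2.0)
        series = np.array([2.5, 1.8, 1.2, 1.6, 2.4])
        (ev,) = detect_anomalies_series(series, floor, np.array([2000]),
                                        (5, 6, 7, 8, 9))
        assert ev.start_month == 7 and ev.rt == 2
        assert ev.ms == pytest.approx(0.8)

    def test_no_return_within_record_is_unresolved(self):
        floor = np.full(3, 1.0)
        series = np.array([1.5, 0.4, 0.6])
        (ev,) = detect_anomalies_series(series, floor, np.array([2000]),
                                        (5, 6, 7))
        assert not ev.resolved and ev.rt is None
        assert ev.ms == pytest.approx(0.6)

    def test_cross_season_event_concatenates_years(self):
        # 2 years x 2 months; below band in Sep yr1 and May yr2
        floor = np.full(4, 1.0)
        series = np.array([1.2, 0.5, 0.8, 1.1])
        (ev,) = detect_anomalies_series(series, floor, np.array([2000, 2001]),
                                        (5, 9))
        assert ev.start_year == 2000 and ev.rt == 2 and ev.cross_year

    def test_zero_noise_scene_recovers_every_injected_event(self, scene_zero_noise):
        scene = scene_zero_noise
        monthly = monthly_aggregate(scene.stack)
        clim = climatology(monthly, beta=scene.config.beta)
        events = detect_anomalies(monthly, clim)
        key = lambda e: (e.pixel, e.start_year, e.start_month)
        assert sorted(events, key=key) == sorted(scene.truth.events, key=key)
        # recovered events carry the designed depth and duration
        specs = {(s.pixel, s.start_year, s.start_month): s
                 for s in scene.truth.specs}
        matched = 0
        for ev in events:
            sp = specs.get((ev.pixel, ev.start_year, ev.start_month))
            if sp is None:
                continue
            matched += 1
            assert ev.ms == pytest.approx(sp.depth, abs=1e-9)
            if ev.resolved:
                assert ev.rt == sp.duration
        assert matched == len(specs) == len(events)


class TestAnnualGRI:
    def test_event_year_then_carry_forward(self):
        ev = AnomalyEvent(0, 2003, 6, ms=0.5, rt=2, resolved=True, lai_lowest=1.0)
        gri, prov = annual_gri_series([ev], [2002, 2003, 2004])
        assert np.isnan(gri[0])  # leading year: no donor
        assert gri[1] == pytest.approx(0.25)
        assert gri[2] == pytest.approx(0.25)  # inherited
        assert prov.tolist() == [gc.PROV_NODATA, gc.PROV_COMPUTED, gc.PROV_CARRIED]

    def test_multiple_events_in_a_year_average(self):
        evs = [
            AnomalyEvent(0, 2003, 5, ms=0.4, rt=2, resolved=True, lai_lowest=1.0),
            AnomalyEvent(0, 2003, 8, ms=0.4, rt=1, resolved=True, lai_lowest=1.0),
        ]
        gri, prov = annual_gri_series(evs, [2003])
        assert gri[0] == pytest.approx((0.2 + 0.4) / 2)
        assert prov[0] == gc.PROV_AVERAGED

    def test_cross_year_event_attributed_to_recovery_start(self):
        ev = AnomalyEvent(0, 2005, 9, ms=0.6, rt=2, resolved=True,
                          lai_lowest=1.0, cross_year=True)
        gri, _ = annual_gri_series([ev], [2005, 2006])
        assert gri[0] == pytest.approx(0.3)
        assert gri[1] == pytest.approx(0.3)  # 2006 inherits

    def test_unresolved_events_contribute_nothing(self):
        ev = AnomalyEvent(0, 2003, 6, ms=0.5, rt=None, resolved=False,
                          lai_lowest=1.0)
        gri, _ = annual_gri_series([ev], [2003, 2004])
        assert np.all(np.isnan(gri))

    def test_zero_noise_annual_truth_reproduced(self, scene_zero_noise):
        from gri_toolkit import compute_gri

        scene = scene_zero_noise
        gri_map, _ = compute_gri(scene.stack, beta=scene.config.beta)
        assert np.array_equal(gri_map.raw, scene.truth.annual_raw, equal_nan=True)


class TestNormalize:
    def _map_of(self, values):
        grid = Grid(0, 1, 1, 1, (1, len(values)))
        return AnnualGRIMap(grid, np.array([2000]),
                            np.asarray(values, float).reshape(1, 1, -1))

    def test_min_max_rescale(self):
        out = normalize_gri(self._map_of([0.10, 0.14, 0.22]), scope="per_year")
        np.testing.assert_allclose(out.normalized[0, 0], [0.0, 1 / 3, 1.0])

    def test_degenerate_scope_maps_to_zero(self):
        out = normalize_gri(self._map_of([0.3, 0.3, 0.3]))
        np.testing.assert_array_equal(out.normalized[0, 0], [0, 0, 0])

    @pytest.mark.parametrize("scope", ["per_year", "global"])
    def test_bounds_and_extremes(self, scope, scene_zero_noise):
        from gri_toolkit import compute_gri

        gri_map, _ = compute_gri(scene_zero_noise.stack,
                                 normalization_scope=scope)
        norm = gri_map.normalized
        valid = np.isfinite(norm)
        assert np.nanmin(norm[valid]) == 0.0
        assert np.nanmax(norm[valid]) == 1.0
        assert ((norm[valid] >= 0) & (norm[valid] <= 1)).all()


class TestEquivariance:
    """Band and data shift together, so the index has clean symmetries."""

    @staticmethod
    def _events_for(series, floor):
        return detect_anomalies_series(
            np.asarray(series, float), np.asarray(floor, float),
            np.array([2000, 2001]), (5, 6, 7, 8, 9),
        )

    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_translation_and_scale_equivariance(self, shift, scale):
        base = np.array([2.0, 1.1, 1.5, 1.9, 2.1, 2.0, 0.9, 1.4, 1.7, 2.2])
        floor = np.full(10, 1.6)
        ref = self._events_for(base, floor)
        shifted = self._events_for(base + shift, floor + shift)
        scaled = self._events_for(base * scale, floor * scale)
        assert len(ref) == len(shifted) == len(scaled) == 2
        for r, s, k in zip(ref, shifted, scaled):
            assert s.ms == pytest.approx(r.ms, rel=1e-9)
            assert s.rt == r.rt
            assert k.ms == pytest.approx(r.ms * scale, rel=1e-9)
            assert k.rt == r.rt

    def test_deeper_anomaly_increases_event_gri(self):
        floor = np.full(5, 1.6)
        gris = []
        for depth in (0.3, 0.5, 0.7):
            (ev,) = detect_anomalies_series(
                np.array([2.0, 1.6 - depth, 1.9, 2.0, 2.0]), floor,
                np.array([2000]), (5, 6, 7, 8, 9))
            gris.append(ev.ms / ev.rt)
        assert gris[0] < gris[1] < gris[2]

    def test_longer_recovery_decreases_event_gri(self):
        floor = np.full(6, 1.6)
        gris = []
        for rt in (1, 2, 3):
            series = np.full(6, 2.0)
            series[1] = 1.1  # trough
            series[2:1 + rt] = 1.5  # still below band
            (ev,) = detect_anomalies_series(series, floor, np.array([2000]),
                                            (4, 5, 6, 7, 8, 9))
            assert ev.rt == rt
            gris.append(ev.ms / ev.rt)
        assert gris[0] > gris[1] > gris[2]

    def test_emitted_invariants(self, scene_noisy):
        from gri_toolkit import compute_gri

        gri_map, events = compute_gri(scene_noisy.stack)
        assert all(e.ms > 0 for e in events)
        assert all(e.rt >= 1 for e in events if e.resolved)
        assert all(e.rt is None for e in events if not e.resolved)
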
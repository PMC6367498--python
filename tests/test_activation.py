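"""Synthetic activation maps: geometry, wavefront fusion, capture,
cohort statistics, generic patterns, dyssynchrony indices and CSV I/O."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crtsim import activation as act
from crtsim.activation import (ActivationMap, GeneratorParams,
                               N_LVFW, N_RVFW, N_SEGMENTS, N_SEPT_LV,
                               N_SEPT_RV, build_geometry,
                               dyssynchrony_indices, generic_pattern,
                               read_map, read_maps, simulate_activation,
                               virtual_cohort, write_maps)


class TestGeometry:
    def test_segment_counts(self, geometry):
        assert N_SEGMENTS == 112
        counts = {w: int(np.sum(geometry.wall == w))
                  for w in np.unique(geometry.wall)}
        assert counts[act.WALL_LVFW] == 52
        assert counts[act.WALL_RVFW] == 50
        assert counts[act.WALL_SEPT_RV] == 7
        assert counts[act.WALL_SEPT_LV] == 3

    def test_pacing_sites_at_zero_distance(self, geometry):
        assert geometry.dist_rv_site[geometry.rv_site_segment] == 0.0
        assert geometry.dist_lv_site[geometry.lv_site_segment] == 0.0
        assert np.sum(geometry.dist_rv_site == 0.0) == 1
        assert np.sum(geometry.dist_lv_site == 0.0) == 1
        assert geometry.wall[geometry.rv_site_segment] == act.WALL_RVFW
        assert geometry.wall[geometry.lv_site_segment] == act.WALL_LVFW

    def test_triangle_inequality_against_inter_site_path(self, geometry):
        # brute force over all segments, using both directions of the
        # (source-dependent) inter-site geodesic
        d = max(geometry.dist_rv_site[geometry.lv_site_segment],
                geometry.dist_lv_site[geometry.rv_site_segment])
        gap = np.abs(geometry.dist_lv_site - geometry.dist_rv_site)
        assert np.all(gap <= d + 1e-9)

    def test_deterministic(self, gen_params, geometry):
        g2 = build_geometry(gen_params)
        np.testing.assert_array_equal(g2.dist_rv_site,
                                      geometry.dist_rv_site)
        np.testing.assert_array_equal(g2.dist_lv_site,
                                      geometry.dist_lv_site)

    def test_all_distances_finite_nonnegative(self, geometry):
        for d in (geometry.dist_rv_site, geometry.dist_lv_site):
            assert np.all(np.isfinite(d))
            assert np.all(d >= 0)


class TestSimulateActivation:
    def test_both_delays_none_is_an_error(self, geometry, gen_params):
        with pytest.raises(ValueError, match="no ventricular pacing"):
            simulate_activation(None, None, geometry, gen_params)

    def test_simultaneous_is_pointwise_min(self, geometry, quiet_params):
        m_lv = simulate_activation(100.0, None, geometry, quiet_params)
        m_rv = simulate_activation(None, 100.0, geometry, quiet_params)
        m = simulate_activation(100.0, 100.0, geometry, quiet_params)
        assert m.captured_lv and m.captured_rv
        np.testing.assert_allclose(
            m.t_act, np.minimum(m_lv.t_act, m_rv.t_act))

    def test_rv_only_depends_on_rv_distances(self, geometry, quiet_params):
        m = simulate_activation(None, 125.0, geometry, quiet_params)
        assert not m.captured_lv and m.captured_rv
        np.testing.assert_allclose(
            m.t_act, 125.0 + geometry.dist_rv_site / quiet_params.v_cond)

    def test_capture_rule_oracle(self, geometry, quiet_params):
        # explicit comparison of stimulus time vs contralateral arrival
        t_cross = geometry.lv_to_rv_site / quiet_params.v_cond
        m = simulate_activation(50.0, 230.0, geometry, quiet_params)
        assert m.captured_rv == (230.0 < 50.0 + t_cross)
        # and just below the threshold capture is retained
        a_rv = 50.0 + t_cross - 1.0
        m2 = simulate_activation(50.0, a_rv, geometry, quiet_params)
        assert m2.captured_rv

    def test_monotone_capture_loss(self, geometry, quiet_params):
        """Past the contralateral arrival time the late ventricle's delay
        no longer matters: the map is the pure single-site map."""
        t_cross = geometry.lv_to_rv_site / quiet_params.v_cond
        pure = simulate_activation(50.0, None, geometry, quiet_params)
        for a_rv in (50.0 + t_cross + 1.0, 50.0 + t_cross + 50.0):
            m = simulate_activation(50.0, a_rv, geometry, quiet_params)
            assert not m.captured_rv
            np.testing.assert_allclose(m.t_act, pure.t_act)

    @given(shift=st.floats(-60.0, 60.0))
    def test_shift_equivariance(self, geometry, quiet_params, shift):
        m1 = simulate_activation(100.0, 140.0, geometry, quiet_params)
        m2 = simulate_activation(100.0 + shift, 140.0 + shift, geometry,
                                 quiet_params)
        np.testing.assert_allclose(m2.t_act - m1.t_act, shift, atol=1e-9)
        i1, i2 = dyssynchrony_indices(m1), dyssynchrony_indices(m2)
        assert i1.lv_tat == pytest.approx(i2.lv_tat, abs=1e-9)
        assert i1.rv_tat == pytest.approx(i2.rv_tat, abs=1e-9)
        assert i1.veu == pytest.approx(i2.veu, abs=1e-9)

    def test_jitter_floored_at_earliest_stimulus(self, geometry,
                                                 gen_params):
        p = dataclasses.replace(gen_params, jitter_sd=15.0)
        rng = np.random.default_rng(7)
        m = simulate_activation(80.0, 120.0, geometry, p, rng=rng)
        assert np.all(m.t_act >= 80.0 - 1e-12)

    def test_jitter_clipped_at_three_sd(self, geometry, gen_params):
        p = dataclasses.replace(gen_params, jitter_sd=2.0)
        clean = simulate_activation(None, 125.0, geometry,
                                    dataclasses.replace(p, jitter_sd=0.0))
        for seed in range(5):
            m = simulate_activation(None, 125.0, geometry, p,
                                    rng=np.random.default_rng(seed))
            assert np.all(np.abs(m.t_act - clean.t_act) <= 6.0 + 1e-12)


class TestVirtualCohort:
    def test_single_quiet_dog_matches_direct_simulation(self, geometry):
        p = GeneratorParams(jitter_sd=0.0, dog_geom_sd=0.0)
        cohort = virtual_cohort([(None, 125.0)], p, n_dogs=1)
        direct = simulate_activation(None, 125.0, geometry, p)
        np.testing.assert_allclose(cohort[(None, 125.0)][0].t_act,
                                   direct.t_act)

    def test_reproducible_for_fixed_seed(self, gen_params):
        settings = [(110.0, 110.0), (None, 125.0)]
        a = virtual_cohort(settings, gen_params)
        b = virtual_cohort(settings, gen_params)
        for s in settings:
            for ma, mb in zip(a[s], b[s]):
                np.testing.assert_array_equal(ma.t_act, mb.t_act)

    def test_across_dog_variability_positive(self, gen_params):
        cohort = virtual_cohort([(None, 125.0)], gen_params, n_dogs=6)
        stack = np.stack([m.t_act for m in cohort[(None, 125.0)]])
        sd = stack.std(axis=0)
        assert np.mean(sd > 0) > 0.9

    def test_invalid_n_dogs(self, gen_params):
        with pytest.raises(ValueError):
            virtual_cohort([(None, 125.0)], gen_params, n_dogs=0)


class TestGenericPattern:
    def _map(self, wall, times, setting=(100.0, 120.0)):
        return ActivationMap(a_lv=setting[0], a_rv=setting[1],
                             t_act=np.asarray(times, float),
                             wall=np.asarray(wall),
                             captured_lv=True, captured_rv=True)

    def test_single_map_gives_per_wall_sorted_times(self):
        wall = [act.WALL_LVFW] * 3 + [act.WALL_RVFW] * 2
        m = self._map(wall, [3.0, 1.0, 2.0, 9.0, 5.0])
        g = generic_pattern([m])
        np.testing.assert_allclose(g.t_act, [1.0, 2.0, 3.0, 5.0, 9.0])

    def test_permutation_invariance_within_wall(self):
        wall = [act.WALL_LVFW] * 3
        g1 = generic_pattern([self._map(wall, [3.0, 1.0, 2.0]),
                              self._map(wall, [1.0, 2.0, 3.0])])
        g2 = generic_pattern([self._map(wall, [2.0, 3.0, 1.0]),
                              self._map(wall, [3.0, 2.0, 1.0])])
        np.testing.assert_allclose(g1.t_act, g2.t_act)
        np.testing.assert_allclose(g1.t_act, [1.0, 2.0, 3.0])

    def test_elementwise_median_by_hand(self):
        wall = [act.WALL_RVFW] * 2
        maps = [self._map(wall, [0.0, 10.0]), self._map(wall, [0.0, 20.0]),
                self._map(wall, [0.0, 30.0])]
        g = generic_pattern(maps)
        np.testing.assert_allclose(g.t_act, [0.0, 20.0])

    def test_idempotent(self, study_maps):
        g = study_maps[(110.0, 110.0)]
        gg = generic_pattern([g])
        np.testing.assert_allclose(np.sort(gg.t_act), np.sort(g.t_act))

    def test_empty_and_mismatched_inputs_raise(self):
        with pytest.raises(ValueError):
            generic_pattern([])
        wall = [act.WALL_LVFW]
        with pytest.raises(ValueError, match="settings"):
            generic_pattern([self._map(wall, [1.0], (100.0, 120.0)),
                             self._map(wall, [1.0], (100.0, 140.0))])


class TestDyssynchronyIndices:
    def test_uniform_map_gives_zero_indices(self, geometry):
        m = ActivationMap(a_lv=100.0, a_rv=100.0,
                          t_act=np.full(N_SEGMENTS, 42.0),
                          wall=geometry.wall.copy(),
                          captured_lv=True, captured_rv=True)
        i = dyssynchrony_indices(m)
        assert i.lv_tat == 0.0 and i.rv_tat == 0.0 and i.veu == 0.0

    def test_lv_tat_includes_septum(self, geometry):
        t = np.zeros(N_SEGMENTS)
        sept = geometry.wall == act.WALL_SEPT_RV
        t[sept] = 50.0
        m = ActivationMap(a_lv=0.0, a_rv=0.0, t_act=t,
                          wall=geometry.wall.copy(),
                          captured_lv=True, captured_rv=True)
        i = dyssynchrony_indices(m)
        assert i.lv_tat == 50.0
        assert i.rv_tat == 0.0

    def test_rv_only_veu_positive(self, study_maps):
        i = dyssynchrony_indices(study_maps[(None, 125.0)])
        assert i.veu >= 20.0

    def test_lv_only_veu_negative(self, study_maps):
        i = dyssynchrony_indices(study_maps[(125.0, None)])
        assert i.veu <= -40.0

    def test_veu_crosses_zero_at_slight_lv_preexcitation(
            self, geometry, quiet_params):
        veu = [dyssynchrony_indices(
            simulate_activation(110.0, 110.0 + vv, geometry,
                                quiet_params)).veu
            for vv in np.arange(0.0, 31.0)]
        assert veu[0] > 0
        assert min(veu) <= 0

    def test_lv_tat_minimal_at_simultaneous_pacing(self, geometry,
                                                   quiet_params):
        lt = {vv: dyssynchrony_indices(
            simulate_activation(110.0, 110.0 + vv, geometry,
                                quiet_params)).lv_tat
            for vv in (-40.0, -20.0, 0.0, 20.0, 40.0)}
        assert lt[0.0] == min(lt.values())


class TestMapCsv:
    def test_round_trip(self, tmp_path, study_maps):
        m = study_maps[(110.0, 150.0)]
        path = tmp_path / "map.csv"
        write_maps(path, m)
        m2 = read_map(path)
        np.testing.assert_allclose(m2.t_act, m.t_act, atol=1e-3)
        assert m2.a_lv == m.a_lv and m2.a_rv == m.a_rv
        assert m2.captured_lv == m.captured_lv
        assert m2.captured_rv == m.captured_rv
        assert np.all(m2.wall == m.wall)

    def test_multiple_maps_in_one_file(self, tmp_path, study_maps):
        maps = [study_maps[(None, 125.0)], study_maps[(110.0, 110.0)]]
        path = tmp_path / "maps.csv"
        write_maps(path, maps)
        back = read_maps(path)
        assert len(back) == 2
        with pytest.raises(ValueError, match="2 maps"):
            read_map(path)

    def test_none_delay_round_trips(self, tmp_path, study_maps):
        path = tmp_path / "rv_only.csv"
        write_maps(path, study_maps[(None, 125.0)])
        m = read_map(path)
        assert m.a_lv is None and m.a_rv == 125.0

    def test_wrong_segment_count_is_descriptive(self, tmp_path,
                                                study_maps):
        import pandas as pd
        path = tmp_path / "bad.csv"
        write_maps(path, study_maps[(None, 125.0)])
        df = pd.read_csv(path).iloc[:-1]
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="112"):
            read_map(path)

    def test_row_order_does_not_change_indices(self, tmp_path, study_maps,
                                               rng):
        import pandas as pd
        m = study_maps[(110.0, 150.0)]
        path = tmp_path / "shuffled.csv"
        write_maps(path, m)
        df = pd.read_csv(path)
        df = df.iloc[rng.permutation(len(df))]
        df.to_csv(path, index=False)
        i1 = dyssynchrony_indices(m)
        i2 = dyssynchrony_indices(read_map(path))
        assert i1.veu == pytest.approx(i2.veu, abs=1e-3)
        assert i1.lv_tat == pytest.approx(i2.lv_tat, abs=1e-3)
        assert i1.rv_tat == pytest.approx(i2.rv_tat, abs=1e-3)
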
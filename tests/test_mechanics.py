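"""Wall mechanics: cap geometry, sarcomere stress, common-tension
multipatch walls, TriSeg coupling, spherical chambers, pericardium."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate
from scipy.optimize import brentq

from crtsim import mechanics as M
from crtsim.config import PericardiumConfig, SarcomereParams
from crtsim import units as U

SARC = SarcomereParams()


class TestCapGeometry:
    def test_unit_hemisphere(self):
        vm, am, cm = M.cap_geometry(1.0, 1.0)
        assert vm == pytest.approx(2 * math.pi / 3)
        assert am == pytest.approx(2 * math.pi)
        assert cm == pytest.approx(1.0)

    def test_flat_wall(self):
        vm, am, cm = M.cap_geometry(0.0, 2.0)
        assert vm == 0.0
        assert am == pytest.approx(math.pi * 4.0)
        assert cm == 0.0

    def test_invalid_junction_radius(self):
        with pytest.raises(ValueError):
            M.cap_geometry(1.0, 0.0)
        with pytest.raises(ValueError):
            M.solve_xm(1.0, -1.0)

    @given(xm=st.floats(-3.0, 3.0), ym=st.floats(0.3, 4.0))
    def test_quadrature_oracle(self, xm, ym):
        """Cap area and volume agree with numeric surface/volume
        integration of the spherical cap."""
        vm, am, cm = M.cap_geometry(xm, ym)
        if abs(xm) < 1e-6:
            assert vm == pytest.approx(0.0, abs=1e-5)
            return
        # sphere of radius R through the ring (radius ym) and pole at xm
        r_sph = (xm * xm + ym * ym) / (2 * abs(xm))
        # integrate cap cross-sections from the ring plane to the pole
        def disc(z):
            return math.pi * (r_sph ** 2 - z ** 2)
        z0 = r_sph - abs(xm)  # ring plane
        v_num, _ = integrate.quad(disc, z0, r_sph)
        a_num = 2 * math.pi * r_sph * abs(xm)  # zone area, exact
        # add the volume of the cone/complement: the closed-form vm is the
        # volume between the cap and the ring plane
        assert abs(vm) == pytest.approx(v_num, rel=1e-6, abs=1e-9)
        assert am == pytest.approx(a_num, rel=1e-6)
        assert cm == pytest.approx(math.copysign(1.0 / r_sph, xm),
                                   rel=1e-9)

    @given(xm=st.floats(-3.0, 3.0), ym=st.floats(0.3, 4.0))
    def test_solve_xm_round_trip(self, xm, ym):
        vm, _, _ = M.cap_geometry(xm, ym)
        assert M.solve_xm(vm, ym) == pytest.approx(xm, abs=1e-9, rel=1e-9)

    def test_solve_xm_special_values(self):
        assert M.solve_xm(0.0, 1.7) == 0.0
        assert M.solve_xm(2 * math.pi / 3, 1.0) == pytest.approx(1.0)


class TestSarcomereStress:
    def test_slack_and_inactive_is_stress_free(self):
        eps = math.log(SARC.ls_pas0 / SARC.ls_ref)
        sig, _ = M.sarcomere_stress(SARC, eps, -5.0)
        assert sig == pytest.approx(0.0, abs=1e-12)

    def test_peak_active_stress_by_construction(self):
        # with the slack length at ls_ref the passive part vanishes and
        # at mid-twitch, reference length, the active part is sigma_max
        s = SarcomereParams(ls_pas0=2.0)
        sig, _ = M.sarcomere_stress(s, 0.0, s.tw_ref / 2)
        assert sig == pytest.approx(s.sigma_act_max, rel=1e-12)

    def test_continuous_at_onset_and_twitch_end(self):
        for tau in (-1e-6, 1e-6):
            sig_a = M.sarcomere_stress(SARC, 0.05, tau)[0]
            sig_b = M.sarcomere_stress(SARC, 0.05, 0.0)[0]
            assert sig_a == pytest.approx(sig_b, abs=1e-4)
        tw = SARC.tw_ref + SARC.k_tw * (SARC.ls_ref * math.exp(0.05)
                                        - SARC.ls_ref)
        for tau in (tw - 1e-6, tw + 1e-6):
            sig_a = M.sarcomere_stress(SARC, 0.05, tau)[0]
            sig_b = M.sarcomere_stress(SARC, 0.05, tw)[0]
            assert sig_a == pytest.approx(sig_b, abs=1e-4)

    @given(eps=st.floats(-0.3, 0.3), tau=st.floats(-50.0, 400.0))
    def test_strain_derivative_matches_finite_difference(self, eps, tau):
        h = 1e-6
        sp, _ = M.sarcomere_stress(SARC, eps + h, tau)
        sm, _ = M.sarcomere_stress(SARC, eps - h, tau)
        sig, dsig = M.sarcomere_stress(SARC, eps, tau)
        fd = (sp - sm) / (2 * h)
        assert dsig == pytest.approx(fd, rel=1e-4, abs=1e-3)

    def test_twitch_collapse_is_an_error(self):
        # extreme shortening with a strong duration-length slope drives
        # tw(ls) through zero
        with pytest.raises(ValueError, match="twitch"):
            M.sarcomere_stress(SARC, -3.0, 10.0)


def _bisect_two_patch_oracle(wall, am_target, t):
    """Independent 1-D force-balance solve for a two-patch wall: find the
    split of am_target for which both patch tensions match."""
    pp = M._pack_wall(wall)
    from crtsim._kernels import sarc_stress
    am_si = am_target * U.CM2_TO_M2

    def tension(i, a):
        eps = 0.5 * math.log(a / pp[i, 1])
        sig, _ = sarc_stress(*pp[i, 3:11],
                             eps, (t - wall.patches[i].t_act) * 1e-3)
        return sig * pp[i, 0] / a

    def gap(a0):
        return tension(0, a0) - tension(1, am_si - a0)

    a0 = brentq(gap, 0.12 * am_si, 0.88 * am_si, xtol=1e-16)
    return a0 * U.M2_TO_CM2, tension(0, a0)


class TestWallCommonTension:
    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_multipatch_collapse(self, n):
        """N identical patches behave exactly like one patch."""
        w1 = M.WallState.uniform("w", 30.0, 100.0, [100.0], SARC)
        wn = M.WallState.uniform("w", 30.0, 100.0, [100.0] * n, SARC)
        tm1, _ = M.wall_common_tension(w1, 88.0, 260.0)
        tmn, _ = M.wall_common_tension(wn, 88.0, 260.0)
        assert tmn == pytest.approx(tm1, rel=1e-8)

    def test_two_patch_solution_matches_bisection_oracle(self):
        wall = M.WallState.uniform("w", 30.0, 100.0, [50.0, 1e9], SARC)
        tm, areas = M.wall_common_tension(wall, 95.0, 200.0)
        a0_ref, tm_ref = _bisect_two_patch_oracle(wall, 95.0, 200.0)
        assert areas[0] == pytest.approx(a0_ref, rel=1e-5)
        assert tm == pytest.approx(tm_ref, rel=1e-5)
        # the activated patch has contracted
        assert areas[0] < areas[1]

    def test_patch_areas_sum_to_target(self):
        t_acts = [0.0, 40.0, 80.0, 120.0, 1e9]
        wall = M.WallState.uniform("w", 40.0, 90.0, t_acts, SARC)
        for am in (70.0, 85.0, 100.0):
            _, areas = M.wall_common_tension(wall, am, 150.0)
            assert areas.sum() == pytest.approx(am, rel=1e-9)

    def test_invalid_target_area(self):
        wall = M.WallState.uniform("w", 30.0, 100.0, [0.0], SARC)
        with pytest.raises(ValueError):
            M.wall_common_tension(wall, -1.0, 0.0)

    def test_patch_state_validation(self):
        with pytest.raises(ValueError):
            M.PatchState(0.0, 0.5, 0.0, SARC)
        with pytest.raises(ValueError, match="shares sum"):
            M.WallState("w", 10.0, 10.0, [
                M.PatchState(0.4, 0.5, 0.0, SARC),
                M.PatchState(0.4, 0.5, 0.0, SARC)])


def _symmetric_walls(t_act=0.0):
    return {
        "LVFW": M.WallState.uniform("LVFW", 60.0, 90.0, [t_act] * 4, SARC),
        "SEPT": M.WallState.uniform("SEPT", 30.0, 45.0, [t_act] * 2, SARC),
        "RVFW": M.WallState.uniform("RVFW", 60.0, 90.0, [t_act] * 4, SARC),
    }


class TestTriSeg:
    def test_mirror_symmetry_through_a_twitch(self):
        """Identical free walls, equal volumes and symmetric activation
        give a flat septum and equal pressures at every time point."""
        warm = None
        for t in (0.0, 80.0, 150.0, 220.0, 300.0):
            ts = M.triseg_pressures(110.0, 110.0, _symmetric_walls(), t,
                                    warm_start=warm)
            warm = ts
            assert abs(ts.vm_s) < 1e-3
            assert abs(ts.xm["SEPT"]) < 1e-3
            assert ts.p_lv_trans == pytest.approx(ts.p_rv_trans, abs=1e-6)

    def test_passive_inflation_is_monotone(self):
        walls = _symmetric_walls(t_act=1e9)
        warm = None
        last = -np.inf
        for v_lv in np.linspace(80.0, 160.0, 9):
            ts = M.triseg_pressures(v_lv, 110.0, walls, 0.0,
                                    warm_start=warm)
            warm = ts
            assert ts.p_lv_trans > last
            last = ts.p_lv_trans

    def test_septal_laplace_consistency(self):
        """The free-wall pressure difference approximately equals the
        septal Laplace pressure (thin-shell diagnostic)."""
        walls = {
            "LVFW": M.WallState.uniform("LVFW", 87.0, 95.0,
                                        [0.0] * 4, SARC),
            "SEPT": M.WallState.uniform("SEPT", 38.0, 48.0,
                                        [0.0] * 2, SARC),
            "RVFW": M.WallState.uniform("RVFW", 30.0, 110.0,
                                        [0.0] * 4, SARC),
        }
        ts = M.triseg_pressures(100.0, 105.0, walls, 90.0)
        dp_sept = 2.0 * ts.tensions["SEPT"] * (
            2 * ts.xm["SEPT"] / (ts.xm["SEPT"] ** 2 + ts.ym ** 2)
        ) * U.M_TO_CM * U.PA_TO_MMHG
        gap = abs((ts.p_lv_trans - ts.p_rv_trans) - dp_sept)
        scale = max(abs(ts.p_lv_trans), abs(ts.p_rv_trans), 1.0)
        assert gap <= 0.05 * scale

    def test_junction_residual_small(self):
        walls = _symmetric_walls()
        ts = M.triseg_pressures(100.0, 120.0, walls, 120.0)
        tmax = max(abs(v) for v in ts.tensions.values())
        assert abs(ts.residual[0]) <= 1e-6 * tmax + 1e-6
        assert abs(ts.residual[1]) <= 1e-6 * tmax + 1e-6

    def test_invalid_volumes(self):
        with pytest.raises(ValueError):
            M.triseg_pressures(-1.0, 100.0, _symmetric_walls(), 0.0)


class TestSpherePressure:
    def test_stress_free_reference(self):
        """A passive wall at its slack area carries no pressure."""
        s = SarcomereParams(ls_pas0=1.9)
        wall = M.WallState.uniform("LA", 8.0, 70.0, [1e9], s)
        am_slack = 70.0 * (s.ls_pas0 / s.ls_ref) ** 2
        r = math.sqrt(am_slack * U.CM2_TO_M2 / (4 * math.pi))
        vmid = 4.0 / 3.0 * math.pi * r ** 3 * U.M3_TO_ML
        p = M.sphere_pressure(vmid - wall.vw / 2, wall, 0.0)
        assert p == pytest.approx(0.0, abs=1e-9)

    def test_pressure_linear_in_wall_volume(self):
        """Doubling wall thickness at fixed midwall geometry and strain
        doubles the Laplace pressure."""
        wall1 = M.WallState.uniform("A", 8.0, 70.0, [1e9], SARC)
        wall2 = M.WallState.uniform("A", 16.0, 70.0, [1e9], SARC)
        vmid = 120.0
        p1 = M.sphere_pressure(vmid - wall1.vw / 2, wall1, 0.0)
        p2 = M.sphere_pressure(vmid - wall2.vw / 2, wall2, 0.0)
        assert p2 == pytest.approx(2.0 * p1, rel=1e-9)

    def test_virtual_work_consistency(self):
        """Over a passive inflation ramp, integral p dV equals the fiber
        strain energy 2 vw integral sigma d(eps)."""
        wall = M.WallState.uniform("A", 10.0, 70.0, [1e9], SARC)
        vols = np.linspace(80.0, 150.0, 141)
        p = np.array([M.sphere_pressure(v, wall, 0.0) for v in vols])
        w_pv = np.trapezoid(p * U.MMHG_TO_PA, vols * U.ML_TO_M3)
        eps = np.empty_like(vols)
        sig = np.empty_like(vols)
        for i, v in enumerate(vols):
            vmid = (v + wall.vw / 2) * U.ML_TO_M3
            r = (3 * vmid / (4 * math.pi)) ** (1 / 3)
            am = 4 * math.pi * r * r
            eps[i] = 0.5 * math.log(am / (wall.am_ref * U.CM2_TO_M2))
            sig[i] = M.sarcomere_stress(SARC, eps[i], -1.0)[0] * 1e3
        w_fiber = 2.0 * wall.vw * U.ML_TO_M3 * np.trapezoid(sig, eps)
        assert w_pv == pytest.approx(w_fiber, rel=1e-3)

    def test_closed_loop_net_work_zero(self):
        """A quasi-static closed volume loop in the passive state does no
        net work (the passive wall is elastic, not viscous)."""
        wall = M.WallState.uniform("A", 10.0, 70.0, [1e9], SARC)
        up = np.linspace(90.0, 140.0, 51)
        loop = np.concatenate([up, up[::-1]])
        p = np.array([M.sphere_pressure(v, wall, 0.0) for v in loop])
        net = np.trapezoid(p, loop)
        assert net == pytest.approx(0.0, abs=1e-9)


class TestPericardium:
    def test_disabled_gives_zero(self):
        cfg = PericardiumConfig(enabled=False)
        assert M.pericardial_pressure(900.0, cfg) == 0.0

    def test_reference_volume_gives_p0(self):
        cfg = PericardiumConfig()
        assert M.pericardial_pressure(cfg.v_ref, cfg) == pytest.approx(
            cfg.p0)

    def test_strictly_increasing(self):
        cfg = PericardiumConfig()
        vols = np.linspace(400.0, 900.0, 20)
        p = [M.pericardial_pressure(v, cfg) for v in vols]
        assert np.all(np.diff(p) > 0)


class TestUnits:
    @given(x=st.floats(1e-3, 1e3))
    def test_resistance_and_compliance_round_trip(self, x):
        assert U.r_to_iface(U.r_to_si(x)) == pytest.approx(x, rel=1e-12)
        assert U.c_to_iface(U.c_to_si(x)) == pytest.approx(x, rel=1e-12)

    def test_pressure_conversion_anchor(self):
        assert 1.0 * U.MMHG_TO_PA == pytest.approx(133.322)
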
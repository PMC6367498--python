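"""Numba kernels: the numerical core of the heart/circulation model.

Everything here works in SI units (Pa, m, m^2, m^3, s, N/m); sarcomere
length in micrometres.  The public modules (:mod:`crtsim.mechanics`,
:mod:`crtsim.circulation`) wrap these kernels and do unit conversion.

Patch parameter matrix ``pp`` has one row per myocardial patch with columns

== ==================================================
0  vw          patch tissue volume (m^3)
1  am_ref      patch reference midwall area (m^2)
2  t_act       activation onset within the cycle (s)
3  sig_act     peak active stress (Pa)
4  ls_ref      reference sarcomere length (um)
5  ls_act0     zero-active-force sarcomere length (um)
6  ls_pas0     passive slack sarcomere length (um)
7  k_pas       passive stiffness scale (Pa)
8  c_pas       passive stiffness exponent (-)
9  tw_ref      twitch duration at ls_ref (s)
10 k_tw        length sensitivity of twitch duration (s/um)
== ==================================================

Wall boundaries are given by an index array ``widx`` such that wall ``w``
owns rows ``widx[w]:widx[w+1]``.  The ventricular TriSeg walls are, in
order, LV free wall, septum, RV free wall; atrial walls (single patch)
follow.

Status codes returned by the solvers:

0 ok, 1 non-positive volume, 2 TriSeg divergence, 3 wall-tension solve
divergence, 4 collapsed twitch duration.
"""

import numpy as np
from numba import njit

PI = np.pi

OK = 0
ERR_NEG_VOLUME = 1
ERR_TRISEG = 2
ERR_WALL = 3
ERR_TWITCH = 4

# record column layout for run_beat (see circulation.BeatRecord)
REC_NCOL = 28


@njit(cache=True)
def _cbrt(x):
    if x >= 0.0:
        return x ** (1.0 / 3.0)
    return -((-x) ** (1.0 / 3.0))


@njit(cache=True)
def cap_geometry(xm, ym):
    """Spherical cap: midwall volume, area, curvature from extent xm and
    junction radius ym (all signed by xm)."""
    h = xm * xm + ym * ym
    vm = (PI / 6.0) * xm * (xm * xm + 3.0 * ym * ym)
    am = PI * h
    cm = 2.0 * xm / h
    return vm, am, cm


@njit(cache=True)
def solve_xm(vm, ym):
    """Unique real root of (pi/6) xm^3 + (pi/2) ym^2 xm - vm = 0.

    Cardano closed form (the depressed cubic x^3 + 3 ym^2 x - 6 vm/pi has
    positive discriminant, hence one real root), polished with two Newton
    steps to round-trip with :func:`cap_geometry` at 1e-9 relative.
    """
    a = 3.0 * vm / PI  # = -q/2 of the depressed cubic
    p3 = ym * ym       # = p/3
    d = np.sqrt(a * a + p3 * p3 * p3)
    if a >= 0.0:
        u = _cbrt(a + d)
    else:
        u = _cbrt(a - d)
    x = u - p3 / u
    # Newton polish on f = (pi/6)x^3 + (pi/2)y^2 x - vm
    for _ in range(2):
        f = (PI / 6.0) * x * x * x + (PI / 2.0) * p3 * x - vm
        fp = (PI / 2.0) * (x * x + p3)
        x -= f / fp
    return x


@njit(cache=True)
def sarc_stress(sig_act, ls_ref, ls_act0, ls_pas0, k_pas, c_pas, tw_ref,
                k_tw, eps, tau):
    """Total fiber Cauchy stress (Pa) and its strain derivative.

    eps is natural fiber strain (ls = ls_ref * exp(eps)); tau is time since
    activation onset (s), negative meaning not yet activated.  The passive
    branch is exponential above the slack length with a slope-matched
    linear continuation below it; the active branch is a length-dependent
    sin^2 twitch.  Returns (nan, nan) if the twitch duration collapses.
    """
    ls = ls_ref * np.exp(eps)
    # passive
    slope0 = k_pas * c_pas / ls_pas0
    if ls > ls_pas0:
        # clamp the exponent so extreme transient strains give huge but
        # finite stresses instead of overflowing to inf
        arg = c_pas * (ls / ls_pas0 - 1.0)
        if arg > 60.0:
            arg = 60.0
        e = np.exp(arg)
        sp = k_pas * (e - 1.0)
        dsp_dls = slope0 * e
    else:
        sp = slope0 * (ls - ls_pas0)
        dsp_dls = slope0
    # active
    tw = tw_ref + k_tw * (ls - ls_ref)
    if tw <= 0.0:
        return np.nan, np.nan
    sa = 0.0
    dsa_dls = 0.0
    fl = (ls - ls_act0) / (ls_ref - ls_act0)
    if fl > 0.0 and 0.0 <= tau <= tw:
        s = np.sin(PI * tau / tw)
        g = s * s
        sa = sig_act * fl * g
        dg_dtw = -np.sin(2.0 * PI * tau / tw) * PI * tau / (tw * tw)
        dsa_dls = sig_act * (g / (ls_ref - ls_act0) + fl * dg_dtw * k_tw)
    sig = sp + sa
    dsig_deps = (dsp_dls + dsa_dls) * ls
    return sig, dsig_deps


@njit(cache=True)
def _tau(t, t_act, cycle):
    """Time since activation, wrapped into [0, cycle) when cycle is finite
    (periodic running); pass cycle = inf for one-shot semantics where a
    negative value means 'not yet activated'."""
    tau = t - t_act
    if np.isfinite(cycle):
        tau -= cycle * np.floor(tau / cycle)
    return tau


@njit(cache=True)
def wall_tension(pp, i0, i1, am_w, t, cycle, areas):
    """Common wall tension of patches pp[i0:i1] at total midwall area am_w.

    All patches share one tension; each patch's midwall area adjusts so
    that its thin-shell tension T_i = sigma_i * vw_i / A_i equals the
    common value while areas sum to am_w.  Solved by iterating the
    linearisation of each patch's tension-area relation about the warm
    areas in ``areas`` (updated in place).  Returns (tm, status).
    """
    n = i1 - i0
    if n == 1:
        eps = 0.5 * np.log(am_w / pp[i0, 1])
        tau = _tau(t, pp[i0, 2], cycle)
        sig, _ = sarc_stress(pp[i0, 3], pp[i0, 4], pp[i0, 5], pp[i0, 6],
                             pp[i0, 7], pp[i0, 8], pp[i0, 9], pp[i0, 10],
                             eps, tau)
        if np.isnan(sig):
            return 0.0, ERR_TWITCH
        areas[i0] = am_w
        return sig * pp[i0, 0] / am_w, OK

    # normalise warm areas to the current target
    s = 0.0
    for i in range(i0, i1):
        s += areas[i]
    if s <= 0.0:
        # cold start: distribute by reference-area share
        s = 0.0
        for i in range(i0, i1):
            areas[i] = pp[i, 1]
            s += areas[i]
    f = am_w / s
    for i in range(i0, i1):
        areas[i] *= f

    ti = np.empty(n)
    ki = np.empty(n)
    tm = 0.0
    relax = 1.0
    prev_spread = np.inf
    for it in range(120):
        sum_inv = 0.0
        sum_tinv = 0.0
        for j in range(n):
            i = i0 + j
            a = areas[i]
            eps = 0.5 * np.log(a / pp[i, 1])
            tau = _tau(t, pp[i, 2], cycle)
            sig, dsig = sarc_stress(pp[i, 3], pp[i, 4], pp[i, 5], pp[i, 6],
                                    pp[i, 7], pp[i, 8], pp[i, 9], pp[i, 10],
                                    eps, tau)
            if np.isnan(sig):
                return 0.0, ERR_TWITCH
            ti[j] = sig * pp[i, 0] / a
            # dT/dA = vw/A^2 * (dsig/deps / 2 - sig); clamp to keep the
            # linearised update well-posed (monotone tension-area relation)
            k = (0.5 * dsig - sig) * pp[i, 0] / (a * a)
            kmin = 1.0e-9 * (abs(ti[j]) + 1.0) / a
            if k < kmin:
                k = kmin
            ki[j] = k
            sum_inv += 1.0 / k
            sum_tinv += ti[j] / k
        tm = sum_tinv / sum_inv  # areas already sum to am_w
        spread = 0.0
        for j in range(n):
            d = abs(ti[j] - tm)
            if d > spread:
                spread = d
        # tight tolerance: the TriSeg Newton differentiates through this
        # solve, so its residual noise must sit well below the finite
        # difference steps taken there
        if spread <= 1.0e-8 * abs(tm) + 1.0e-11:
            return tm, OK
        # adaptive under-relaxation guards against the 2-cycle oscillation
        # the clamped linearised update can fall into on steep curves
        if spread > 0.7 * prev_spread:
            relax = max(0.5 * relax, 0.02)
        else:
            relax = min(1.25 * relax, 1.0)
        prev_spread = spread
        # update areas, clamped, then renormalise to the exact sum
        s = 0.0
        for j in range(n):
            i = i0 + j
            da = relax * (tm - ti[j]) / ki[j]
            lim = 0.25 * areas[i]
            if da > lim:
                da = lim
            elif da < -lim:
                da = -lim
            areas[i] += da
            s += areas[i]
        f = am_w / s
        for i in range(i0, i1):
            areas[i] *= f
    return tm, ERR_WALL


@njit(cache=True)
def triseg_residual(ym, vms, v_lv, v_rv, pp, widx, vw3, t, cycle, areas,
                    out):
    """Junction force residuals (Tx, Ty) of the three-wall assembly.

    out (length 9) receives per-wall xm, am, cm for walls L, S, R followed
    by nothing; tensions are returned via the tuple.  Returns
    (tx, ty, tm_l, tm_s, tm_r, status).
    """
    vm_l = -(v_lv + 0.5 * vw3[0] + 0.5 * vw3[1]) + vms
    vm_r = (v_rv + 0.5 * vw3[2] + 0.5 * vw3[1]) + vms
    tx = 0.0
    ty = 0.0
    tms = np.empty(3)
    vms3 = (vm_l, vms, vm_r)
    for w in range(3):
        xm = solve_xm(vms3[w], ym)
        h = xm * xm + ym * ym
        am = PI * h
        cm = 2.0 * xm / h
        tm, st = wall_tension(pp, widx[w], widx[w + 1], am, t, cycle, areas)
        if st != OK:
            return 0.0, 0.0, 0.0, 0.0, 0.0, st
        tms[w] = tm
        tx += tm * 2.0 * xm * ym / h
        ty += tm * (ym * ym - xm * xm) / h
        out[3 * w] = xm
        out[3 * w + 1] = am
        out[3 * w + 2] = cm
    return tx, ty, tms[0], tms[1], tms[2], OK


@njit(cache=True)
def triseg_solve(v_lv, v_rv, pp, widx, vw3, t, cycle, ts, areas, out):
    """2-D Newton on the TriSeg unknowns (ym, vm_s).

    ts = [ym, vms] is the warm start, updated in place.  out (length 9)
    receives xm/am/cm per wall.  Returns
    (p_lv_trans, p_rv_trans, tm_l, tm_s, tm_r, status), pressures in Pa.
    """
    for attempt in range(3):
        if attempt >= 1:
            # symmetric re-initialisation from the cavity volumes; on the
            # last attempt also cold-start the patch areas
            vtot = v_lv + v_rv + vw3[0] + vw3[1] + vw3[2]
            r = (3.0 * vtot / (4.0 * PI)) ** (1.0 / 3.0)
            ts[0] = 0.9 * r
            ts[1] = 0.1 * v_lv
            if attempt == 2:
                for i in range(widx[0], widx[3]):
                    areas[i] = pp[i, 1]
        ym = ts[0]
        vms = ts[1]
        stalls = 0
        tx, ty, tl, tsp, tr, st = triseg_residual(
            ym, vms, v_lv, v_rv, pp, widx, vw3, t, cycle, areas, out)
        if st != OK and st != ERR_WALL:
            return 0.0, 0.0, 0.0, 0.0, 0.0, st
        ok = st == OK
        for it in range(40):
            if not ok:
                break
            tmax = max(abs(tl), abs(tsp), abs(tr))
            # absolute floor keeps the Newton from wandering along the
            # nearly flat residual valley of a fully slack diastolic heart
            tol = 1.0e-7 * tmax + 1.0e-8
            if abs(tx) <= tol and abs(ty) <= tol:
                ts[0] = ym
                ts[1] = vms
                # refresh geometry/tensions at the accepted point (out may
                # hold a rejected line-search candidate)
                tx, ty, tl, tsp, tr, st = triseg_residual(
                    ym, vms, v_lv, v_rv, pp, widx, vw3, t, cycle, areas,
                    out)
                if st != OK:
                    ok = False
                    continue
                dp_l = 2.0 * tl * out[2]
                dp_r = 2.0 * tr * out[8]
                return -dp_l, dp_r, tl, tsp, tr, OK
            # finite-difference Jacobian; steps large enough that residual
            # changes dominate the inner solves' convergence noise
            dy = 1.0e-4 * ym
            dv = 1.0e-4 * (abs(vms) + 0.1 * ym * ym * ym)
            tx1, ty1, _, _, _, s1 = triseg_residual(
                ym + dy, vms, v_lv, v_rv, pp, widx, vw3, t, cycle, areas, out)
            tx2, ty2, _, _, _, s2 = triseg_residual(
                ym, vms + dv, v_lv, v_rv, pp, widx, vw3, t, cycle, areas, out)
            if s1 != OK or s2 != OK:
                ok = False
                break
            j11 = (tx1 - tx) / dy
            j12 = (tx2 - tx) / dv
            j21 = (ty1 - ty) / dy
            j22 = (ty2 - ty) / dv
            det = j11 * j22 - j12 * j21
            if det == 0.0:
                ok = False
                break
            sy = -(j22 * tx - j12 * ty) / det
            sv = -(-j21 * tx + j11 * ty) / det
            # bound the step: keeps ym positive and prevents runaway along
            # ill-conditioned directions
            lim_y = 0.3 * ym
            lim_v = 0.3 * (abs(vms) + 0.1 * ym * ym * ym)
            f = 1.0
            if abs(sy) > lim_y:
                f = min(f, lim_y / abs(sy))
            if abs(sv) > lim_v:
                f = min(f, lim_v / abs(sv))
            sy *= f
            sv *= f
            # backtracking line search keeping the best candidate seen
            norm0 = np.sqrt(tx * tx + ty * ty)
            lam = 1.0
            best_norm = np.inf
            b_ym = ym
            b_vms = vms
            b_tx = tx
            b_ty = ty
            b_tl = tl
            b_tsp = tsp
            b_tr = tr
            for half in range(8):
                ym_n = ym + lam * sy
                vms_n = vms + lam * sv
                if ym_n > 0.0:
                    txn, tyn, tln, tspn, trn, sn = triseg_residual(
                        ym_n, vms_n, v_lv, v_rv, pp, widx, vw3, t, cycle,
                        areas, out)
                    if sn == OK:
                        normn = np.sqrt(txn * txn + tyn * tyn)
                        if normn < best_norm:
                            best_norm = normn
                            b_ym = ym_n
                            b_vms = vms_n
                            b_tx, b_ty = txn, tyn
                            b_tl, b_tsp, b_tr = tln, tspn, trn
                        if normn < 0.5 * norm0:
                            break
                lam *= 0.5
            if best_norm < norm0:
                ym, vms = b_ym, b_vms
                tx, ty, tl, tsp, tr = b_tx, b_ty, b_tl, b_tsp, b_tr
            elif np.isfinite(best_norm):
                # accept the least-bad candidate once; repeated stalls
                # abort to the next restart
                ym, vms = b_ym, b_vms
                tx, ty, tl, tsp, tr = b_tx, b_ty, b_tl, b_tsp, b_tr
                stalls += 1
                if stalls >= 3:
                    ok = False
            else:
                ok = False
    return 0.0, 0.0, 0.0, 0.0, 0.0, ERR_TRISEG


@njit(cache=True)
def sphere_wall_pressure(v, pp, i0, i1, vw_w, t, cycle, areas):
    """Transmural pressure of a closed thick-shell spherical chamber.

    Midwall sphere encloses the cavity plus half the wall; common wall
    tension at the spherical midwall area; Laplace p = 2 tm / r.
    Returns (p_trans Pa, tm, status)."""
    vmid = v + 0.5 * vw_w
    r = (3.0 * vmid / (4.0 * PI)) ** (1.0 / 3.0)
    am = 4.0 * PI * r * r
    tm, st = wall_tension(pp, i0, i1, am, t, cycle, areas)
    return 2.0 * tm / r, tm, st


@njit(cache=True)
def pericardial_pressure(v_heart, p0, v_ref, stiff, enabled):
    if enabled == 0.0:
        return 0.0
    return p0 * np.exp((v_heart - v_ref) / (stiff * v_ref))


DIODE_KNEE = 66.66  # Pa, ~0.5 mmHg valve-opening regularisation


@njit(cache=True)
def _diode(dp, r):
    """One-way valve flow with a C1-smooth opening knee."""
    if dp <= 0.0:
        return 0.0
    if dp < DIODE_KNEE:
        return dp * dp / (2.0 * DIODE_KNEE * r)
    return (dp - 0.5 * DIODE_KNEE) / r


@njit(cache=True)
def derivatives(y, t, pp, widx, vw3, cp, ts, areas, rec_row):
    """Closed-loop state derivative; fills rec_row[1:] with pressures,
    flows and TriSeg diagnostics.  Returns (dy, status).

    y = [V_la, V_lv, V_ra, V_rv, V_as, V_vs, V_ap, V_vp] (m^3).
    cp layout: see circulation._pack_circ.
    """
    dy = np.zeros(8)
    for i in range(8):
        if y[i] <= 0.0:
            return dy, ERR_NEG_VOLUME
    cycle = cp[0]
    v_heart = y[0] + y[1] + y[2] + y[3] + cp[21]
    p_peri = pericardial_pressure(v_heart, cp[18], cp[19], cp[20], cp[17])

    out = np.empty(9)
    p_lv_t, p_rv_t, tm_l, tm_s, tm_r, st = triseg_solve(
        y[1], y[3], pp, widx, vw3, t, cycle, ts, areas, out)
    if st != OK:
        return dy, st
    p_la_t, _, st = sphere_wall_pressure(
        y[0], pp, widx[3], widx[4], pp[widx[3], 0], t, cycle, areas)
    if st != OK:
        return dy, st
    p_ra_t, _, st = sphere_wall_pressure(
        y[2], pp, widx[4], widx[5], pp[widx[4], 0], t, cycle, areas)
    if st != OK:
        return dy, st

    p_la = p_la_t + p_peri
    p_lv = p_lv_t + p_peri
    p_ra = p_ra_t + p_peri
    p_rv = p_rv_t + p_peri
    p_as = (y[4] - cp[13]) / cp[9]
    p_vs = (y[5] - cp[14]) / cp[10]
    p_ap = (y[6] - cp[15]) / cp[11]
    p_vp = (y[7] - cp[16]) / cp[12]

    # valves: quasi-static diode resistors with a C1 quadratic knee over
    # the first ~0.5 mmHg of forward gradient; the smooth opening keeps
    # d2p/dt2 continuous so beat metrics converge cleanly in dt
    q_mv = _diode(p_la - p_lv, cp[1])
    q_av = _diode(p_lv - p_as, cp[2])
    q_tv = _diode(p_ra - p_rv, cp[3])
    q_pv = _diode(p_rv - p_ap, cp[4])
    # vascular beds (signed)
    q_sys = (p_as - p_vs) / cp[5]
    q_pulm = (p_ap - p_vp) / cp[6]
    q_vs_ra = (p_vs - p_ra) / cp[7]
    q_vp_la = (p_vp - p_la) / cp[8]

    dy[0] = q_vp_la - q_mv
    dy[1] = q_mv - q_av
    dy[2] = q_vs_ra - q_tv
    dy[3] = q_tv - q_pv
    dy[4] = q_av - q_sys
    dy[5] = q_sys - q_vs_ra
    dy[6] = q_pv - q_pulm
    dy[7] = q_pulm - q_vp_la

    rec_row[9] = p_la
    rec_row[10] = p_lv
    rec_row[11] = p_ra
    rec_row[12] = p_rv
    rec_row[13] = p_as
    rec_row[14] = p_vs
    rec_row[15] = p_ap
    rec_row[16] = p_vp
    rec_row[17] = p_peri
    rec_row[18] = q_mv
    rec_row[19] = q_av
    rec_row[20] = q_sys
    rec_row[21] = q_vs_ra
    rec_row[22] = q_tv
    rec_row[23] = q_pv
    rec_row[24] = q_pulm
    rec_row[25] = q_vp_la
    rec_row[26] = ts[0]
    rec_row[27] = ts[1]
    return dy, OK


@njit(cache=True)
def run_beat(y, pp, widx, vw3, cp, ts, areas, dt, nstep, rec):
    """Fixed-step RK4 over one cardiac cycle.

    y (length 8) is advanced in place; rec must be (nstep+1, REC_NCOL) and
    receives time, volumes, pressures, flows and TriSeg diagnostics at
    every step.  Returns (status, i_fail)."""
    scratch = np.empty(REC_NCOL)
    for i in range(nstep + 1):
        t = i * dt
        k1, st = derivatives(y, t, pp, widx, vw3, cp, ts, areas, rec[i])
        if st != OK:
            return st, i
        rec[i, 0] = t
        for j in range(8):
            rec[i, 1 + j] = y[j]
        if i == nstep:
            break
        k2, st = derivatives(y + 0.5 * dt * k1, t + 0.5 * dt, pp, widx, vw3,
                             cp, ts, areas, scratch)
        if st != OK:
            return st, i
        k3, st = derivatives(y + 0.5 * dt * k2, t + 0.5 * dt, pp, widx, vw3,
                             cp, ts, areas, scratch)
        if st != OK:
            return st, i
        k4, st = derivatives(y + dt * k3, t + dt, pp, widx, vw3,
                             cp, ts, areas, scratch)
        if st != OK:
            return st, i
        for j in range(8):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
    return OK, nstep
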
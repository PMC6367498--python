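"""Myocardial wall mechanics: sarcomere stress, common-tension multipatch
walls, spherical-cap geometry, TriSeg three-wall ventricular coupling,
spherical atria and the pericardial constraint.

The model chain is stress -> tension -> Laplace pressure:

* each patch carries a phenomenological fiber stress, the sum of a
  length-dependent sin^2 active twitch and an exponential passive branch;
* all patches of a wall share one tension ``Tm = sigma * (Vw/Am)`` (thin
  shell), so a wall's tension at a prescribed total midwall area follows
  from a small nonlinear solve over the patch areas;
* the three ventricular walls meet in a junction ring; force balance on
  the ring (TriSeg) fixes the septal geometry and yields both transmural
  pressures;
* atria are single-patch spheres; the pericardium adds a common external
  pressure that grows exponentially with total heart volume.

Interface units: mmHg, mL, cm^2, 1/cm, N/m, ms, kPa; natural fiber strain
is dimensionless.  The heavy lifting happens in :mod:`crtsim._kernels`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .config import PericardiumConfig, SarcomereParams
from .units import (CM2_TO_M2, CM_TO_M, KPA_TO_PA, M2_TO_CM2, M3_TO_ML,
                    M_TO_CM, ML_TO_M3, MMHG_TO_PA, MS_TO_S, PA_TO_MMHG)

__all__ = [
    "PatchState", "WallState", "TriSegState", "cap_geometry", "solve_xm",
    "sarcomere_stress", "wall_common_tension", "triseg_pressures",
    "sphere_pressure", "pericardial_pressure", "SarcomereParams",
]


@dataclass
class PatchState:
    """One myocardial segment of a wall.

    Shares are fractions of the wall's tissue volume and reference midwall
    area; ``t_act`` is the activation onset in ms after the atrial pace.
    ``eps_f`` / ``sigma_f`` / ``am`` hold the patch's current natural fiber
    strain, fiber stress (kPa) and midwall area (cm^2) after a solve.
    """

    wall_volume_share: float
    am_ref_share: float
    t_act: float
    sarc: SarcomereParams
    eps_f: float = 0.0
    sigma_f: float = 0.0
    am: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.wall_volume_share <= 1.0:
            raise ValueError("wall_volume_share must be in (0, 1]")
        if not 0.0 < self.am_ref_share <= 1.0:
            raise ValueError("am_ref_share must be in (0, 1]")


@dataclass
class WallState:
    """A wall: tissue volume vw (mL), reference midwall area am_ref (cm^2)
    and its patches.  tm/am/cm hold the current tension (N/m), midwall
    area (cm^2) and curvature (1/cm) after a solve."""

    name: str
    vw: float
    am_ref: float
    patches: list[PatchState]
    tm: float | None = None
    am: float | None = None
    cm: float | None = None

    def __post_init__(self) -> None:
        if self.vw <= 0 or self.am_ref <= 0:
            raise ValueError(f"wall {self.name}: vw and am_ref must be > 0")
        for tot in (sum(p.wall_volume_share for p in self.patches),
                    sum(p.am_ref_share for p in self.patches)):
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"wall {self.name}: patch shares sum to {tot}, not 1")

    @classmethod
    def uniform(cls, name: str, vw: float, am_ref: float,
                t_acts, sarc: SarcomereParams) -> "WallState":
        """Wall of identical patches with the given activation onsets."""
        n = len(t_acts)
        patches = [PatchState(1.0 / n, 1.0 / n, float(t), sarc)
                   for t in t_acts]
        return cls(name, vw, am_ref, patches)


@dataclass
class TriSegState:
    """Septal geometry unknowns and derived wall quantities."""

    ym: float                       # junction ring radius (cm)
    vm_s: float                     # signed septal cap volume (mL)
    xm: dict = field(default_factory=dict)        # per-wall extent (cm)
    tensions: dict = field(default_factory=dict)  # per-wall Tm (N/m)
    p_lv_trans: float = 0.0         # mmHg
    p_rv_trans: float = 0.0         # mmHg
    residual: tuple = (0.0, 0.0)    # junction force residual (N/m)


def cap_geometry(xm: float, ym: float):
    """Solid geometry of a spherical cap spanning a ring of radius ym.

    Returns (midwall cap volume mL, midwall area cm^2, curvature 1/cm),
    all signed by the cap extent xm (cm).
    """
    if ym <= 0:
        raise ValueError("junction radius ym must be positive")
    h = xm * xm + ym * ym
    vm = (math.pi / 6.0) * xm * (xm * xm + 3.0 * ym * ym)
    am = math.pi * h
    cm = 2.0 * xm / h
    return vm, am, cm


def solve_xm(vm: float, ym: float) -> float:
    """Invert cap_geometry's volume: the unique real root of
    (pi/6) xm^3 + (pi/2) ym^2 xm - vm = 0 (cm)."""
    if ym <= 0:
        raise ValueError("junction radius ym must be positive")
    return float(K.solve_xm(float(vm), float(ym)))


def _sarc_si(sarc: SarcomereParams):
    return (sarc.sigma_act_max * KPA_TO_PA, sarc.ls_ref, sarc.ls_act0,
            sarc.ls_pas0, sarc.k_pas * KPA_TO_PA, sarc.c_pas,
            sarc.tw_ref * MS_TO_S, sarc.k_tw * MS_TO_S)


def sarcomere_stress(sarc: SarcomereParams, eps_f: float,
                     t_since_act: float):
    """Fiber stress (kPa) and strain derivative (kPa) at natural strain
    eps_f and time since activation onset t_since_act (ms; negative means
    not yet activated)."""
    sig, dsig = K.sarc_stress(*_sarc_si(sarc), float(eps_f),
                              float(t_since_act) * MS_TO_S)
    if math.isnan(sig):
        raise ValueError("twitch duration collapsed (tw(ls) <= 0)")
    return sig / KPA_TO_PA, dsig / KPA_TO_PA


def _pack_wall(wall: WallState) -> np.ndarray:
    pp = np.empty((len(wall.patches), 11))
    for i, p in enumerate(wall.patches):
        s = _sarc_si(p.sarc)
        pp[i, 0] = wall.vw * p.wall_volume_share * ML_TO_M3
        pp[i, 1] = wall.am_ref * p.am_ref_share * CM2_TO_M2
        pp[i, 2] = p.t_act * MS_TO_S
        pp[i, 3:11] = s
    return pp


def _warm_areas(wall: WallState, pp: np.ndarray) -> np.ndarray:
    areas = np.empty(len(wall.patches))
    for i, p in enumerate(wall.patches):
        areas[i] = p.am * CM2_TO_M2 if p.am is not None else pp[i, 1]
    return areas


def _store_wall(wall: WallState, pp, areas, tm, am, cm, t_ms) -> None:
    wall.tm = float(tm)
    wall.am = am
    wall.cm = cm
    for i, p in enumerate(wall.patches):
        a = areas[i]
        p.am = a * M2_TO_CM2
        p.eps_f = 0.5 * math.log(a / pp[i, 1])
        sig, _ = K.sarc_stress(*pp[i, 3:11], p.eps_f,
                               (t_ms - p.t_act) * MS_TO_S)
        p.sigma_f = sig / KPA_TO_PA


def wall_common_tension(wall: WallState, am_target: float, t: float):
    """Common tension of a wall constrained to total midwall area
    am_target (cm^2) at time t (ms after the atrial pace).

    Updates the wall state in place (tension, patch areas, strains,
    stresses) and returns (tm N/m, patch areas cm^2).
    """
    if am_target <= 0:
        raise ValueError("am_target must be positive")
    pp = _pack_wall(wall)
    areas = _warm_areas(wall, pp)
    tm, st = K.wall_tension(pp, 0, len(wall.patches),
                            am_target * CM2_TO_M2, t * MS_TO_S, np.inf,
                            areas)
    if st == K.ERR_TWITCH:
        raise ValueError("twitch duration collapsed (tw(ls) <= 0)")
    if st != K.OK:
        spread = _tension_spread(pp, areas, tm, t)
        raise RuntimeError(
            f"wall_common_tension did not converge for wall {wall.name}: "
            f"tension spread {spread:.3e} N/m at tm={tm:.3e} N/m")
    _store_wall(wall, pp, areas, tm, am_target, None, t)
    return float(tm), areas * M2_TO_CM2


def _tension_spread(pp, areas, tm, t_ms):
    spread = 0.0
    for i in range(pp.shape[0]):
        eps = 0.5 * math.log(areas[i] / pp[i, 1])
        sig, _ = K.sarc_stress(*pp[i, 3:11], eps,
                               (t_ms * MS_TO_S - pp[i, 2]))
        spread = max(spread, abs(sig * pp[i, 0] / areas[i] - tm))
    return spread


_TRISEG_ORDER = ("LVFW", "SEPT", "RVFW")


def triseg_pressures(v_lv: float, v_rv: float, walls: dict, t: float,
                     warm_start: TriSegState | None = None) -> TriSegState:
    """Solve the three-wall junction balance at cavity volumes v_lv, v_rv
    (mL) and time t (ms); returns the TriSeg state with both transmural
    pressures (mmHg).  ``walls`` maps LVFW/SEPT/RVFW to WallState (updated
    in place)."""
    if v_lv <= 0 or v_rv <= 0:
        raise ValueError("cavity volumes must be positive")
    wl = [walls[k] for k in _TRISEG_ORDER]
    pps = [_pack_wall(w) for w in wl]
    pp = np.vstack(pps)
    widx = np.array([0, len(wl[0].patches),
                     len(wl[0].patches) + len(wl[1].patches),
                     pp.shape[0]], dtype=np.int64)
    vw3 = np.array([w.vw * ML_TO_M3 for w in wl])
    areas = np.concatenate([_warm_areas(w, p) for w, p in zip(wl, pps)])
    if warm_start is not None:
        ts = np.array([warm_start.ym * CM_TO_M, warm_start.vm_s * ML_TO_M3])
    else:
        vtot = (v_lv + v_rv) * ML_TO_M3 + vw3.sum()
        r = (3.0 * vtot / (4.0 * math.pi)) ** (1.0 / 3.0)
        ts = np.array([0.9 * r, 0.1 * v_lv * ML_TO_M3])
    out = np.empty(9)
    p_lv, p_rv, tl, tsp, tr, st = K.triseg_solve(
        v_lv * ML_TO_M3, v_rv * ML_TO_M3, pp, widx, vw3, t * MS_TO_S,
        np.inf, ts, areas, out)
    if st != K.OK:
        raise RuntimeError(
            "TriSeg solve failed: "
            f"v_lv={v_lv:.2f} mL, v_rv={v_rv:.2f} mL, t={t:.1f} ms, "
            f"ym={ts[0] * M_TO_CM:.3f} cm, vm_s={ts[1] * M3_TO_ML:.3f} mL")
    state = TriSegState(ym=ts[0] * M_TO_CM, vm_s=ts[1] * M3_TO_ML)
    tms = (tl, tsp, tr)
    for w, wall, tm in zip(range(3), wl, tms):
        xm, am, cm = out[3 * w], out[3 * w + 1], out[3 * w + 2]
        state.xm[wall.name] = xm * M_TO_CM
        state.tensions[wall.name] = tm
        _store_wall(wall, pps[w], areas[widx[w]:widx[w + 1]], tm,
                    am * M2_TO_CM2, cm * CM_TO_M, t)
    state.p_lv_trans = p_lv * PA_TO_MMHG
    state.p_rv_trans = p_rv * PA_TO_MMHG
    # residual diagnostic at the solution
    tx, ty, *_ = K.triseg_residual(ts[0], ts[1], v_lv * ML_TO_M3,
                                   v_rv * ML_TO_M3, pp, widx, vw3,
                                   t * MS_TO_S, np.inf, areas, out)
    state.residual = (tx, ty)
    return state


def sphere_pressure(v: float, wall: WallState, t: float) -> float:
    """Transmural pressure (mmHg) of a closed spherical chamber of cavity
    volume v (mL) bounded by the given wall at time t (ms)."""
    if v <= 0:
        raise ValueError("cavity volume must be positive")
    vmid = (v + 0.5 * wall.vw) * ML_TO_M3
    r = (3.0 * vmid / (4.0 * math.pi)) ** (1.0 / 3.0)
    am = 4.0 * math.pi * r * r
    tm, _ = wall_common_tension(wall, am * M2_TO_CM2, t)
    wall.cm = (1.0 / r) * CM_TO_M
    return 2.0 * tm / r * PA_TO_MMHG


def pericardial_pressure(v_total_heart: float,
                         params: PericardiumConfig) -> float:
    """Pericardial pressure (mmHg) at total heart volume (chambers plus
    wall tissue, mL)."""
    if v_total_heart <= 0:
        raise ValueError("total heart volume must be positive")
    if not params.enabled:
        return 0.0
    return params.p0 * math.exp(
        (v_total_heart - params.v_ref) / (params.stiffness * params.v_ref))
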
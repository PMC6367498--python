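"""Closed-loop hemodynamics: four chambers, four diode valves, systemic
and pulmonary windkessels, fixed-step RK4 beat integration, beat
segmentation and summary metrics.

Compartment order everywhere: LA, LV, RA, RV, systemic arteries, systemic
veins, pulmonary arteries, pulmonary veins.  Atria activate at t = 0 of
every cycle; ventricular patch onsets come from the imposed activation
map (ms after the atrial pace), wrapped modulo the cycle.  Valves are
quasi-static diode resistors: flow Δp/R when Δp > 0, else zero — no
inertance, no regurgitation.

Interface units: mmHg, mL, mL/s, ms; the integration itself runs in SI
inside :mod:`crtsim._kernels`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels as K
from .config import (PericardiumConfig, VascularConfig, WallConfig,
                     default_walls)
from .units import (CM_TO_M, M3_TO_ML, M_TO_CM, ML_TO_M3, MMHG_TO_PA,
                    MS_TO_S, PA_TO_MMHG, c_to_si, r_to_si)
from .mechanics import _sarc_si

__all__ = [
    "CircConfig", "CircState", "BeatRecord", "BeatSummary",
    "initial_state", "derivatives", "run_beat", "run_to_steady",
    "dpdt_max", "beat_summary", "COMPARTMENTS",
    "config_to_dict", "config_from_dict", "save_config", "load_config",
]

COMPARTMENTS = ("la", "lv", "ra", "rv", "art_sys", "ven_sys",
                "art_pulm", "ven_pulm")

# order of the mechanical walls in the packed patch matrix
_WALL_ORDER = ("LVFW", "SEPT", "RVFW", "LA", "RA")


@dataclass
class CircConfig:
    """Full simulation configuration.

    t_act_ventricles holds one activation onset (ms after the atrial
    pace) per ventricular patch, in wall order LVFW, SEPT, RVFW; atria
    activate at t_act_atria (default 0) each cycle.
    """

    hr: float = 70.0                     # bpm
    dt: float = 1.0                      # ms
    walls: dict = field(default_factory=default_walls)
    vasc: VascularConfig = field(default_factory=VascularConfig)
    pericardium: PericardiumConfig = field(
        default_factory=PericardiumConfig)
    t_act_ventricles: np.ndarray | None = None
    t_act_atria: float = 0.0

    def __post_init__(self) -> None:
        if self.hr <= 0 or self.dt <= 0:
            raise ValueError("hr and dt must be positive")
        n_vent = sum(self.walls[w].n_patches for w in
                     ("LVFW", "SEPT", "RVFW"))
        if self.t_act_ventricles is None:
            # synchronous reference activation
            self.t_act_ventricles = np.zeros(n_vent)
        self.t_act_ventricles = np.asarray(self.t_act_ventricles, float)
        if len(self.t_act_ventricles) != n_vent:
            raise ValueError(
                f"t_act_ventricles has {len(self.t_act_ventricles)} "
                f"entries, walls define {n_vent} ventricular patches")
        tw_max = max(w.sarc.tw_ref for w in self.walls.values())
        if self.cycle < self.t_act_ventricles.max() + tw_max:
            warnings.warn(
                "cycle shorter than latest activation plus twitch "
                "duration; twitches wrap into the next beat",
                stacklevel=2)

    @property
    def cycle(self) -> float:
        """Cycle length (ms)."""
        return 60000.0 / self.hr

    def with_activation(self, t_act) -> "CircConfig":
        return replace(self, t_act_ventricles=np.asarray(t_act, float))


def config_to_dict(config: CircConfig) -> dict:
    """Plain-dict (YAML/JSON-serialisable) form of a CircConfig."""
    import dataclasses as _dc
    return {
        "hr": config.hr, "dt": config.dt,
        "walls": {k: _dc.asdict(w) for k, w in config.walls.items()},
        "vasculature": _dc.asdict(config.vasc),
        "pericardium": _dc.asdict(config.pericardium),
        "t_act_atria": config.t_act_atria,
        "t_act_ventricles": [float(x) for x in config.t_act_ventricles],
    }


def config_from_dict(d: dict) -> CircConfig:
    from .config import (PericardiumConfig as _Peri,
                         VascularConfig as _Vasc, walls_from_dict)
    return CircConfig(
        hr=d["hr"], dt=d["dt"], walls=walls_from_dict(d["walls"]),
        vasc=_Vasc(**d["vasculature"]),
        pericardium=_Peri(**d["pericardium"]),
        t_act_atria=d.get("t_act_atria", 0.0),
        t_act_ventricles=np.asarray(d["t_act_ventricles"], float))


def save_config(path, config: CircConfig) -> None:
    from .config import save_yaml
    save_yaml(path, config_to_dict(config))


def load_config(path) -> CircConfig:
    from .config import load_yaml
    return config_from_dict(load_yaml(path))


class _Packed:
    """Kernel-ready parameter arrays for one CircConfig."""

    def __init__(self, cfg: CircConfig):
        n = sum(cfg.walls[w].n_patches for w in _WALL_ORDER)
        pp = np.empty((n, 11))
        widx = np.empty(len(_WALL_ORDER) + 1, np.int64)
        widx[0] = 0
        i = 0
        t_vent = cfg.t_act_ventricles
        k = 0
        for wi, wname in enumerate(_WALL_ORDER):
            w: WallConfig = cfg.walls[wname]
            s = _sarc_si(w.sarc)
            for j in range(w.n_patches):
                pp[i, 0] = w.vw / w.n_patches * ML_TO_M3
                pp[i, 1] = w.am_ref / w.n_patches * 1.0e-4
                if wname in ("LVFW", "SEPT", "RVFW"):
                    pp[i, 2] = t_vent[k] * MS_TO_S
                    k += 1
                else:
                    pp[i, 2] = cfg.t_act_atria * MS_TO_S
                pp[i, 3:11] = s
                i += 1
            widx[wi + 1] = i
        self.pp = pp
        self.widx = widx
        self.vw3 = np.array([cfg.walls[w].vw * ML_TO_M3
                             for w in ("LVFW", "SEPT", "RVFW")])
        v = cfg.vasc
        peri = cfg.pericardium
        vw_total = sum(w.vw for w in cfg.walls.values()) * ML_TO_M3
        self.cp = np.array([
            cfg.cycle * MS_TO_S,
            r_to_si(v.r_mitral), r_to_si(v.r_aortic),
            r_to_si(v.r_tricuspid), r_to_si(v.r_pulm_valve),
            r_to_si(v.r_sys), r_to_si(v.r_pulm),
            r_to_si(v.r_ven_sys), r_to_si(v.r_ven_pulm),
            c_to_si(v.c_art_sys), c_to_si(v.c_ven_sys),
            c_to_si(v.c_art_pulm), c_to_si(v.c_ven_pulm),
            v.v_unstr_art_sys * ML_TO_M3, v.v_unstr_ven_sys * ML_TO_M3,
            v.v_unstr_art_pulm * ML_TO_M3, v.v_unstr_ven_pulm * ML_TO_M3,
            1.0 if peri.enabled else 0.0, peri.p0 * MMHG_TO_PA,
            peri.v_ref * ML_TO_M3, peri.stiffness,
            vw_total,
        ])
        self.nstep = int(round(cfg.cycle / cfg.dt))
        self.dt_s = cfg.cycle * MS_TO_S / self.nstep


@dataclass
class CircState:
    """ODE state: compartment volumes (mL, order COMPARTMENTS) plus the
    TriSeg and patch-area warm starts carried between solves."""

    volumes: np.ndarray
    triseg: np.ndarray          # [ym, vm_s] in SI, kernel warm start
    areas: np.ndarray           # patch midwall areas (m^2), warm start

    @property
    def ym(self) -> float:
        """TriSeg junction radius (cm)."""
        return float(self.triseg[0]) * M_TO_CM

    @property
    def vm_s(self) -> float:
        """Septal cap volume (mL)."""
        return float(self.triseg[1]) * M3_TO_ML

    def copy(self) -> "CircState":
        return CircState(self.volumes.copy(), self.triseg.copy(),
                         self.areas.copy())

    def total_volume(self) -> float:
        return float(self.volumes.sum())


def initial_state(config: CircConfig) -> CircState:
    """A physiologically plausible cold-start state holding exactly the
    configured blood volume; the surplus over nominal chamber and
    arterial filling sits in the systemic veins."""
    v = config.vasc
    vols = np.empty(8)
    vols[0], vols[1], vols[2], vols[3] = 60.0, 120.0, 60.0, 120.0
    vols[4] = v.v_unstr_art_sys + v.c_art_sys * 80.0
    vols[6] = v.v_unstr_art_pulm + v.c_art_pulm * 15.0
    vols[7] = v.v_unstr_ven_pulm + v.c_ven_pulm * 8.0
    vols[5] = v.blood_volume - (vols[0] + vols[1] + vols[2] + vols[3]
                                + vols[4] + vols[6] + vols[7])
    if vols[5] <= 0:
        raise ValueError("blood volume too small for the nominal filling")
    vtot = (vols[1] + vols[3]) * ML_TO_M3 + sum(
        config.walls[w].vw for w in ("LVFW", "SEPT", "RVFW")) * ML_TO_M3
    r = (3.0 * vtot / (4.0 * np.pi)) ** (1.0 / 3.0)
    n = sum(config.walls[w].n_patches for w in _WALL_ORDER)
    return CircState(volumes=vols,
                     triseg=np.array([0.9 * r, 0.1 * vols[1] * ML_TO_M3]),
                     areas=np.zeros(n))


class BeatRecord:
    """Uniform-dt traces of one cycle: volumes, pressures, valve and bed
    flows, TriSeg diagnostics."""

    _P_COLS = ("p_la", "p_lv", "p_ra", "p_rv", "p_art_sys", "p_ven_sys",
               "p_art_pulm", "p_ven_pulm")
    _Q_COLS = ("q_mitral", "q_aortic", "q_sys", "q_ven_sys", "q_tricuspid",
               "q_pulm_valve", "q_pulm", "q_ven_pulm")

    def __init__(self, rec: np.ndarray, dt_ms: float, hr: float):
        self._rec = rec
        self.dt = dt_ms
        self.hr = hr

    @property
    def t(self) -> np.ndarray:
        """Time within the cycle (ms)."""
        return self._rec[:, 0] / MS_TO_S

    def volume(self, comp: str) -> np.ndarray:
        return self._rec[:, 1 + COMPARTMENTS.index(comp)] * M3_TO_ML

    def pressure(self, comp: str) -> np.ndarray:
        return self._rec[:, 9 + COMPARTMENTS.index(comp)] * PA_TO_MMHG

    @property
    def p_peri(self) -> np.ndarray:
        return self._rec[:, 17] * PA_TO_MMHG

    def flow(self, name: str) -> np.ndarray:
        """Flow trace (mL/s) by name, e.g. 'q_mitral', 'q_sys'."""
        return self._rec[:, 18 + self._Q_COLS.index(name)] * M3_TO_ML

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.t})
        for c in COMPARTMENTS:
            df[f"v_{c}"] = self.volume(c)
        for c in COMPARTMENTS:
            df[f"p_{c}"] = self.pressure(c)
        df["p_peri"] = self.p_peri
        for q in self._Q_COLS:
            df[q] = self.flow(q)
        df["triseg_ym_cm"] = self._rec[:, 26] * M_TO_CM
        df["triseg_vm_s_ml"] = self._rec[:, 27] * M3_TO_ML
        return df


@dataclass
class BeatSummary:
    """Per-beat hemodynamic summary."""

    lv_dpdt_max: float  # mmHg/s
    rv_dpdt_max: float  # mmHg/s
    sv_lv: float        # mL
    sv_rv: float        # mL
    edv_lv: float       # mL
    edv_rv: float       # mL
    esv_lv: float       # mL
    esv_rv: float       # mL
    map_art: float      # mmHg
    co: float           # L/min


def _raise_status(status: int, state: CircState, t_s: float) -> None:
    if status == K.OK:
        return
    t_ms = t_s / MS_TO_S
    if status == K.ERR_NEG_VOLUME:
        i = int(np.argmin(state.volumes))
        raise RuntimeError(
            f"volume of compartment {COMPARTMENTS[i]} non-positive near "
            f"t={t_ms:.1f} ms (V={state.volumes[i]:.3f} mL)")
    if status == K.ERR_TRISEG:
        raise RuntimeError(f"TriSeg solve diverged near t={t_ms:.1f} ms")
    if status == K.ERR_WALL:
        raise RuntimeError(
            f"wall tension solve diverged near t={t_ms:.1f} ms")
    if status == K.ERR_TWITCH:
        raise ValueError("twitch duration collapsed (tw(ls) <= 0)")
    raise RuntimeError(f"integration failed with status {status}")


def derivatives(state: CircState, t: float, config: CircConfig,
                _packed: _Packed | None = None):
    """Time derivatives of all compartment volumes at time t (ms within
    the cycle).

    Returns (dvdt mL/s array in COMPARTMENTS order, pressures dict mmHg,
    flows dict mL/s).  The eight derivatives sum to zero identically
    (closed loop)."""
    p = _packed or _Packed(config)
    row = np.empty(K.REC_NCOL)
    y = state.volumes * ML_TO_M3
    dy, st = K.derivatives(y, t * MS_TO_S, p.pp, p.widx, p.vw3, p.cp,
                           state.triseg, state.areas, row)
    _raise_status(st, state, t * MS_TO_S)
    pressures = {c: row[9 + i] * PA_TO_MMHG
                 for i, c in enumerate(COMPARTMENTS)}
    pressures["pericardium"] = row[17] * PA_TO_MMHG
    flows = {q: row[18 + i] * M3_TO_ML
             for i, q in enumerate(BeatRecord._Q_COLS)}
    return dy * M3_TO_ML, pressures, flows


def run_beat(state: CircState, config: CircConfig,
             _packed: _Packed | None = None):
    """Integrate one cardiac cycle with fixed-step RK4.

    Returns (state at end of beat, BeatRecord).  On a TriSeg divergence
    the beat is retried once from its starting state at half the step."""
    p = _packed or _Packed(config)
    for attempt in range(2):
        nstep = p.nstep * (attempt + 1)
        dt_s = p.dt_s / (attempt + 1)
        trial = state.copy()
        y = trial.volumes * ML_TO_M3
        rec = np.empty((nstep + 1, K.REC_NCOL))
        st, i_fail = K.run_beat(y, p.pp, p.widx, p.vw3, p.cp, trial.triseg,
                                trial.areas, dt_s, nstep, rec)
        trial.volumes = y * M3_TO_ML
        if st == K.OK:
            return trial, BeatRecord(rec, dt_s / MS_TO_S, config.hr)
        if st not in (K.ERR_TRISEG, K.ERR_WALL):
            _raise_status(st, trial, i_fail * dt_s)
    _raise_status(st, trial, i_fail * dt_s)


def dpdt_max(pressure: np.ndarray, dt: float) -> float:
    """Maximum rate of pressure rise (mmHg/s) of a uniformly sampled
    pressure trace (mmHg at spacing dt ms).

    Centred finite differences, with the discrete maximum refined by the
    vertex of a parabola through its three neighbouring samples so the
    estimate is robust to where the samples fall on the peak."""
    pressure = np.asarray(pressure, float)
    if pressure.size < 3:
        raise ValueError("pressure trace needs at least 3 samples")
    # fixed ~3 ms half-window: the estimate reflects the trace, not the
    # sampling step (cf. the finite bandwidth of catheter dP/dt), so beat
    # metrics converge cleanly when dt is refined
    k = max(1, int(round(3.0 / dt)))
    if 2 * k >= pressure.size:
        k = 1
    d = (pressure[2 * k:] - pressure[:-2 * k]) / (2.0 * k * dt * MS_TO_S)
    i = int(np.argmax(d))
    if 0 < i < d.size - 1:
        a, b, c = d[i - 1], d[i], d[i + 1]
        denom = a - 2.0 * b + c
        if denom < 0.0:
            return float(b - (c - a) ** 2 / (8.0 * denom))
    return float(d[i])


def beat_summary(record: BeatRecord) -> BeatSummary:
    """EDV/ESV as the extrema of the ventricular volume traces over the
    cycle; MAP as the time average of systemic arterial pressure; CO from
    LV stroke volume and heart rate."""
    v_lv = record.volume("lv")
    v_rv = record.volume("rv")
    edv_lv, esv_lv = float(v_lv.max()), float(v_lv.min())
    edv_rv, esv_rv = float(v_rv.max()), float(v_rv.min())
    sv_lv = edv_lv - esv_lv
    sv_rv = edv_rv - esv_rv
    return BeatSummary(
        lv_dpdt_max=dpdt_max(record.pressure("lv"), record.dt),
        rv_dpdt_max=dpdt_max(record.pressure("rv"), record.dt),
        sv_lv=sv_lv, sv_rv=sv_rv,
        edv_lv=edv_lv, edv_rv=edv_rv, esv_lv=esv_lv, esv_rv=esv_rv,
        map_art=float(record.pressure("art_sys")[:-1].mean()),
        co=sv_lv * record.hr / 1000.0)


def run_to_steady(state: CircState, config: CircConfig, tol: float = 0.001,
                  max_beats: int = 50, _packed: _Packed | None = None,
                  keep_records: bool = False):
    """Iterate beats until both ventricles' stroke volumes change by less
    than tol (relative) between consecutive beats.

    Returns (steady state, [BeatSummary per beat]) — the whole transient —
    and, with keep_records, the matching BeatRecords as a third element.
    Raises if max_beats is exceeded.
    """
    p = _packed or _Packed(config)
    summaries = []
    records = []
    prev = None
    for _ in range(max_beats):
        state, rec = run_beat(state, config, _packed=p)
        s = beat_summary(rec)
        summaries.append(s)
        if keep_records:
            records.append(rec)
        if prev is not None:
            d_lv = abs(s.sv_lv - prev.sv_lv) / max(prev.sv_lv, 1e-9)
            d_rv = abs(s.sv_rv - prev.sv_rv) / max(prev.sv_rv, 1e-9)
            if d_lv < tol and d_rv < tol:
                if keep_records:
                    return state, summaries, records
                return state, summaries
        prev = s
    trace = ", ".join(f"{s.sv_lv:.2f}/{s.sv_rv:.2f}" for s in summaries[-5:])
    raise RuntimeError(
        f"no hemodynamic steady state within {max_beats} beats "
        f"(last SV_lv/SV_rv: {trace})")
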
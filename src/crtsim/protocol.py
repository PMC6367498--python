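"""The pacing-delay optimization protocol.

Reproduces the study pipeline end to end:

1. impose the baseline activation pattern (RV-only pacing, A-RV 125 ms)
   and tune systemic resistance and circulating blood volume until the
   baseline hemodynamics match the experiment (MAP 60 mmHg, CO 5.1 L/min
   at HR 80);
2. calibrate LV- and RV-side contractility so baseline dP/dt_max matches
   the measured medians;
3. sweep all 100 (A-LV, A-RV) combinations of the 50..230 ms / 20 ms
   lattice from the same converged baseline with the vasculature frozen,
   recording the first beat after the activation switch, the beat-to-beat
   transient, and the new steady state;
4. express responses as relative changes versus baseline and lay them out
   as delay-grid heat maps.

The "AV delay" of a setting is the delay of the first-paced ventricle,
min(A-LV, A-RV); the VV delay is A-RV − A-LV (positive = LV
pre-excitation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from . import __version__
from .activation import (ActivationMap, DyssynchronyIndices,
                         GeneratorParams, dyssynchrony_indices,
                         generic_maps)
from .circulation import (BeatSummary, CircConfig, CircState, _Packed,
                          initial_state, run_to_steady)
from .config import (CANINE_LV_DPDT_TARGET, CANINE_RV_DPDT_TARGET,
                     TuneTargets, canine_targets, human_targets)

__all__ = [
    "GRID_DELAYS", "PacingSetting", "BASELINE_SETTING", "build_grid",
    "activation_times_for_patches", "tune_vasculature",
    "calibrate_contractility", "baseline_canine", "reference_human",
    "SettingResult", "ProtocolResult", "run_setting", "run_grid",
    "heatmap_matrix", "report",
]

GRID_DELAYS = tuple(float(d) for d in range(50, 231, 20))


@dataclass(frozen=True)
class PacingSetting:
    """One (A-LV, A-RV) delay pair in ms; None = that ventricle unpaced."""

    a_lv: float | None
    a_rv: float | None

    @property
    def av_delay(self) -> float:
        """Delay of the first-paced ventricle (ms)."""
        return min(d for d in (self.a_lv, self.a_rv) if d is not None)

    @property
    def vv_delay(self) -> float | None:
        """A-RV − A-LV (ms, positive = LV pre-excitation); None for
        single-ventricle pacing."""
        if self.a_lv is None or self.a_rv is None:
            return None
        return self.a_rv - self.a_lv

    def key(self) -> tuple:
        return (self.a_lv, self.a_rv)

    def label(self) -> str:
        f = lambda d: "none" if d is None else f"{d:g}"  # noqa: E731
        return f"{f(self.a_lv)}_{f(self.a_rv)}"


BASELINE_SETTING = PacingSetting(a_lv=None, a_rv=125.0)


def build_grid() -> list[PacingSetting]:
    """All 100 delay combinations, A-LV-major order."""
    return [PacingSetting(a_lv, a_rv)
            for a_lv in GRID_DELAYS for a_rv in GRID_DELAYS]


def activation_times_for_patches(amap: ActivationMap) -> np.ndarray:
    """Ventricular patch onsets (ms) in mechanical wall order LVFW, SEPT,
    RVFW from an activation map (whose segment order is LVFW, septum RV
    side, septum LV side, RVFW — already aligned)."""
    return np.asarray(amap.t_act, float).copy()


# ---------------------------------------------------------------------------
# tuning and calibration


def _steady(config: CircConfig, state: CircState | None, max_beats=50):
    if state is None:
        state = initial_state(config)
    packed = _Packed(config)
    state, summaries = run_to_steady(state, config, _packed=packed,
                                     max_beats=max_beats)
    return state, summaries[-1]


def tune_vasculature(config: CircConfig, targets: TuneTargets,
                     state: CircState | None = None,
                     max_iter: int = 30):
    """Fix systemic resistance and circulating blood volume so the steady
    state hits the target MAP and CO.

    Alternates a multiplicative update of r_sys against MAP with a secant
    update of blood volume against CO, re-running to steady state after
    each change (volume changes are applied to the systemic veins).
    Returns (tuned config, steady state, history) where history is a list
    of dicts (one per outer iteration).
    """
    config = dataclasses.replace(config, hr=targets.hr)
    state, s = _steady(config, state)
    history = []
    prev_bv_co = None
    for it in range(max_iter):
        history.append({"iter": it, "r_sys": config.vasc.r_sys,
                        "blood_volume": config.vasc.blood_volume,
                        "map": s.map_art, "co": s.co})
        err_map = s.map_art / targets.map_target - 1.0
        err_co = s.co / targets.co_target - 1.0
        if abs(err_map) < targets.tolerance and \
                abs(err_co) < targets.tolerance:
            return config, state, history
        # resistance against MAP; subtract the estimated venous pressure so
        # the update stays effective when it is a large share of MAP
        q_sys = s.co * 1000.0 / 60.0  # mL/s
        p_vs = max(s.map_art - q_sys * config.vasc.r_sys, 0.0)
        ratio = (targets.map_target - p_vs) / max(s.map_art - p_vs, 1e-6)
        ratio = min(max(ratio, 0.3), 3.0)
        r_new = config.vasc.r_sys * ratio ** 0.9
        # blood volume against CO: secant once two points exist
        bv = config.vasc.blood_volume
        if prev_bv_co is not None and abs(s.co - prev_bv_co[1]) > 1e-6:
            slope = (bv - prev_bv_co[0]) / (s.co - prev_bv_co[1])
            slope = min(max(slope, 30.0), 600.0)  # mL per L/min, guarded
        else:
            slope = 150.0
        dbv = (targets.co_target - s.co) * slope
        # moderate volume steps: a large instantaneous withdrawal can
        # transiently deflate the heart into a non-physiological state
        dbv = min(max(dbv, -250.0), 250.0)
        prev_bv_co = (bv, s.co)
        vasc = dataclasses.replace(config.vasc, r_sys=r_new,
                                   blood_volume=bv + dbv)
        config = dataclasses.replace(config, vasc=vasc)
        state = state.copy()
        state.volumes[5] += dbv  # systemic veins absorb the change
        if state.volumes[5] <= 0:
            raise RuntimeError("blood-volume update emptied the veins")
        state, s = _steady(config, state)
    raise RuntimeError(
        "tune_vasculature did not converge; trajectory: "
        + json.dumps(history, default=float))


def _scale_sigma(config: CircConfig, wall_names, factor: float
                 ) -> CircConfig:
    walls = dict(config.walls)
    for name in wall_names:
        w = walls[name]
        sarc = dataclasses.replace(
            w.sarc, sigma_act_max=w.sarc.sigma_act_max * factor)
        walls[name] = dataclasses.replace(w, sarc=sarc)
    return dataclasses.replace(config, walls=walls)


def calibrate_contractility(config: CircConfig,
                            lv_dpdt_target: float = CANINE_LV_DPDT_TARGET,
                            rv_dpdt_target: float = CANINE_RV_DPDT_TARGET,
                            targets: TuneTargets | None = None,
                            state: CircState | None = None,
                            tol: float = 0.10, max_iter: int = 12):
    """Scale LV-side (LV free wall + septum) and RV-side (RV free wall)
    peak active stress until the tuned baseline's dP/dt_max values match
    the experimental medians, re-tuning the vasculature after each scale
    change.  Returns (config, state, steady BeatSummary)."""
    targets = targets or canine_targets()
    for it in range(max_iter):
        config, state, _ = tune_vasculature(config, targets, state=state)
        _, s = _steady(config, state)
        err_lv = s.lv_dpdt_max / lv_dpdt_target - 1.0
        err_rv = s.rv_dpdt_max / rv_dpdt_target - 1.0
        if abs(err_lv) < tol and abs(err_rv) < tol:
            return config, state, s
        f_lv = (lv_dpdt_target / s.lv_dpdt_max) ** 0.8
        f_rv = (rv_dpdt_target / s.rv_dpdt_max) ** 0.8
        config = _scale_sigma(config, ("LVFW", "SEPT"), f_lv)
        config = _scale_sigma(config, ("RVFW",), f_rv)
    raise RuntimeError(
        f"calibrate_contractility did not converge: LV dP/dt "
        f"{s.lv_dpdt_max:.0f} vs {lv_dpdt_target:.0f}, RV "
        f"{s.rv_dpdt_max:.0f} vs {rv_dpdt_target:.0f}")


def baseline_canine(gen_params: GeneratorParams | None = None,
                    config: CircConfig | None = None,
                    maps: dict | None = None,
                    calibrate: bool = True):
    """Build the calibrated canine baseline simulation.

    Generates (or is given) the generic activation maps, imposes the
    baseline RV-only A-RV 125 ms pattern, tunes the vasculature to
    MAP 60 mmHg / CO 5.1 L/min at HR 80 and, unless disabled, calibrates
    contractility to the measured baseline dP/dt_max medians.

    Returns (config, state, steady BeatSummary, maps).
    """
    gen_params = gen_params or GeneratorParams()
    if maps is None:
        settings = [BASELINE_SETTING.key()] + [s.key() for s in build_grid()]
        maps = generic_maps(settings, gen_params)
    config = config or CircConfig()
    config = config.with_activation(
        activation_times_for_patches(maps[BASELINE_SETTING.key()]))
    targets = canine_targets()
    if calibrate:
        config, state, s = calibrate_contractility(config, targets=targets)
    else:
        config, state, _ = tune_vasculature(config, targets)
        _, s = _steady(config, state)
    return config, state, s, maps


def reference_human(config: CircConfig | None = None):
    """The healthy human reference: synchronous activation, HR 70, tuned
    to MAP 92 mmHg / CO 5.1 L/min.  Returns (config, state, summary)."""
    config = config or CircConfig()
    n_vent = sum(config.walls[w].n_patches for w in ("LVFW", "SEPT",
                                                     "RVFW"))
    config = config.with_activation(np.zeros(n_vent))
    config, state, _ = tune_vasculature(config, human_targets())
    _, s = _steady(config, state)
    return config, state, s


# ---------------------------------------------------------------------------
# the sweep

_METRICS = ("lv_dpdt_max", "rv_dpdt_max", "sv_lv", "sv_rv", "edv_lv",
            "edv_rv", "map_art", "co")


@dataclass
class SettingResult:
    """One pacing setting's outcome: first-beat and steady-state
    summaries, the per-beat transient, and relative changes (%) versus
    the baseline steady state."""

    setting: PacingSetting
    indices: DyssynchronyIndices
    captured_lv: bool
    captured_rv: bool
    first_beat: BeatSummary
    steady: BeatSummary
    n_beats: int
    transient: list
    rel_steady: dict = field(default_factory=dict)
    rel_first: dict = field(default_factory=dict)


def _rel(x: float, base: float) -> float:
    return 100.0 * (x - base) / base


def run_setting(baseline_state: CircState, setting: PacingSetting,
                config: CircConfig, maps: dict,
                baseline_summary: BeatSummary,
                tol: float = 0.001, max_beats: int = 50) -> SettingResult:
    """Switch the ventricular activation to the setting's generic map at
    the next beat boundary and run to steady state with the vasculature
    frozen.  Beat 1 is the first complete cycle using the new map."""
    amap = maps[setting.key()]
    cfg = config.with_activation(activation_times_for_patches(amap))
    state = baseline_state.copy()
    state, summaries = run_to_steady(state, cfg, tol=tol,
                                     max_beats=max_beats,
                                     _packed=_Packed(cfg))
    first, steady = summaries[0], summaries[-1]
    res = SettingResult(
        setting=setting, indices=dyssynchrony_indices(amap),
        captured_lv=amap.captured_lv, captured_rv=amap.captured_rv,
        first_beat=first, steady=steady, n_beats=len(summaries),
        transient=summaries)
    for m in _METRICS:
        base = getattr(baseline_summary, m)
        res.rel_steady[m] = _rel(getattr(steady, m), base)
        res.rel_first[m] = _rel(getattr(first, m), base)
    return res


@dataclass
class ProtocolResult:
    """The full sweep: one row per setting plus per-setting transients."""

    table: pd.DataFrame
    transients: dict
    baseline: BeatSummary
    failures: dict = field(default_factory=dict)


def _result_row(r: SettingResult) -> dict:
    s = r.setting
    row = {"a_lv": s.a_lv, "a_rv": s.a_rv, "av_delay": s.av_delay,
           "vv_delay": s.vv_delay, "captured_lv": r.captured_lv,
           "captured_rv": r.captured_rv, "lv_tat": r.indices.lv_tat,
           "rv_tat": r.indices.rv_tat, "veu": r.indices.veu,
           "n_beats": r.n_beats}
    for m in _METRICS:
        row[f"fb_{m}"] = getattr(r.first_beat, m)
        row[f"ss_{m}"] = getattr(r.steady, m)
        row[f"rel_{m}"] = r.rel_steady[m]
        row[f"relfb_{m}"] = r.rel_first[m]
    return row


def run_grid(config: CircConfig, maps: dict, baseline_state: CircState,
             baseline_summary: BeatSummary,
             settings: list | None = None, progress: bool = False
             ) -> ProtocolResult:
    """Run every pacing setting independently from the same converged
    baseline state.  Per-setting failures are recorded and the sweep
    continues."""
    settings = settings if settings is not None else build_grid()
    if progress:
        from tqdm import tqdm
        settings = tqdm(list(settings), desc="sweep")
    rows, transients, failures = [], {}, {}
    for setting in settings:
        try:
            r = run_setting(baseline_state, setting, config, maps,
                            baseline_summary)
        except Exception as exc:  # noqa: BLE001 - per-setting isolation
            failures[setting.key()] = str(exc)
            continue
        rows.append(_result_row(r))
        transients[setting.key()] = pd.DataFrame(
            [dataclasses.asdict(b) for b in r.transient])
    table = pd.DataFrame(rows)
    return ProtocolResult(table=table, transients=transients,
                          baseline=baseline_summary, failures=failures)


def heatmap_matrix(result: ProtocolResult, metric: str,
                   interpolate: bool = False, factor: int = 4
                   ) -> pd.DataFrame:
    """Delay-grid heat map of one result column: rows A-RV, columns A-LV.

    With interpolate=True the 10x10 lattice is bilinearly upsampled
    (factor points per lattice interval); lattice-node values pass
    through unchanged."""
    if metric not in result.table.columns:
        numeric = [c for c in result.table.columns
                   if result.table[c].dtype.kind == "f"]
        raise KeyError(f"unknown metric {metric!r}; available: {numeric}")
    sub = result.table.dropna(subset=["a_lv", "a_rv"])
    mat = sub.pivot(index="a_rv", columns="a_lv", values=metric)
    mat = mat.sort_index().sort_index(axis=1)
    if not interpolate:
        return mat
    rv, lv = mat.index.to_numpy(float), mat.columns.to_numpy(float)
    interp = RegularGridInterpolator((rv, lv), mat.to_numpy())
    rv_f = np.linspace(rv[0], rv[-1], (len(rv) - 1) * factor + 1)
    lv_f = np.linspace(lv[0], lv[-1], (len(lv) - 1) * factor + 1)
    grid = np.meshgrid(rv_f, lv_f, indexing="ij")
    vals = interp(np.stack([g.ravel() for g in grid], axis=-1))
    return pd.DataFrame(vals.reshape(len(rv_f), len(lv_f)),
                        index=rv_f, columns=lv_f)


def _config_fingerprint(config: CircConfig) -> str:
    d = {"hr": config.hr, "dt": config.dt,
         "walls": {k: dataclasses.asdict(w)
                   for k, w in sorted(config.walls.items())},
         "vasc": dataclasses.asdict(config.vasc),
         "pericardium": dataclasses.asdict(config.pericardium),
         "t_act_atria": config.t_act_atria,
         "t_act_ventricles": np.round(config.t_act_ventricles, 9).tolist()}
    return hashlib.sha256(
        json.dumps(d, sort_keys=True).encode()).hexdigest()


def report(result: ProtocolResult, outdir, config: CircConfig | None = None,
           seed: int | None = None,
           heatmap_metrics=("rel_lv_dpdt_max", "rel_rv_dpdt_max",
                            "rel_co")) -> list:
    """Write results.csv, per-setting transient tables, heat-map CSVs and
    a run manifest under outdir.  Returns the written paths."""
    outdir = Path(outdir)
    (outdir / "transients").mkdir(parents=True, exist_ok=True)
    paths = []
    p = outdir / "results.csv"
    result.table.to_csv(p, index=False)
    paths.append(p)
    for key, tr in result.transients.items():
        setting = PacingSetting(*key)
        p = outdir / "transients" / f"{setting.label()}.csv"
        tr.to_csv(p, index=False)
        paths.append(p)
    for metric in heatmap_metrics:
        if metric in result.table.columns:
            p = outdir / f"heatmap_{metric}.csv"
            heatmap_matrix(result, metric).to_csv(p)
            paths.append(p)
    manifest = {
        "package": "crtsim", "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": seed, "n_settings": int(len(result.table)),
        "failures": {PacingSetting(*k).label(): v
                     for k, v in result.failures.items()},
        "config_hash": _config_fingerprint(config) if config else None,
    }
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    paths.append(p)
    return paths
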
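"""Default parameterization and YAML config handling.

One heart parameter set — a human-sized reference heart — serves both
study profiles: the *canine* profile (the experiment's hemodynamic state:
HR 80 bpm, MAP 60 mmHg, CO 5.1 L/min, imposed dyssynchronous activation)
and the *human reference* profile (HR 70 bpm, MAP 92 mmHg, CO 5.1 L/min,
synchronous activation).  The profiles differ only in heart rate, tuning
targets and imposed activation; systemic resistance and circulating blood
volume are free parameters fixed by the vascular tuning procedure
(:func:`crtsim.protocol.tune_vasculature`).

All values here are in interface units (mmHg, mL, cm^2, ms, kPa, um).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class SarcomereParams:
    """Phenomenological sarcomere model parameters.

    sigma_act_max : peak active stress (kPa)
    ls_ref        : reference sarcomere length (um); strain zero point
    ls_act0       : sarcomere length of zero active force (um)
    ls_pas0       : passive slack length (um)
    k_pas, c_pas  : passive stress scale (kPa) and exponent (-)
    tw_ref        : twitch duration at ls_ref (ms)
    k_tw          : twitch-duration length sensitivity (ms/um)
    """

    sigma_act_max: float = 60.0
    ls_ref: float = 2.0
    ls_act0: float = 1.58
    ls_pas0: float = 1.8
    k_pas: float = 1.5
    c_pas: float = 12.0
    tw_ref: float = 180.0
    k_tw: float = 120.0

    def __post_init__(self) -> None:
        for name in ("sigma_act_max", "ls_ref", "ls_act0", "ls_pas0",
                     "k_pas", "c_pas", "tw_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SarcomereParams.{name} must be positive")
        if self.ls_act0 >= self.ls_ref:
            raise ValueError("ls_act0 must be below ls_ref")


@dataclass
class WallConfig:
    """One cardiac wall: tissue volume (mL), reference midwall area (cm^2),
    patch count and sarcomere parameters shared by its patches."""

    name: str
    vw: float
    am_ref: float
    n_patches: int
    sarc: SarcomereParams = field(default_factory=SarcomereParams)

    def __post_init__(self) -> None:
        if self.vw <= 0 or self.am_ref <= 0 or self.n_patches < 1:
            raise ValueError(f"invalid wall geometry for {self.name}")


@dataclass
class PericardiumConfig:
    """Exponential pericardial constraint p = p0 exp((V-Vref)/(s Vref))."""

    enabled: bool = True
    p0: float = 0.4        # mmHg at the reference heart volume
    v_ref: float = 650.0   # mL, chambers plus wall tissue
    stiffness: float = 0.12


@dataclass
class VascularConfig:
    """Windkessel circulation: one arterial and one venous compartment per
    side, diode valves, resistances in mmHg*s/mL, compliances in mL/mmHg,
    volumes in mL."""

    r_sys: float = 1.10
    r_pulm: float = 0.09
    r_ven_sys: float = 0.060
    r_ven_pulm: float = 0.060
    r_mitral: float = 0.003
    r_aortic: float = 0.004
    r_tricuspid: float = 0.003
    r_pulm_valve: float = 0.004
    c_art_sys: float = 2.4
    c_ven_sys: float = 25.0
    c_art_pulm: float = 6.0
    c_ven_pulm: float = 5.0
    v_unstr_art_sys: float = 450.0
    v_unstr_ven_sys: float = 2800.0
    v_unstr_art_pulm: float = 120.0
    v_unstr_ven_pulm: float = 300.0
    blood_volume: float = 4900.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"VascularConfig.{f.name} must be positive")


def default_ventricular_sarc() -> SarcomereParams:
    return SarcomereParams()


def default_atrial_sarc() -> SarcomereParams:
    # atria: weaker, brisker twitch
    return SarcomereParams(sigma_act_max=30.0, tw_ref=120.0, k_tw=30.0,
                           ls_act0=1.51)


def default_walls() -> dict:
    """The five-wall heart: TriSeg ventricular walls plus spherical atria.

    The septum is one mechanical wall of 10 patches (7 mapped on its RV
    side, 3 on its LV side); the atria are single-patch spheres."""
    vs = default_ventricular_sarc()
    return {
        "LVFW": WallConfig("LVFW", vw=87.0, am_ref=95.0, n_patches=52,
                           sarc=dataclasses.replace(vs)),
        "SEPT": WallConfig("SEPT", vw=38.0, am_ref=48.0, n_patches=10,
                           sarc=dataclasses.replace(vs)),
        "RVFW": WallConfig("RVFW", vw=30.0, am_ref=110.0, n_patches=50,
                           sarc=dataclasses.replace(vs)),
        "LA": WallConfig("LA", vw=8.0, am_ref=70.0, n_patches=1,
                         sarc=default_atrial_sarc()),
        "RA": WallConfig("RA", vw=6.0, am_ref=70.0, n_patches=1,
                         sarc=default_atrial_sarc()),
    }


@dataclass
class TuneTargets:
    """Hemodynamic targets for the vascular tuning loop."""

    map_target: float  # mmHg
    co_target: float   # L/min
    hr: float          # bpm
    tolerance: float = 0.01

    def __post_init__(self) -> None:
        if min(self.map_target, self.co_target, self.hr,
               self.tolerance) <= 0:
            raise ValueError("TuneTargets fields must be positive")


def canine_targets() -> TuneTargets:
    """The experiment's baseline hemodynamic state."""
    return TuneTargets(map_target=60.0, co_target=5.1, hr=80.0)


def human_targets() -> TuneTargets:
    """Healthy resting human reference."""
    return TuneTargets(map_target=92.0, co_target=5.1, hr=70.0)


# contractility calibration anchors (baseline measurement medians, mmHg/s)
CANINE_LV_DPDT_TARGET = 1205.0
CANINE_RV_DPDT_TARGET = 520.0


# ---------------------------------------------------------------------------
# YAML round trip


def to_dict(obj) -> dict:
    return dataclasses.asdict(obj)


def walls_from_dict(d: dict) -> dict:
    out = {}
    for name, w in d.items():
        sarc = SarcomereParams(**w["sarc"])
        out[name] = WallConfig(w["name"], w["vw"], w["am_ref"],
                               w["n_patches"], sarc)
    return out


def save_yaml(path, d: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
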
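#!/usr/bin/env python
"""Tune the two reference hemodynamic states.

Canine baseline: the RV-only A-RV 125 ms generic map is imposed at HR 80
and systemic resistance / circulating blood volume are adjusted until
MAP = 60 mmHg and CO = 5.1 L/min (the experiment's anesthetized state).

Human reference: the same heart with synchronous activation at HR 70,
tuned to MAP 92 mmHg / CO 5.1 L/min.

Writes the tuned (not yet contractility-calibrated) canine configuration
to results/tuned_canine.yaml and a summary table to
results/baseline_tuning.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import dataclasses

import pandas as pd

from crtsim.activation import GeneratorParams, generic_maps
from crtsim.circulation import CircConfig, save_config
from crtsim.config import canine_targets
from crtsim.protocol import (BASELINE_SETTING, _steady,
                             activation_times_for_patches,
                             reference_human, tune_vasculature)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gen = GeneratorParams()
    maps = generic_maps([BASELINE_SETTING.key()], gen)
    amap = maps[BASELINE_SETTING.key()]

    print("tuning the canine baseline (MAP 60 mmHg, CO 5.1 L/min, "
          "HR 80) ...")
    cfg = CircConfig().with_activation(activation_times_for_patches(amap))
    cfg, state, history = tune_vasculature(cfg, canine_targets())
    _, s = _steady(cfg, state)
    print(f"  converged in {len(history)} outer iterations: "
          f"MAP {s.map_art:.2f} mmHg, CO {s.co:.3f} L/min")
    print(f"  r_sys {cfg.vasc.r_sys:.3f} mmHg*s/mL, blood volume "
          f"{cfg.vasc.blood_volume:.0f} mL")
    print(f"  EDV {s.edv_lv:.0f}/{s.edv_rv:.0f} mL, ESV "
          f"{s.esv_lv:.0f}/{s.esv_rv:.0f} mL (LV/RV), LV dP/dt "
          f"{s.lv_dpdt_max:.0f} mmHg/s (pre-calibration)")
    save_config(OUT / "tuned_canine.yaml", cfg)

    print("tuning the human reference (MAP 92 mmHg, CO 5.1 L/min, "
          "HR 70) ...")
    cfg_h, _, s_h = reference_human()
    print(f"  MAP {s_h.map_art:.2f} mmHg, CO {s_h.co:.3f} L/min, "
          f"LV dP/dt {s_h.lv_dpdt_max:.0f} mmHg/s")
    save_config(OUT / "tuned_human.yaml", cfg_h)

    rows = [dict(profile="canine", **dataclasses.asdict(s)),
            dict(profile="human", **dataclasses.asdict(s_h))]
    pd.DataFrame(rows).to_csv(OUT / "baseline_tuning.csv", index=False)
    print(f"wrote {OUT / 'tuned_canine.yaml'}, tuned_human.yaml, "
          "baseline_tuning.csv")


if __name__ == "__main__":
    main()
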
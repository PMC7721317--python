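#!/usr/bin/env python
"""Calibration of the default C3 vacuolar storage capacity.

The capacity (mol solutes per m2 leaf carried across a step boundary) is not
directly measurable here; it is calibrated so that the CAM-anatomy variant
(3.1x the C3 capacity) reproduces two anchors under the reference
environment:

  * carboxylic-acid pools stored overnight at 80% productivity on the order
    of 10^2 mmol m-2, the range reported for CAM leaves;
  * more than half of the daily water saved at 80% of maximum phloem output.

Run `python scripts/calibrate_vacuole.py` to print the scan; the chosen
default (0.1 mol m-2 for C3) is recorded in DielConstraintSet and the config.
"""

from __future__ import annotations

import numpy as np

from dielfba import (DielConstraintSet, apply_vacuole_capacity,
                     build_toy_core, couple_water_loss, expand_diel,
                     make_profile, maximize_phloem, minimize_water)


def main() -> None:
    net = build_toy_core()
    env = make_profile()
    cs = DielConstraintSet()
    base = expand_diel(net, env, cs)
    couple_water_loss(base)

    print(f"{'C3 cap':>8} {'CAM cap':>8} {'save80_CAM%':>12} {'save80_C3%':>11} "
          f"{'acid peak mmol':>15}")
    for c3_cap in (0.05, 0.075, 0.1, 0.125, 0.15):
        row = {}
        for label, cap in (("C3", c3_cap), ("CAM", 3.1 * c3_cap)):
            model = base.copy()
            apply_vacuole_capacity(model, cap)
            p_max = maximize_phloem(model, flux_min=False).phloem_output
            w100 = minimize_water(model, p_max, flux_min=False).water_total
            sol80 = minimize_water(model, 0.8 * p_max, flux_min=False)
            row[label] = 100.0 * (1.0 - sol80.water_total / w100)
            if label == "CAM":
                acids = sol80.linkers.loc[["MAL_v", "CIT_v", "ICIT_v"]]
                row["acid_peak"] = float(
                    (acids.to_numpy().sum(axis=0) * env.step_seconds * 1e-3).max())
        print(f"{c3_cap:>8.3f} {3.1 * c3_cap:>8.3f} {row['CAM']:>12.1f} "
              f"{row['C3']:>11.1f} {row['acid_peak']:>15.0f}")

    print("\nchosen default: C3 capacity 0.1 mol m-2 (CAM 0.31): the smallest "
          "scanned value at which the CAM leaf saves >50% of its water at 80% "
          "productivity, with overnight acid pools (~150 mmol m-2) inside the "
          "range reported for CAM leaves.")


if __name__ == "__main__":
    main()
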
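"""Depth dose in water for the three surrogate beam energies.

Calibrates each beam model, computes the dose of an 8 x 8 cm^2 open field
on a tall water phantom, and prints central-axis depth-dose landmarks.
The depth of maximum dose (d_max) grows with beam energy and the
percentage depth dose at 10 cm tracks beam penetration — the classic
commissioning sanity check for a photon dose engine.
"""

import numpy as np

import ccdose as cc
import ccdose.fixtures as fx


def main() -> None:
    grid = fx._make_grid(
        np.array([120.0, 120.0, 250.0]), np.array([5.0, 5.0, 2.5]), (0.0, 0.0, -125.0)
    )
    grid.values[:] = 1.0
    phantom = cc.DensityVolume(grid, np.ones(grid.dims, dtype=bool))
    plan = cc.build_square_field_plan(8.0, mu=1.0)
    config = cc.EngineConfig()

    print("energy   d_max   PDD(10 cm)  PDD(20 cm)  surface")
    for name in ("6MV", "10FFF", "15MV"):
        beam = cc.load_beam_model(name)
        beam.calibration_scale = 1.0  # relative mode
        dose = cc.calc_plan_dose(plan, phantom, beam, config).dose
        pdd = cc.extract_pdd(dose, (0, 0, 0), (0, 0, -1))
        print(
            f"{name:6s} {pdd.d_max:5.1f} mm {pdd.at(100):8.1f}% {pdd.at(200):10.1f}%"
            f" {pdd.values[0]:8.1f}%"
        )
    print("\nd_max deepens and PDD(10 cm) rises with energy: harder beams")
    print("penetrate further and push the build-up region deeper.")


if __name__ == "__main__":
    main()
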
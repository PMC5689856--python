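"""Small-field depth dose across a lung slab, with and without HCS.

A 2 x 2 cm^2 15 MV field on the 5 cm water / 5 cm lung (ED 0.3) / 20 cm
water slab phantom loses lateral electronic equilibrium inside the lung:
the central-axis dose dips in the low-density region and re-builds after
the distal interface.  The optional heterogeneity-compensated
superposition (HCS) density filter raises the in-lung dose toward the
equilibrium expectation while leaving the homogeneous entrance region
untouched.
"""

import numpy as np

import ccdose as cc


def main() -> None:
    slab = cc.build_slab_phantom(spacing=np.array([5.0, 5.0, 2.5]), lateral_mm=200.0)
    plan = cc.build_square_field_plan(2.0, mu=1.0)
    beam = cc.load_beam_model("15MV")
    beam.calibration_scale = 1.0

    X = slab.grid.voxel_centers()
    mask = (np.abs(X[..., 0]) <= 40) & (np.abs(X[..., 1]) <= 40)

    plain = cc.calc_plan_dose(plan, slab, beam, cc.EngineConfig(), mask=mask).dose
    hcs = cc.calc_plan_dose(
        plan, slab, beam, cc.EngineConfig(hcs=cc.HCSParams()), mask=mask
    ).dose

    print("depth   no-HCS dose   HCS dose   HCS/no-HCS")
    for depth in (25, 45, 60, 70, 80, 90, 105, 125):
        p = np.array([0.0, 0.0, -float(depth)])
        a, b = float(plain.sample(p)), float(hcs.sample(p))
        print(f"{depth:4d} mm {a:10.5f} {b:10.5f} {b / a:10.3f}")
    print("\nDepths 60-90 mm lie inside the lung slab: the ratio > 1 shows HCS")
    print("raising the disequilibrated lung dose; entrance (25 mm) is unchanged.")


if __name__ == "__main__":
    main()
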
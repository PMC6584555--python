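"""Full pipeline: analytic flow field → tracer → stress tensor → PAS.

Advects a passive platelet-sized tracer through a Taylor–Couette annulus
(the classic stand-in for the narrow gap between a rotating magnet house
and the pump housing), evaluates the Newtonian viscous stress tensor along
the path, contracts it to the three scalar stresses, and integrates the
power-law activation model on each.  The choice of scalar contraction
alone changes the predicted PAS.
"""

import numpy as np

import plateletuq as pq

# 3000 rpm inner cylinder, 0.5 mm gap at ~22 mm radius
field = pq.analytic_field(
    "taylor_couette_annulus",
    omega_inner=2 * np.pi * 50, r_inner=21.5e-3, r_outer=22.0e-3,
)
st = pq.stokes_number(pq.relaxation_time(pq.PlateletProperties(), field.mu), 1e-3)
print(f"platelet Stokes number ~ {st:.1e} (≪ 1: passive tracer is justified)")

path = pq.advect(field, x0=(21.75e-3, 0.0, 0.0), duration=1.0, dt=1e-4)
tensor = pq.stress_along_path(field, path)

nobili = pq.builtin_parameters("nobili")
print(f"\n{'contraction':>12} {'tau (dyn/cm²)':>14} {'final PAS':>12}")
for variant in ("a", "b", "c"):
    tau = pq.contract_tensor(tensor, variant)
    pas = pq.integrate_nobili(tau, nobili).final_pas
    print(f"{variant:>12} {tau.tau.mean():>14.4g} {pas:>12.3e}")

print("\nThe (a) contraction is invariant under rotation of the laboratory"
      "\naxes and recovers the full gap shear; the shear-only (b) and"
      "\nnormal-only (c) contractions each capture only the part of that"
      "\nshear that lands in 'their' block of the Cartesian tensor as the"
      "\nplatelet orbits — and the factor-of-two difference in scalar"
      "\nstress maps into a factor ~1.6 in PAS, because PAS ∝ τ^b.")
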
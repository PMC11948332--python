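"""Standard-state constants and restraint-release corrections.

Builds a typical Boresch restraint set (five angular restraints at
K = 100 kcal/mol/rad^2), evaluates the surface integral S*, the bulk
orientational integral and the combined angular correction both by
adaptive quadrature and by the stiff-restraint Gaussian closed forms,
and prints the symmetry correction for a homodimer.
"""

import math

from georoute import (RestraintSpec, angular_correction,
                      bulk_orientational_term, orientational_analytic,
                      orientational_integral_numeric, s_star_analytic,
                      s_star_numeric, standard_state, symmetry_correction)

ctx = standard_state()  # 298.15 K, 1 M standard state
print(f"V0 = {ctx.v_standard:.0f} A^3 per molecule at 1 M")
print(f"r0 = {ctx.r_standard:.3f} A   A0 = {ctx.a_standard:.1f} A^2")

spec = RestraintSpec.from_dict({
    "thetaA": (85.0, 100.0), "phiA": (-60.0, 100.0),
    "thetaB": (70.0, 100.0), "phiB": (120.0, 100.0), "phiC": (40.0, 100.0)})
r_star = 25.0

s_num = s_star_numeric(spec, r_star, ctx)
s_ana = s_star_analytic(spec, r_star, ctx)
print(f"\nS* at r* = {r_star} A: quadrature {s_num:.4f} A^2, "
      f"closed form {s_ana:.4f} A^2")

o_num = orientational_integral_numeric(spec, ctx)
o_ana = orientational_analytic(spec, ctx)
print(f"orientational integral: quadrature {o_num:.6f}, "
      f"closed form {o_ana:.6f} (unrestrained would be 8 pi^2 = "
      f"{8 * math.pi ** 2:.3f})")

print(f"bulk orientational release: "
      f"{bulk_orientational_term(spec, ctx):+.3f} kcal/mol")
print(f"angular correction (all five restraints): "
      f"{angular_correction(spec, ctx):+.3f} kcal/mol")

sym = symmetry_correction(2, ctx)
print(f"\nhomodimer symmetry: sigma = {sym.sigma}, correction "
      f"{sym.energy:+.3f} kcal/mol (kT ln 2 = {ctx.kT * math.log(2):.3f})")
# The corrections are what must be added back when harmonic Boresch
# restraints are released after a restrained separation calculation.
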
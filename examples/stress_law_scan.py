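"""Scan the intercellular stress law over the full concentration range.

The stress changes sign at the equilibrium concentration C_eq: repulsive
(positive) in a crowded aggregate, adhesive traction (negative) in a
sparse one, vanishing below the interaction cut-off C_inf.  The quadratic
adhesion envelope is normalised so that the deepest traction equals
exactly -sigma_att.
"""

import numpy as np

from gliomech import SimulationParams, intercellular_stress

p = SimulationParams()
C = np.linspace(0.0, 2.0 * p.C_eq, 200001)
sigma = intercellular_stress(C, p)

i_min = int(np.argmin(sigma))
print(f"equilibrium:      sigma_C(C_eq = {p.C_eq:.2e}) = "
      f"{intercellular_stress(p.C_eq, p):+.3f} Pa")
print(f"cut-off:          sigma_C(C_inf = {p.C_inf:.2e}) = "
      f"{intercellular_stress(p.C_inf, p):+.3f} Pa")
print(f"deepest traction: {sigma[i_min]:+.3f} Pa at C = {C[i_min]:.3e} cells/mm^3")
print(f"  (analytic minimiser (2 C_eq + C_inf)/3 = {(2*p.C_eq + p.C_inf)/3:.3e})")
print(f"crowded (2 C_eq): sigma_C = {intercellular_stress(2*p.C_eq, p):+.1f} Pa "
      "(= K_C0, linear repulsive branch)")
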
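"""Derive the composite-model constants from single-cell measurements.

Every continuum parameter of the cell aggregate is fixed by a handful of
measured quantities: the cell volume, the intercellular force-distance
curve, and the rheology of cells and collagen.
"""

from gliomech import (bulk_modulus_from_young, concentration_from_spacing,
                      max_contractile_stress, max_packing_concentration,
                      mobility_from_permeability)

V_CELL = 1200.0      # μm^3, typical glioma cell volume
R_CUTOFF = 33.0      # μm, centre spacing at which cells detach
R_ATT = 16.2         # μm, centre spacing of maximal attraction
F_MAX = 430.0        # pN, maximal intercellular attraction force
N_NEIGHBORS = 12     # kissing number for close-packed spheres
S_CELL = 550.0       # μm^2, cell surface area

print("cell packing geometry")
print(f"  C_max  = {max_packing_concentration(V_CELL):.3e} cells/mm^3  "
      "(dense packing, one cell per cell volume)")
print(f"  C_inf  = {concentration_from_spacing(R_CUTOFF):.3e} cells/mm^3  "
      "(below this, cells no longer interact)")
print(f"  C_att  = {concentration_from_spacing(R_ATT):.3e} cells/mm^3  "
      "(strongest mutual attraction)")

print("adhesion and rheology")
print(f"  max sigma_att = {max_contractile_stress(F_MAX, N_NEIGHBORS, S_CELL):.2f} Pa  "
      "(deepest intercellular traction)")
print(f"  K_ECM(E=0.5 kPa, nu=0.13) = {bulk_modulus_from_young(500.0, 0.13):.0f} Pa")
print(f"  K_C0 (E=300 Pa,  nu=0.40) = {bulk_modulus_from_young(300.0, 0.40):.0f} Pa")

print("transport")
print(f"  M0 = {mobility_from_permeability(1.0e-12, 300.0):.3e} mm^2/(Pa day)  "
      "(Darcy mobility: collagen permeability / cell viscosity)")
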
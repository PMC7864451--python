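"""Cell-cell interaction basics: equilibrium distance, well depth, forces.

Two blastomeres interact through a short-ranged potential whose minimum
(-U0) sits at r* = (Ri + Rj) cos(theta): larger contact angles theta mean
stronger adhesion relative to cortical tension and deeper interpenetration.
"""

import numpy as np

import blastopack as bp

params = bp.ModelParams(theta=np.radians(30.0))
Ri = Rj = 1.0

rstar = bp.equilibrium_distance(Ri, Rj, params.theta)
print(f"contact angle 30 deg -> equilibrium distance r* = {rstar:.4f} R0")
print(f"potential at r*:      {bp.cell_cell_potential(rstar, Ri, Rj, params):+.6f} U0")
print(f"potential at 0.8 r*:  {bp.cell_cell_potential(0.8 * rstar, Ri, Rj, params):+.6f} U0 (repulsive core)")
print(f"potential at 3 (Ri+Rj): {bp.cell_cell_potential(6.0, Ri, Rj, params):+.2e} U0 (beyond reach)")

f = bp.cell_cell_force(np.array([0.8 * rstar, 0, 0]), np.zeros(3), Ri, Rj, params)
print(f"force on a cell at 0.8 r*: {f[0]:+.3f} U0/R0 along +x (pushed apart)")

# overlapping cells grow an effective radius absorbing the shared volume
vo = bp.sphere_overlap_volume(rstar, Ri, Rj)
print(f"overlap volume at r*: {vo:.4f} R0^3 -> corrected radius "
      f"{bp.corrected_radius(Ri, vo):.4f} R0 (base 1)")
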
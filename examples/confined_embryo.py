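"""One confined embryo from egg to 4-cell stage.

A repulsive spherical shell with volume 1.52x the egg volume; random
division orientations every 10 tau_M.  The run ends one timestep before
the 8-cell division and reports the packing topology -- under this tight
confinement it is a tetrahedron regardless of how the divisions were
oriented.
"""

import numpy as np

import blastopack as bp

cfg = bp.SimulationConfig(
    params=bp.ModelParams(theta=np.radians(30.0)),
    shell=bp.ShellSpec.from_volume_ratio("repulsive", Vs_over_Vc=1.52,
                                         aspect=1.0),
    plan=bp.DivisionPlan(mode="random", tauD=10.0),
    init="gaussian",
    seed=42,
)
traj = bp.run_simulation(cfg)

for ev in traj.events:
    ax = np.array(ev["axis"])
    print(f"t = {ev['time']:5.1f}  cell {ev['mother']} divided along "
          f"[{ax[0]:+.2f} {ax[1]:+.2f} {ax[2]:+.2f}]")
final = traj.final_frame
print(f"run ended at t = {final.time:.3f} tau_M ({traj.termination})")
print(f"final packing topology: {traj.final_label.value}")
r = np.linalg.norm(final.positions, axis=1)
print(f"cell centre radii: {np.round(r, 3)} (shell radius "
      f"{cfg.shell.b_axis:.3f})")
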
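"""The floppy mode: rotational diffusion of one blastomere.

Three cells are immobilized in an equilateral triangle; a fourth rolls over
the flat rim of their combined potential.  Its angular mean squared
displacement grows linearly in time (log-log slope ~1), showing that the
diamond-to-tetrahedron transition is a free diffusion process -- which is
why unconfined equilibration is so slow.
"""

import numpy as np

import blastopack as bp

trace = bp.angular_msd(bp.ModelParams(theta=np.radians(30.0)),
                       n_runs=8, t_max=1000.0, seed_base=0)
print("lag tau_M    MSD (rad^2)")
for target in (10, 30, 100, 250):
    k = int(np.argmin(np.abs(trace.t - target)))
    print(f"{trace.t[k]:8.1f}    {trace.msd[k]:.3e}")
print(f"\nlog-log slope = {trace.slope:.3f} (1 = diffusive)")
print(f"angular diffusion coefficient D = {trace.D_fit:.2e} rad^2/tau_M")
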
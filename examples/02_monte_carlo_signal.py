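"""Monte Carlo BOLD signal from a 2D vessel network.

Runs the random-walk engine on a 2% voxel (reduced spin count for speed),
reads the gradient-echo and spin-echo signals and converts them to the
apparent relaxation-rate increases dR2' and dR2.
"""

import numpy as np

from boldsim import SimulationConfig, relaxation_rate, run_approach

cfg = SimulationConfig(n_spins=4000, n_voxels=1, seed=0)
radius = 3.0          # um

tc = run_approach("2D-ANA-MC", radius, 0, cfg)
ge = abs(tc.at_time(cfg.te_gradient_echo))
se = abs(tc.at_time(cfg.te_spin_echo))
print(f"vessel radius {radius} um, {tc.n_iv} of "
      f"{tc.n_ev + tc.n_iv} spins intravascular")
print(f"|S| at the gradient echo (30 ms): {ge:.4f}")
print(f"|S| at the spin echo (70 ms):     {se:.4f} "
      "(partially refocused by the 180-deg pulse)")
print(f"dR2' = {relaxation_rate(tc, cfg.te_gradient_echo):5.2f} 1/s   "
      f"dR2 = {relaxation_rate(tc, cfg.te_spin_echo):5.2f} 1/s")
print("dR2' > dR2: gradient-echo decay keeps the static dephasing that "
      "the spin echo recovers")
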
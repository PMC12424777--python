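"""Relaxation rate versus vessel radius (a Boxerman plot) at desk scale.

Sweeps a few radii with the 2D Monte Carlo approach and prints dR2'
(gradient echo) and dR2 (spin echo).  The spin-echo rate peaks at small
radii and falls off for large vessels — diffusion averaging is only
effective when vessels are small — while the gradient-echo rate plateaus
in the static-dephasing regime.
"""

from boldsim import SimulationConfig, boxerman, run_experiment

cfg = SimulationConfig(n_spins=2500, n_voxels=2,
                       radii=(1.0, 3.0, 10.0, 30.0), seed=0)
result = run_experiment(("2D-ANA-MC",), cfg)
curve = boxerman(result, "2D-ANA-MC")
total = curve[curve.compartment == "total"]
print(f"{'radius (um)':>12} {'dR2p (1/s)':>12} {'dR2 (1/s)':>12}")
for _, row in total.iterrows():
    print(f"{row.radius_um:12.1f} {row.dr2p:12.2f} {row.dr2:12.2f}")
print("dR2 is non-monotonic in radius (diffusion narrowing -> static "
      "dephasing); dR2' approaches its static plateau for large vessels")
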
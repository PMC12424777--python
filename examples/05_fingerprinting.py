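"""Vascular fingerprinting: estimating vessel radius by dictionary lookup.

Builds a small dictionary of normalized signal evolutions from the 2D
Monte Carlo approach and matches reference-style test signals against it
by the coefficient of determination R^2.
"""

from boldsim import (SimulationConfig, build_dictionary,
                     fingerprint_error_report, fingerprint_radii,
                     run_experiment)

cfg = SimulationConfig(n_spins=2500, n_voxels=1,
                       radii=(1.0, 3.0, 6.0, 10.0, 20.0, 40.0), seed=0)
result = run_experiment(("2D-ANA-MC", "3D-ANA-MC"), cfg)

dictionary = build_dictionary(result, "2D-ANA-MC")
matches = fingerprint_radii(result, "3D-ANA-MC", dictionary)
table, summary = fingerprint_error_report(matches.estimated_radius_um,
                                          matches.true_radius_um)
print(table.to_string(index=False))
print(f"mean |error| = {summary['mean_abs_percent_error']:.1f}%  "
      f"({summary['n_erroneous']} of {summary['n_radii']} radii "
      "mis-estimated)")
print("the 2D random-B0 dictionary recovers small and mid radii; in the "
      "static-dephasing regime (>~20 um) neighbouring entries are nearly "
      "degenerate, so single-voxel runs at this reduced spin count can "
      "confuse them — more voxels/spins separate the large radii")
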
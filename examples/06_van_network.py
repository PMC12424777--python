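"""A simplified vascular anatomical network (VAN) end to end.

Synthesizes a tortuous capillary bed of finite segments, writes and
re-reads it (CSV + JSON sidecar), voxelizes a mask, solves the field with
the FFT dipole kernel and runs the Monte Carlo engine, applying the
volume-fraction signal scaling.
"""

import tempfile
from pathlib import Path

import numpy as np

from boldsim import (SimulationConfig, field_fft, read_vessel_network,
                     run_approach, synthesize_simple_van, voxelize_mask,
                     write_vessel_network)

cfg = SimulationConfig(n_spins=2000, n_voxels=1, seed=0,
                       van_edge_length=200.0)
net = synthesize_simple_van(cfg.van_edge_length, cfg.van_radius, 0.02,
                            cfg.van_segment_density,
                            np.random.default_rng(3))
print(f"synthesized {net.n_vessels} segments of radius "
      f"{cfg.van_radius} um; achieved volume fraction "
      f"{net.blood_volume_fraction:.4f} (nominal 0.02)")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "van.csv"
    write_vessel_network(net, path)
    back = read_vessel_network(path)
    print(f"round-tripped through {path.name}: {back.n_vessels} segments")

mask = voxelize_mask(net, 96)
field = field_fft(mask, net.voxel.edge_length, cfg.delta_chi, cfg.b0)
print(f"mask fraction {mask.mean():.4f}; field spread "
      f"{field.offsets.std() / cfg.b0 * 1e9:.1f} ppb")

tc = run_approach("3D-FFT-MC-VAN", cfg.van_radius, 0, cfg, base_network=net,
                  grid_points=96)
print(f"|S| at 30 ms (GE): {abs(tc.at_time(30.0)):.4f};  at 70 ms (SE): "
      f"{abs(tc.at_time(70.0)):.4f}")
print("the signal is volume-scaled to the nominal 2% so VAN runs are "
      "comparable with the infinite-cylinder networks")
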
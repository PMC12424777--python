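"""Seeded, scaled presets for tests, examples and desk-scale reproductions.

Each preset bundles a :class:`SimulationConfig` with the approaches it is
meant to exercise.  The "full-table1" preset is the standard operating
point (40,000 spins, ten voxels, all fifteen radii) — an overnight-scale
run; the others are desk-scale surrogates that keep the physics and the
qualitative orderings while completing in seconds to minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import SimulationConfig
from .engine import APPROACHES


@dataclass
class FixturePreset:
    name: str
    config: SimulationConfig
    approaches: tuple[str, ...]
    description: str
    extras: dict = field(default_factory=dict)


def make_preset(name: str, seed: int = 0) -> FixturePreset:
    """Build a named preset.

    - ``unit``: one vessel, 100 spins, 50 steps — an end-to-end smoke run.
    - ``matched-2d``: a small 2D voxel simulated by both the Monte Carlo
      and the deterministic-diffusion engines for direct comparison.
    - ``mini-fingerprint``: 5,000 spins, 2 voxels, all fifteen radii — the
      desk-scale fingerprinting comparison (reference, 3B0 and
      single-vessel dictionaries).
    - ``full-table1``: the full standard configuration.
    """
    if name == "unit":
        cfg = SimulationConfig(
            n_spins=100, n_voxels=1, radii=(2.0,), total_time=10.0,
            te_gradient_echo=4.0, te_spin_echo=6.0, seed=seed)
        return FixturePreset(name, cfg, ("2D-ANA-MC-1V",),
                             "single vessel, 100 spins, 50 steps")
    if name == "matched-2d":
        cfg = SimulationConfig(
            n_spins=5000, n_voxels=1, radii=(2.0,), edge_length_2d=40.0,
            base_radius=2.0, total_time=30.0, te_gradient_echo=10.0,
            te_spin_echo=20.0, seed=seed)
        return FixturePreset(name, cfg, ("2D-ANA-MC", "2D-ANA-DD"),
                             "identical small 2D network for MC vs DD",
                             extras={"dd_grid_points": 240})
    if name == "mini-fingerprint":
        cfg = SimulationConfig(n_spins=5000, n_voxels=2, seed=seed)
        return FixturePreset(
            name, cfg, ("3D-ANA-MC", "2D-ANA-MC-3B0", "2D-ANA-MC-1V"),
            "desk-scale fingerprinting sweep over all 15 radii")
    if name == "full-table1":
        return FixturePreset(name, SimulationConfig(seed=seed), APPROACHES,
                             "the full standard configuration")
    raise ValueError(f"unknown preset {name!r}; choose from unit, "
                     f"matched-2d, mini-fingerprint, full-table1")
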
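"""Simulation configuration.

All scalar physics and acquisition parameters live in :class:`SimulationConfig`.
Units follow the field's conventions: lengths in micrometres, times in
milliseconds, fields in tesla, the diffusion coefficient in um^2/ms and the
susceptibility difference as a dimensionless SI volume susceptibility.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

#: Gyromagnetic ratio of the hydrogen nucleus, rad s^-1 T^-1.
GAMMA = 2.675e8

#: Vessel radii (um) of the standard radius sweep.
DEFAULT_RADII = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 13.0, 16.0,
                 20.0, 30.0, 40.0, 60.0)


@dataclass
class SimulationConfig:
    """Parameters shared by every simulation approach.

    The defaults are the standard operating point of the suite: a 3 T scanner,
    venous blood with a susceptibility offset of 4.15e-7 (about 65%
    oxygenation at 35% hematocrit), 2% blood volume, free-water diffusion at
    1 um^2/ms, a 0.2 ms timestep, a 70 ms spin echo with the gradient-echo
    readout taken from the same run at 30 ms, 40,000 Monte Carlo spins and
    ten random voxels per radius.
    """

    b0: float = 3.0                      # main field, T
    delta_chi: float = 4.15e-7           # IV-EV susceptibility difference, SI
    diffusion_coefficient: float = 1.0   # um^2/ms
    timestep: float = 0.2                # ms
    te_gradient_echo: float = 30.0       # ms
    te_spin_echo: float = 70.0           # ms
    total_time: float = 120.0            # ms
    n_spins: int = 40_000
    blood_volume_fraction: float = 0.02
    radii: tuple[float, ...] = DEFAULT_RADII
    n_voxels: int = 10
    seed: int = 0

    # Geometry of the base (1-um radius) voxels; larger radii reuse the same
    # vessel arrangements with every length scaled by radius/base_radius.
    base_radius: float = 1.0             # um
    edge_length_3d: float = 149.0        # um
    edge_length_2d: float = 251.0        # um

    # Grid resolutions for discretized field maps.
    grid_points_3d: int = 500
    grid_points_2d: int = 1000

    # Deterministic-diffusion grid sizing rule: base_grid points per side at
    # dd_base_radius, scaled linearly with radius, rounded up to a multiple of
    # ten, never below dd_min_grid.  dd_max_cells is a memory guard.
    dd_base_grid: int = 15_860
    dd_base_radius: float = 60.0
    dd_min_grid: int = 1000
    dd_max_cells: int = 300_000_000

    # Single-vessel (1V) voxel sizing: edge chosen so one centred vessel of
    # radius R occupies this area fraction.
    single_vessel_volume_fraction: float = 0.02

    # Simplified VAN stand-in generator.
    van_edge_length: float = 400.0       # um, at van_radius
    van_radius: float = 2.85             # um, single radius for all segments
    van_segment_density: float = 26_100.0  # segments per mm^3
    van_persistence: float = 4.0         # correlated-walk stiffness (unitless)

    def __post_init__(self) -> None:
        for name in ("b0", "timestep", "total_time", "blood_volume_fraction",
                     "edge_length_3d", "edge_length_2d", "base_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be non-negative")
        if not 0 < self.blood_volume_fraction < 1:
            raise ValueError("blood_volume_fraction must lie in (0, 1)")
        if self.n_spins < 1 or self.n_voxels < 1:
            raise ValueError("n_spins and n_voxels must be at least 1")
        if any(r <= 0 for r in self.radii):
            raise ValueError("all radii must be positive")
        self.radii = tuple(float(r) for r in self.radii)
        for te, half in ((self.te_gradient_echo, False),
                         (self.te_spin_echo, True)):
            t = te / 2 if half else te
            if abs(t / self.timestep - round(t / self.timestep)) > 1e-9:
                raise ValueError(
                    f"echo time {te} ms (half={half}) is not an integer "
                    f"multiple of the timestep {self.timestep} ms")
        if self.te_spin_echo > self.total_time or \
                self.te_gradient_echo > self.total_time:
            raise ValueError("echo times must fit inside total_time")

    @property
    def n_steps(self) -> int:
        """Number of recorded time points, total_time / timestep."""
        return int(round(self.total_time / self.timestep))

    @property
    def sigma2(self) -> float:
        """Per-axis displacement variance per step, 2*D*dt (um^2)."""
        return 2.0 * self.diffusion_coefficient * self.timestep

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["radii"] = list(d["radii"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "radii" in d:
            d["radii"] = tuple(d["radii"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml
            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))
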
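"""The eight named simulation approaches and experiment orchestration.

Each approach is a fixed combination of voxel dimensionality, field-offset
solver (analytic vs Fourier, continuous vs gridded) and diffusion engine
(Monte Carlo vs deterministic):

=================  ===  ==========  ==========  ====  =========================
name               dim  dB0         sampling    diff  notes
=================  ===  ==========  ==========  ====  =========================
3D-ANA-MC          3    analytic    continuous  MC    reference approach
2D-ANA-MC          2    analytic    continuous  MC    random B0 per vessel
2D-ANA-DD          2    analytic    gridded     DD    as above, deterministic
2D-ANA-MC-1V       2    analytic    continuous  MC    single vessel, 9 angles
2D-ANA-MC-3B0      2    analytic    continuous  MC    3-orthogonal-B0 average
3D-ANA-MC-GRID     3    analytic    gridded     MC    reference, gridded field
3D-FFT-MC          3    FFT         gridded     MC    dipole-kernel field
3D-FFT-MC-VAN      3    FFT         gridded     MC    simplified VAN geometry
=================  ===  ==========  ==========  ====  =========================

All 3D infinite-cylinder approaches share the same base voxels (scaled per
radius), so differences between them isolate the field solver; the master
seed deterministically derives every geometry and spin stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diffusion_dd, diffusion_mc, fieldmap as fm, geometry as geo
from .config import SimulationConfig
from .timecourse import SignalTimecourse, mean_timecourse

logger = logging.getLogger(__name__)

APPROACHES = ("3D-ANA-MC", "2D-ANA-MC", "2D-ANA-DD", "2D-ANA-MC-1V",
              "2D-ANA-MC-3B0", "3D-ANA-MC-GRID", "3D-FFT-MC",
              "3D-FFT-MC-VAN")

#: Polar B0 angles (degrees) of the single-vessel approach.
SINGLE_VESSEL_ANGLES = tuple(range(10, 100, 10))

# seed-derivation domains
_GEOM3D, _GEOM2D, _VAN, _SPINS = 1, 2, 3, 4


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *key]))


def _radius_key(radius: float) -> int:
    return int(round(radius * 1000))


# ---------------------------------------------------------------------------
# base geometry (one set per voxel id, reused across radii and approaches)
# ---------------------------------------------------------------------------

def base_network_3d(config: SimulationConfig, voxel_id: int) -> geo.VesselNetwork:
    return geo.generate_network_3d(config.edge_length_3d, config.base_radius,
                                   config.blood_volume_fraction,
                                   _rng(config, _GEOM3D, voxel_id))


def base_network_2d(config: SimulationConfig, voxel_id: int) -> geo.VesselNetwork:
    return geo.generate_network_2d(config.edge_length_2d, config.base_radius,
                                   config.blood_volume_fraction,
                                   _rng(config, _GEOM2D, voxel_id),
                                   field_mode="per_vessel_random_B0")


def base_network_van(config: SimulationConfig, voxel_id: int) -> geo.VesselNetwork:
    return geo.synthesize_simple_van(config.van_edge_length, config.van_radius,
                                     config.blood_volume_fraction,
                                     config.van_segment_density,
                                     _rng(config, _VAN, voxel_id),
                                     persistence=config.van_persistence)


def dd_grid_points(config: SimulationConfig, radius: float) -> int:
    """Deterministic-diffusion grid sizing: base grid scaled linearly with
    radius, rounded up to a multiple of ten, floored at dd_min_grid."""
    n = int(np.ceil(config.dd_base_grid * radius /
                    (config.dd_base_radius * 10.0)) * 10)
    return max(config.dd_min_grid, n)


# ---------------------------------------------------------------------------
# approach dispatch
# ---------------------------------------------------------------------------

def run_approach(name: str, radius: float, voxel_id: int,
                 config: SimulationConfig,
                 base_network: geo.VesselNetwork | None = None,
                 grid_points: int | None = None) -> SignalTimecourse:
    """Run one (approach, radius, voxel) simulation.

    ``base_network`` lets callers reuse a cached base-radius network (the
    standard protocol for the multi-voxel approaches); when omitted it is
    rebuilt from the master seed, so results are identical either way.
    ``grid_points`` overrides the gridded approaches' field resolution
    (config.grid_points_3d / the DD sizing rule by default).
    """
    if name not in APPROACHES:
        raise ValueError(f"unknown approach {name!r}; valid names: "
                         f"{', '.join(APPROACHES)}")
    spin_rng = _rng(config, _SPINS, APPROACHES.index(name),
                    _radius_key(radius), voxel_id)

    if name == "2D-ANA-MC-1V":
        tc = _run_single_vessel(radius, config, spin_rng)
    elif name.startswith("2D"):
        base = base_network or base_network_2d(config, voxel_id)
        net = geo.scale_network_for_radius(base, radius)
        if name == "2D-ANA-MC":
            fld = fm.analytic_field(net, config, mode="per_vessel")
            tc = diffusion_mc.run_mc(net, fld, config, spin_rng)
        elif name == "2D-ANA-MC-3B0":
            fld = fm.analytic_field(net, config, mode="three_b0")
            tc = diffusion_mc.run_mc(net, fld, config, spin_rng)
        else:  # 2D-ANA-DD
            n = grid_points or dd_grid_points(config, radius)
            fld = fm.field_on_grid_analytic(net, n, config, mode="per_vessel")
            tc = diffusion_dd.run_dd(net, fld, config)
    else:
        if name == "3D-FFT-MC-VAN":
            # scaling a 2.85-um VAN to vessel radius R gives the effective
            # voxel edge 400 * R / 2.85 um (~140 um at R = 1 um)
            base = base_network or base_network_van(config, voxel_id)
            net = geo.scale_network_for_radius(base, radius)
        else:
            base = base_network or base_network_3d(config, voxel_id)
            net = geo.scale_network_for_radius(base, radius)
        if name == "3D-ANA-MC":
            fld = fm.analytic_field(net, config, mode="global_z")
            tc = diffusion_mc.run_mc(net, fld, config, spin_rng)
        else:
            n = grid_points or config.grid_points_3d
            if name == "3D-ANA-MC-GRID":
                fld = fm.field_on_grid_analytic(net, n, config,
                                                mode="global_z")
            else:  # 3D-FFT-MC and 3D-FFT-MC-VAN
                mask = geo.voxelize_mask(net, n)
                fld = fm.field_fft(mask, net.voxel.edge_length,
                                   config.delta_chi, config.b0)
            tc = diffusion_mc.run_mc(net, fld, config, spin_rng)
        if name == "3D-FFT-MC-VAN":
            tc = van_volume_scaling(tc, net.blood_volume_fraction,
                                    config.blood_volume_fraction)
    tc.approach = name
    tc.radius = radius
    tc.voxel_id = voxel_id
    tc.seed = config.seed
    return tc


def _run_single_vessel(radius: float, config: SimulationConfig,
                       spin_rng: np.random.Generator) -> SignalTimecourse:
    """Single centred vessel, simulated at nine polar B0 angles and
    sin(theta)-weight averaged.

    The voxel edge is chosen so the one vessel realises the nominal blood
    volume fraction (L = R * sqrt(pi/zeta)); the field is that of the
    isolated vessel (no periodic images), so the intravascular space is
    perfectly homogeneous at every angle.
    """
    edge = radius * np.sqrt(np.pi / config.single_vessel_volume_fraction)
    by_theta = {}
    for theta_deg in SINGLE_VESSEL_ANGLES:
        net = geo.single_vessel_network(edge, radius,
                                        np.deg2rad(theta_deg))
        fld = fm.analytic_field(net, config, mode="per_vessel", wrap=False)
        child = np.random.default_rng(spin_rng.integers(2 ** 31))
        by_theta[theta_deg] = diffusion_mc.run_mc(net, fld, config, child)
    return angle_average(by_theta)


def angle_average(signals_by_theta: dict[float, SignalTimecourse]
                  ) -> SignalTimecourse:
    """sin(theta)-weighted average of single-vessel runs over the polar
    angles 10..90 degrees, applied per compartment and timepoint."""
    missing = [a for a in SINGLE_VESSEL_ANGLES
               if a not in signals_by_theta]
    if missing:
        raise ValueError(f"missing angles: {missing}")
    weights = np.array([np.sin(np.deg2rad(a))
                        for a in SINGLE_VESSEL_ANGLES])
    weights = weights / weights.sum()
    courses = [signals_by_theta[a] for a in SINGLE_VESSEL_ANGLES]
    t = courses[0].times
    out = {}
    for comp in ("s_tot", "s_ev", "s_iv"):
        out[comp] = np.sum([w * getattr(c, comp)
                            for w, c in zip(weights, courses)], axis=0)
    return SignalTimecourse(times=t.copy(), **out,
                            n_ev=courses[0].n_ev, n_iv=courses[0].n_iv,
                            echoes=dict(courses[0].echoes))


def van_volume_scaling(tc: SignalTimecourse, zeta_actual: float,
                       zeta_nominal: float) -> SignalTimecourse:
    """Compensate a blood-volume shortfall by signal scaling.

    The log-magnitude of each compartment signal is multiplied by
    zeta_nominal / zeta_actual (|S|' = |S|^ratio) with the phase preserved,
    the standard correction for a synthesized network whose achieved volume
    fraction missed the nominal one.
    """
    if not (0 < zeta_actual < 1 and 0 < zeta_nominal < 1):
        raise ValueError("volume fractions must lie in (0, 1)")
    ratio = zeta_nominal / zeta_actual
    def scale(s):
        mag = np.abs(s)
        with np.errstate(invalid="ignore"):
            phase = np.where(mag > 0, s / np.where(mag > 0, mag, 1.0), 1.0)
        return mag ** ratio * phase
    return SignalTimecourse(times=tc.times.copy(), s_tot=scale(tc.s_tot),
                            s_ev=scale(tc.s_ev), s_iv=scale(tc.s_iv),
                            approach=tc.approach, radius=tc.radius,
                            voxel_id=tc.voxel_id, seed=tc.seed,
                            n_ev=tc.n_ev, n_iv=tc.n_iv,
                            echoes=dict(tc.echoes))


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """All signals of a radii x voxels x approaches sweep."""

    config: SimulationConfig
    signals: dict = field(default_factory=dict)   # (approach, radius, voxel)

    def voxel_ids(self, approach: str) -> list[int]:
        return sorted({k[2] for k in self.signals if k[0] == approach})

    def radii(self, approach: str) -> list[float]:
        return sorted({k[1] for k in self.signals if k[0] == approach})

    def get(self, approach: str, radius: float,
            voxel_id: int) -> SignalTimecourse:
        return self.signals[(approach, radius, voxel_id)]

    def mean_signal(self, approach: str, radius: float) -> SignalTimecourse:
        courses = [tc for (a, r, _v), tc in sorted(self.signals.items())
                   if a == approach and r == radius]
        if not courses:
            raise KeyError((approach, radius))
        return mean_timecourse(courses)

    def table(self) -> pd.DataFrame:
        """One row per run with signal magnitudes at the echo times."""
        rows = []
        for (a, r, v), tc in sorted(self.signals.items()):
            row = {"approach": a, "radius_um": r, "voxel": v,
                   "n_ev": tc.n_ev, "n_iv": tc.n_iv}
            for echo, te in tc.echoes.items():
                row[f"abs_s_tot_{echo}"] = abs(tc.at_time(te, "total"))
            rows.append(row)
        return pd.DataFrame(rows)


def run_experiment(approaches, config: SimulationConfig,
                   grid_points: int | None = None) -> ExperimentResult:
    """Run every (approach, radius, voxel) combination of a sweep.

    Base networks are generated once per voxel and shared across radii and
    across the approaches that use the same geometry family.  The
    single-vessel approach has no geometric randomness and runs on a single
    voxel.  Everything is deterministic given config.seed.
    """
    result = ExperimentResult(config=config)
    cache: dict[tuple[str, int], geo.VesselNetwork] = {}

    def base_for(name: str, voxel_id: int):
        if name == "2D-ANA-MC-1V":
            return None
        kind = ("van" if name == "3D-FFT-MC-VAN"
                else "3d" if name.startswith("3D") else "2d")
        key = (kind, voxel_id)
        if key not in cache:
            builder = {"3d": base_network_3d, "2d": base_network_2d,
                       "van": base_network_van}[kind]
            cache[key] = builder(config, voxel_id)
        return cache[key]

    for name in approaches:
        if name not in APPROACHES:
            raise ValueError(f"unknown approach {name!r}")
        voxels = [0] if name == "2D-ANA-MC-1V" else range(config.n_voxels)
        for voxel_id in voxels:
            base = base_for(name, voxel_id)
            for radius in config.radii:
                logger.info("running %s R=%.3g um voxel %d",
                            name, radius, voxel_id)
                try:
                    tc = run_approach(name, radius, voxel_id, config,
                                      base_network=base,
                                      grid_points=grid_points)
                except Exception as exc:
                    raise RuntimeError(
                        f"{name} failed at radius {radius} um, voxel "
                        f"{voxel_id}: {exc}") from exc
                result.signals[(name, radius, voxel_id)] = tc
    return result
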
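"""Monte Carlo random-walk diffusion with phase accrual.

Spins perform independent Gaussian random walks (per-axis variance 2*D*dt
per step) inside a cyclic voxel: a spin leaving one face re-enters through
the opposite one, emulating a voxel surrounded by copies of itself.
Vessels are impermeable — a displacement that would move a spin across the
vessel wall is redrawn (the whole displacement vector) until the spin stays
in its original compartment, up to a retry cap after which the spin simply
keeps its position for that step.  Each spin accrues phase
phi_j = phi_{j-1} + gamma * dB0(r_j) * dt, and the signal in each
compartment is the mean of exp(-i*phi) over its spins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GAMMA, SimulationConfig
from .geometry import VesselNetwork, label_points
from .timecourse import SignalTimecourse

#: Redraws allowed before a compartment-violating spin is frozen for a step.
RETRY_CAP = 100


@dataclass
class SpinEnsemble:
    """Positions, phases and (fixed) compartment labels of the spin walkers."""

    positions: np.ndarray        # (Ns, 3), um; z = 0 throughout in 2D
    phases: np.ndarray           # (Ns,), rad
    iv_labels: np.ndarray        # (Ns,) bool, True = intravascular
    dim: int                     # 2 or 3
    frozen_steps: int = 0        # retry-cap exhaustions (diagnostic counter)

    @property
    def n_spins(self) -> int:
        return len(self.phases)


def initialize_spins(network: VesselNetwork, n_spins: int,
                     rng: np.random.Generator) -> SpinEnsemble:
    """Uniformly distribute spins over the voxel with zero phase.

    Compartment labels are assigned once, from the initial positions; with
    impermeable vessels they never change, so the intravascular spin
    fraction is a binomial draw around the blood volume fraction.
    """
    if n_spins < 1:
        raise ValueError("n_spins must be >= 1")
    L = network.voxel.edge_length
    dim = network.voxel.dimensionality
    positions = np.zeros((n_spins, 3))
    positions[:, :dim] = rng.uniform(-L / 2, L / 2, size=(n_spins, dim))
    labels = label_points(network, positions) if network.n_vessels else \
        np.zeros(n_spins, dtype=bool)
    return SpinEnsemble(positions=positions, phases=np.zeros(n_spins),
                        iv_labels=labels, dim=dim)


def _wrap(positions: np.ndarray, L: float, dim: int) -> None:
    positions[:, :dim] = (positions[:, :dim] + L / 2) % L - L / 2


def step_spins(ensemble: SpinEnsemble, network: VesselNetwork, D: float,
               dt: float, rng: np.random.Generator) -> SpinEnsemble:
    """Advance every spin by one Gaussian step with impermeable vessels.

    D is in um^2/ms and dt in ms.  Displacements are drawn per axis with
    variance 2*D*dt; positions wrap cyclically.  Spins whose proposed
    position changes compartment are redrawn as a whole until they stay put
    compartment-wise (RETRY_CAP redraws, then frozen for this step).
    """
    if D < 0 or dt <= 0:
        raise ValueError("require D >= 0 and dt > 0")
    if D == 0:
        return ensemble
    sigma = np.sqrt(2.0 * D * dt)
    L = network.voxel.edge_length
    dim = ensemble.dim
    proposed = ensemble.positions.copy()
    proposed[:, :dim] += rng.normal(0.0, sigma,
                                    size=(ensemble.n_spins, dim))
    _wrap(proposed, L, dim)
    if network.n_vessels == 0:
        ensemble.positions = proposed
        return ensemble
    new_labels = label_points(network, proposed)
    bad = np.flatnonzero(new_labels != ensemble.iv_labels)
    tries = 0
    while bad.size and tries < RETRY_CAP:
        redraw = ensemble.positions[bad].copy()
        redraw[:, :dim] += rng.normal(0.0, sigma, size=(bad.size, dim))
        _wrap(redraw, L, dim)
        ok = label_points(network, redraw) == ensemble.iv_labels[bad]
        proposed[bad[ok]] = redraw[ok]
        bad = bad[~ok]
        tries += 1
    if bad.size:                      # freeze: keep previous position
        proposed[bad] = ensemble.positions[bad]
        ensemble.frozen_steps += bad.size
    ensemble.positions = proposed
    return ensemble


def accrue_phase(ensemble: SpinEnsemble, fieldmap, dt: float) -> SpinEnsemble:
    """Add gamma * dB0(r) * dt to each spin's phase (dt in ms).

    ``fieldmap`` is any object with an ``at(points) -> offsets in T`` method
    (continuous analytic evaluator or gridded map with nearest-neighbour
    lookup).
    """
    offsets = fieldmap.at(ensemble.positions)
    ensemble.phases += GAMMA * offsets * (dt * 1e-3)
    return ensemble


def apply_refocusing(ensemble: SpinEnsemble) -> SpinEnsemble:
    """Ideal instantaneous 180-degree pulse: phase conjugation."""
    np.negative(ensemble.phases, out=ensemble.phases)
    return ensemble


def signals_from_phases(ensemble: SpinEnsemble):
    """Compartment signals (S_tot, S_EV, S_IV) as means of exp(-i*phi).

    An empty compartment yields NaN; the total is always the spin-count
    weighted mean of the compartment signals.
    """
    phasors = np.exp(-1j * ensemble.phases)
    iv = ensemble.iv_labels
    s_tot = phasors.mean()
    s_ev = phasors[~iv].mean() if (~iv).any() else complex(np.nan, np.nan)
    s_iv = phasors[iv].mean() if iv.any() else complex(np.nan, np.nan)
    return s_tot, s_ev, s_iv


def _evaluate(fieldmap, network: VesselNetwork, positions: np.ndarray):
    """Offsets and intravascular flags at the given positions.

    Continuous analytic evaluators expose a fused one-pass routine; for
    gridded fields the offset is a nearest-neighbour lookup and the
    compartment test runs against the vessel geometry.
    """
    if hasattr(fieldmap, "at_with_inside"):
        return fieldmap.at_with_inside(positions)
    offsets = fieldmap.at(positions)
    inside = label_points(network, positions) if network.n_vessels else \
        np.zeros(len(positions), dtype=bool)
    return offsets, inside


def run_mc(network: VesselNetwork, fieldmap, config: SimulationConfig,
           rng: np.random.Generator,
           spin_echo: bool = True) -> SignalTimecourse:
    """Run a full Monte Carlo signal simulation on one voxel.

    Records n_steps = total_time/dt samples at t_j = j*dt (j = 0 gives
    S = 1).  When ``spin_echo`` is set, phases are conjugated once at
    TE_SE/2 (which must be an integer multiple of dt); the gradient-echo
    signal is simply the same run read at TE_GE, before the refocusing
    pulse.  Per step, each spin's field offset and compartment are
    evaluated together at its proposed position; compartment-violating
    displacements are redrawn up to RETRY_CAP, after which the spin is
    frozen for the step and keeps its previous offset (the field is static
    in time).
    """
    dt = config.timestep
    n_steps = config.n_steps
    refocus_at = config.te_spin_echo / 2.0 / dt
    if spin_echo and abs(refocus_at - round(refocus_at)) > 1e-9:
        raise ValueError("TE_SE/2 must be an integer multiple of dt")
    refocus_idx = int(round(refocus_at))
    ensemble = initialize_spins(network, config.n_spins, rng)
    dim = ensemble.dim
    L = network.voxel.edge_length
    D = config.diffusion_coefficient
    sigma = np.sqrt(2.0 * D * dt)
    times = np.arange(n_steps) * dt
    s_tot = np.empty(n_steps, dtype=complex)
    s_ev = np.empty(n_steps, dtype=complex)
    s_iv = np.empty(n_steps, dtype=complex)
    s_tot[0], s_ev[0], s_iv[0] = signals_from_phases(ensemble)
    offsets, _ = _evaluate(fieldmap, network, ensemble.positions)
    dt_s = dt * 1e-3
    for j in range(1, n_steps):
        if D > 0:
            proposed = ensemble.positions.copy()
            proposed[:, :dim] += rng.normal(0.0, sigma,
                                            size=(ensemble.n_spins, dim))
            _wrap(proposed, L, dim)
            new_offsets, inside = _evaluate(fieldmap, network, proposed)
            bad = np.flatnonzero(inside != ensemble.iv_labels)
            tries = 0
            while bad.size and tries < RETRY_CAP:
                redraw = ensemble.positions[bad].copy()
                redraw[:, :dim] += rng.normal(0.0, sigma,
                                              size=(bad.size, dim))
                _wrap(redraw, L, dim)
                off_b, in_b = _evaluate(fieldmap, network, redraw)
                ok = in_b == ensemble.iv_labels[bad]
                sel = bad[ok]
                proposed[sel] = redraw[ok]
                new_offsets[sel] = off_b[ok]
                bad = bad[~ok]
                tries += 1
            if bad.size:               # freeze for this step
                proposed[bad] = ensemble.positions[bad]
                new_offsets[bad] = offsets[bad]
                ensemble.frozen_steps += bad.size
            ensemble.positions = proposed
            offsets = new_offsets
        ensemble.phases += GAMMA * offsets * dt_s
        s_tot[j], s_ev[j], s_iv[j] = signals_from_phases(ensemble)
        if spin_echo and j == refocus_idx:
            apply_refocusing(ensemble)
            # the echo-path signal from here on is the conjugated one
    n_iv = int(ensemble.iv_labels.sum())
    echoes = {"GE": config.te_gradient_echo}
    if spin_echo:
        echoes["SE"] = config.te_spin_echo
    return SignalTimecourse(times=times, s_tot=s_tot, s_ev=s_ev, s_iv=s_iv,
                            n_ev=ensemble.n_spins - n_iv, n_iv=n_iv,
                            echoes=echoes)
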
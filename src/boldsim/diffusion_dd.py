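"""Deterministic (convolution-based) diffusion of a magnetization grid.

Instead of tracking particles, the complex transverse magnetization is
discretized on a 2D grid, initialized to 1 everywhere, and advanced by
alternating precession (element-wise phasor multiplication) and diffusion
(separable circular convolution with the discretized Gaussian kernel
D_k = exp(-a) * I_k(a), a = sigma^2/dx^2, truncated at +-6 sigma).  The
separable per-axis form is exact for independent isotropic diffusion and
far cheaper than a full 2D kernel.

Impermeable vessels are modelled by a conservation correction: convolving
the intravascular indicator with the kernel gives each cell's stay-in-
compartment fraction, and the magnetization a source cell leaks across the
wall is returned to it, so each compartment's summed magnetization is
conserved exactly by the diffusion step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, special

from .config import GAMMA, SimulationConfig
from .geometry import VesselNetwork, voxelize_mask
from .timecourse import SignalTimecourse

#: Minimum number of kernel elements inside +-6 sigma for the kernel not to
#: degenerate toward a delta function.
MIN_KERNEL_ELEMENTS = 13


class KernelResolutionError(ValueError):
    """Grid too coarse to sample the diffusion kernel."""


@dataclass
class MagnetizationGrid:
    """Complex magnetization on a 2D grid with a static compartment mask."""

    m: np.ndarray                # (n, n) complex
    iv_mask: np.ndarray          # (n, n) bool
    spacing: float               # um
    step_index: int = 0

    @property
    def n_iv(self) -> int:
        return int(self.iv_mask.sum())

    @property
    def n_ev(self) -> int:
        return self.iv_mask.size - self.n_iv


def build_diffusion_kernel(sigma2: float, dx: float,
                           renormalize: bool = True) -> np.ndarray:
    """1D discrete diffusion kernel for one timestep.

    sigma2 = 2*D*dt (um^2), dx the grid spacing (um).  The kernel spans
    +-6 sigma and must contain at least 13 elements there, otherwise a
    :class:`KernelResolutionError` directs the caller to refine the grid.
    sigma2 = 0 returns the identity (delta) kernel.  By default the
    truncated kernel is renormalized to unit sum so diffusion conserves
    magnetization exactly.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if sigma2 == 0:
        return np.array([1.0])
    sigma = np.sqrt(sigma2)
    half = int(np.floor(6.0 * sigma / dx))
    n_elements = 2 * half + 1
    if n_elements < MIN_KERNEL_ELEMENTS:
        raise KernelResolutionError(
            f"diffusion kernel would hold {n_elements} elements within "
            f"+-6 sigma (sigma = {sigma:.4g} um, dx = {dx:.4g} um); at "
            f"least {MIN_KERNEL_ELEMENTS} are required — refine the grid "
            f"to dx <= {sigma:.4g} um")
    a = sigma2 / dx ** 2
    k = np.arange(-half, half + 1)
    kernel = special.ive(np.abs(k), a)      # exp(-a) * I_k(a), stable
    if renormalize:
        kernel = kernel / kernel.sum()
    return kernel


def _conv_sep_real(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = ndimage.convolve1d(arr, kernel, axis=0, mode="wrap")
    return ndimage.convolve1d(out, kernel, axis=1, mode="wrap")


def convolve_wrapped(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Separable circular convolution along both axes (complex-safe)."""
    if np.iscomplexobj(arr):
        return _conv_sep_real(arr.real, kernel) + \
            1j * _conv_sep_real(arr.imag, kernel)
    return _conv_sep_real(arr, kernel)


def stay_fraction(iv_mask: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Kernel-convolved IV indicator: each cell's stay-in-IV fraction."""
    return _conv_sep_real(iv_mask.astype(float), kernel)


def impermeability_correction(m_before: np.ndarray, m_after: np.ndarray,
                              iv_mask: np.ndarray,
                              kernel: np.ndarray) -> np.ndarray:
    """Return magnetization that crossed the vessel wall to its source cells.

    ``m_before`` is the magnetization entering the diffusion step (after
    precession), ``m_after`` the freely diffused result.  With
    w = kernel * IV-indicator, an IV source cell leaks the fraction (1 - w)
    of its magnetization into EV cells (and an EV cell the fraction w into
    IV cells); that leaked amount is handed back to the source cell, which
    makes each compartment's sum after the step equal its sum before, up to
    rounding.
    """
    if m_before.shape != m_after.shape or m_before.shape != iv_mask.shape:
        raise ValueError("grid shapes do not match")
    iv = iv_mask.astype(bool)
    if not iv.any():
        return m_after
    w = stay_fraction(iv, kernel)
    a = convolve_wrapped(np.where(iv, m_before, 0.0), kernel)
    b = m_after - a
    corrected = np.where(iv,
                         a + m_before * (1.0 - w),
                         b + m_before * w)
    return corrected


def dd_step(grid: MagnetizationGrid, phasor: np.ndarray, kernel: np.ndarray,
            correct_impermeable: bool = True) -> MagnetizationGrid:
    """One deterministic-diffusion step: precess, diffuse, correct.

    ``phasor`` is exp(-i * gamma * dB0 * dt) on the same grid.
    """
    if phasor.shape != grid.m.shape:
        raise ValueError("phasor grid does not match the magnetization grid")
    m_pre = grid.m * phasor
    m_diff = convolve_wrapped(m_pre, kernel)
    if correct_impermeable and grid.iv_mask.any():
        m_diff = impermeability_correction(m_pre, m_diff, grid.iv_mask,
                                           kernel)
    grid.m = m_diff
    grid.step_index += 1
    return grid


def _signals(grid: MagnetizationGrid):
    m = grid.m
    iv = grid.iv_mask
    s_tot = m.mean()
    s_ev = m[~iv].mean() if (~iv).any() else complex(np.nan, np.nan)
    s_iv = m[iv].mean() if iv.any() else complex(np.nan, np.nan)
    return s_tot, s_ev, s_iv


def run_dd(network: VesselNetwork, fieldmap, config: SimulationConfig,
           spin_echo: bool = True) -> SignalTimecourse:
    """Run a deterministic-diffusion signal simulation on a 2D voxel.

    ``fieldmap`` must be a :class:`~boldsim.fieldmap.GriddedFieldMap` whose
    2D grid sets the magnetization resolution; the vessel mask is
    voxelized at the same resolution.  Refocusing conjugates the grid at
    TE_SE/2.  Grids larger than config.dd_max_cells cells are refused.
    """
    if network.voxel.dimensionality != 2:
        raise ValueError("deterministic diffusion is implemented in 2D")
    offsets = fieldmap.offsets
    if offsets.ndim != 2:
        raise ValueError("run_dd requires a 2D gridded field")
    n = offsets.shape[0]
    if n * n > config.dd_max_cells:
        raise MemoryError(
            f"magnetization grid {n}x{n} exceeds the configured ceiling of "
            f"{config.dd_max_cells} cells; lower the grid size or raise "
            f"config.dd_max_cells")
    dt = config.timestep
    refocus_at = config.te_spin_echo / 2.0 / dt
    if spin_echo and abs(refocus_at - round(refocus_at)) > 1e-9:
        raise ValueError("TE_SE/2 must be an integer multiple of dt")
    refocus_idx = int(round(refocus_at))
    spacing = network.voxel.edge_length / n
    kernel = build_diffusion_kernel(config.sigma2, spacing)
    iv_mask = voxelize_mask(network, n)
    grid = MagnetizationGrid(m=np.ones((n, n), dtype=complex),
                             iv_mask=iv_mask, spacing=spacing)
    phasor = np.exp(-1j * GAMMA * offsets * (dt * 1e-3))
    n_steps = config.n_steps
    times = np.arange(n_steps) * dt
    s_tot = np.empty(n_steps, dtype=complex)
    s_ev = np.empty(n_steps, dtype=complex)
    s_iv = np.empty(n_steps, dtype=complex)
    s_tot[0], s_ev[0], s_iv[0] = _signals(grid)
    for j in range(1, n_steps):
        dd_step(grid, phasor, kernel)
        s_tot[j], s_ev[j], s_iv[j] = _signals(grid)
        if spin_echo and j == refocus_idx:
            grid.m = np.conj(grid.m)
    echoes = {"GE": config.te_gradient_echo}
    if spin_echo:
        echoes["SE"] = config.te_spin_echo
    return SignalTimecourse(times=times, s_tot=s_tot, s_ev=s_ev, s_iv=s_iv,
                            n_ev=grid.n_ev, n_iv=grid.n_iv, echoes=echoes)
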
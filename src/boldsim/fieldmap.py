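"""Susceptibility-induced B0 offset fields.

Three solvers are provided.  The analytic solver sums, over all vessels, the
classic infinite-cylinder dipole field

    dB(r >= R) = (1/2) * dchi * B0 * (R/r)^2 * sin^2(theta) * cos(2*phi)
    dB(r <  R) = (1/6) * dchi * B0 * (3*cos^2(theta) - 1)

where r is the perpendicular distance to the vessel axis, theta the angle
between B0 and the axis, and phi the in-plane angle between the projection
of B0 and the displacement from the axis.  It can be evaluated continuously
at arbitrary points or sampled on a cell-centred grid.  The Fourier solver
convolves a discretized susceptibility map with the point-dipole kernel
(expressed directly in k space as (1/3 - kz^2/|k|^2) * B0, with the k=0
element set to zero) by cyclic FFT multiplication, which handles arbitrary
vessel masks such as VANs.  The three-B0 solver implements the 2D
orientation-averaging shortcut: the field is the weighted sum of 1/3 the
vessel-parallel and 2/3 a single vessel-perpendicular B0 orientation, which
makes the intravascular self-offset of every vessel exactly zero (the
dipole is trace-free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .config import SimulationConfig
from .geometry import Cylinder, VesselNetwork, Z_AXIS, grid_centers_1d, \
    spherical_to_unit

X_AXIS = np.array([1.0, 0.0, 0.0])


def _resolve_b_direction(cylinder: Cylinder,
                         b0_direction: np.ndarray | None) -> np.ndarray:
    if b0_direction is not None:
        return np.asarray(b0_direction, dtype=float)
    if cylinder.theta_b is not None:
        return spherical_to_unit(cylinder.theta_b, cylinder.phi_b or 0.0)
    return Z_AXIS


def cylinder_offset(point, cylinder: Cylinder, delta_chi: float, b0: float,
                    b0_direction: np.ndarray | None = None) -> float:
    """Field offset (T) of a single infinite cylinder at one point.

    The B0 direction is, in order of precedence: the explicit
    ``b0_direction``, the cylinder's own (theta_b, phi_b) angles (2D
    per-vessel-B0 mode), or the global +z axis (3D).  Points on the axis
    fall in the interior branch.
    """
    p = np.zeros(3)
    p[:len(np.atleast_1d(point))] = np.atleast_1d(point)
    b = _resolve_b_direction(cylinder, b0_direction)
    n = cylinder.axis
    d = p - cylinder.anchor
    rvec = d - np.dot(d, n) * n
    r2 = float(np.dot(rvec, rvec))
    cos_t = float(np.dot(b, n))
    if r2 <= cylinder.radius ** 2:
        return delta_chi * b0 / 6.0 * (3.0 * cos_t ** 2 - 1.0)
    bperp = b - cos_t * n
    norm = np.linalg.norm(bperp)
    if norm < 1e-12:
        return 0.0                      # sin^2(theta) = 0
    cos_phi = float(np.dot(bperp / norm, rvec)) / np.sqrt(r2)
    cos_2phi = 2.0 * cos_phi ** 2 - 1.0
    sin2_t = 1.0 - cos_t ** 2
    return 0.5 * delta_chi * b0 * (cylinder.radius ** 2 / r2) * sin2_t * cos_2phi


# ---------------------------------------------------------------------------
# evaluators
# ---------------------------------------------------------------------------

@dataclass
class ContinuousField:
    """Analytic summed-cylinder field, evaluable at arbitrary points.

    ``periods`` holds per-axis minimum-image wrap lengths (0 = no wrap); 2D
    networks wrap in-plane so spins near an edge feel the vessels of the
    adjacent periodic images, while 3D networks rely on the generator's
    out-of-voxel cylinders for the surround.
    """

    anchors: np.ndarray
    axes: np.ndarray
    radii2: np.ndarray
    icoef: np.ndarray
    ecoef: np.ndarray
    bperp: np.ndarray
    periods: np.ndarray
    mode: str

    def at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] == 2:
            pts = np.column_stack([pts, np.zeros(len(pts))])
        pts = np.ascontiguousarray(pts)
        out = np.empty(len(pts))
        if np.any(self.periods > 0):
            _kernels.sum_cylinder_offsets_wrapped(
                pts, self.anchors, self.axes, self.radii2, self.icoef,
                self.ecoef, self.bperp, self.periods, out)
        else:
            _kernels.sum_cylinder_offsets(
                pts, self.anchors, self.axes, self.radii2, self.icoef,
                self.ecoef, self.bperp, out)
        return out

    def at_with_inside(self, points: np.ndarray):
        """Offsets plus the intravascular flag, in one pass over vessels."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] == 2:
            pts = np.column_stack([pts, np.zeros(len(pts))])
        pts = np.ascontiguousarray(pts)
        out = np.empty(len(pts))
        inside = np.empty(len(pts), dtype=np.bool_)
        _kernels.offsets_and_inside(pts, self.anchors, self.axes, self.radii2,
                                    self.icoef, self.ecoef, self.bperp,
                                    self.periods, out, inside)
        return out, inside


def _per_vessel_coefficients(axes: np.ndarray, bvecs: np.ndarray,
                             delta_chi: float, b0: float):
    cos_t = np.einsum("ij,ij->i", bvecs, axes)
    icoef = delta_chi * b0 / 6.0 * (3.0 * cos_t ** 2 - 1.0)
    bperp = bvecs - cos_t[:, None] * axes
    norms = np.linalg.norm(bperp, axis=1)
    ecoef = 0.5 * delta_chi * b0 * (1.0 - cos_t ** 2)
    degenerate = norms < 1e-12
    ecoef[degenerate] = 0.0
    norms[degenerate] = 1.0
    return icoef, ecoef, bperp / norms[:, None]


def analytic_field(network: VesselNetwork, config: SimulationConfig,
                   mode: str | None = None,
                   wrap: bool | None = None) -> ContinuousField:
    """Build the continuous analytic field evaluator for a cylinder network.

    mode: 'global_z' (3D: B0 along +z), 'per_vessel' (each vessel's stored
    B0 angles) or 'three_b0' (orientation-averaged 2D rule).  By default 3D
    networks use 'global_z' and 2D networks 'per_vessel'.
    """
    anchors, axes, radii = network.cylinder_arrays()
    dim = network.voxel.dimensionality
    if mode is None:
        mode = "global_z" if dim == 3 else "per_vessel"
    if mode == "global_z":
        bvecs = np.tile(Z_AXIS, (len(radii), 1))
        icoef, ecoef, bperp = _per_vessel_coefficients(
            axes, bvecs, config.delta_chi, config.b0)
    elif mode == "per_vessel":
        if any(v.theta_b is None for v in network.vessels):
            raise ValueError("per_vessel mode requires per-vessel B0 angles")
        bvecs = np.array([spherical_to_unit(v.theta_b, v.phi_b or 0.0)
                          for v in network.vessels])
        icoef, ecoef, bperp = _per_vessel_coefficients(
            axes, bvecs, config.delta_chi, config.b0)
    elif mode == "three_b0":
        if dim != 2 or not np.allclose(axes, Z_AXIS):
            raise ValueError("three_b0 mode requires a 2D network with all "
                             "vessels perpendicular to the plane")
        # 1/3 parallel: interior dchi*B0/3, exterior 0.
        # 2/3 perpendicular (B0 along +x): interior -dchi*B0/6, exterior
        # (1/2) dchi*B0 (R/r)^2 cos(2*phi_x).  The interior terms cancel.
        n = len(radii)
        icoef = np.zeros(n)
        ecoef = np.full(n, (2.0 / 3.0) * 0.5 * config.delta_chi * config.b0)
        bperp = np.tile(X_AXIS, (n, 1))
    else:
        raise ValueError(f"unknown field mode {mode!r}")
    if wrap is None:
        wrap = dim == 2
    L = network.voxel.edge_length
    periods = np.array([L, L, 0.0]) if (wrap and dim == 2) else (
        np.full(3, float(L)) if wrap else np.zeros(3))
    return ContinuousField(anchors=np.ascontiguousarray(anchors),
                           axes=np.ascontiguousarray(axes),
                           radii2=radii ** 2, icoef=icoef, ecoef=ecoef,
                           bperp=np.ascontiguousarray(bperp),
                           periods=periods, mode=mode)


def field_at_point(network: VesselNetwork, point, config: SimulationConfig,
                   mode: str | None = None,
                   wrap: bool | None = None) -> float:
    """Summed analytic offset (T) at a single point."""
    if network.n_vessels == 0:
        return 0.0
    return float(analytic_field(network, config, mode, wrap).at(point)[0])


@dataclass
class GriddedFieldMap:
    """A discretized offset field (T) on a cell-centred grid."""

    offsets: np.ndarray          # (n, n) or (n, n, n), T
    edge_length: float           # um
    b0: float                    # T

    @property
    def spacing(self) -> float:
        return self.edge_length / self.offsets.shape[0]

    def at(self, points: np.ndarray) -> np.ndarray:
        """Nearest-neighbour lookup for spin positions in the voxel."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = self.offsets.shape[0]
        idx = np.floor((pts + self.edge_length / 2) / self.spacing).astype(int)
        idx = np.clip(idx, 0, n - 1)
        if self.offsets.ndim == 2:
            return self.offsets[idx[:, 0], idx[:, 1]]
        return self.offsets[idx[:, 0], idx[:, 1], idx[:, 2]]


def field_on_grid_analytic(network: VesselNetwork, grid_points_per_side: int,
                           config: SimulationConfig, mode: str | None = None,
                           wrap: bool | None = None) -> GriddedFieldMap:
    """Sample the analytic summed field at every grid-cell centre."""
    if grid_points_per_side < 2:
        raise ValueError("grid_points_per_side must be >= 2")
    n = grid_points_per_side
    L = network.voxel.edge_length
    c = grid_centers_1d(L, n)
    ev = analytic_field(network, config, mode, wrap)
    if network.voxel.dimensionality == 2:
        xx, yy = np.meshgrid(c, c, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        offsets = ev.at(pts).reshape(n, n)
    else:
        offsets = np.empty((n, n, n))
        xx, yy = np.meshgrid(c, c, indexing="ij")
        for iz in range(n):
            pts = np.column_stack([xx.ravel(), yy.ravel(),
                                   np.full(xx.size, c[iz])])
            offsets[:, :, iz] = ev.at(pts).reshape(n, n)
    return GriddedFieldMap(offsets=offsets, edge_length=L, b0=config.b0)


def three_b0_field(network: VesselNetwork, target,
                   config: SimulationConfig):
    """Orientation-averaged (3B0) field at a point or on a grid.

    ``target`` is either a point (offset in T returned) or an integer grid
    size (a :class:`GriddedFieldMap` returned).
    """
    if isinstance(target, (int, np.integer)):
        return field_on_grid_analytic(network, int(target), config,
                                      mode="three_b0")
    return field_at_point(network, target, config, mode="three_b0")


# ---------------------------------------------------------------------------
# Fourier solver
# ---------------------------------------------------------------------------

def dipole_kernel_k(shape: tuple[int, ...], spacing: float,
                    b0: float = 1.0) -> np.ndarray:
    """Point-dipole field kernel in k space, (1/3 - kz^2/|k|^2) * B0.

    Built directly at the discrete frequencies of the unpadded grid (z is
    the B0 axis); the k=0 element is set to zero, the zero-mean-field
    convention, which also avoids the r=0 singularity of the spatial dipole.
    """
    if len(shape) != 3:
        raise ValueError("dipole kernel is defined for 3D grids")
    ks = [np.fft.fftfreq(n, d=spacing) for n in shape]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij")
    k2 = kx ** 2 + ky ** 2 + kz ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = (1.0 / 3.0 - kz ** 2 / k2) * b0
    kernel[0, 0, 0] = 0.0
    return kernel


def field_fft(mask: np.ndarray, edge_length: float, delta_chi: float,
              b0: float) -> GriddedFieldMap:
    """Offset field of a susceptibility mask by cyclic k-space convolution.

    The susceptibility map is delta_chi inside the mask and zero outside;
    the convolution is circular (the voxel is effectively surrounded by
    copies of itself, matching the cyclic boundary of the diffusion
    engines).  The imaginary residual of the inverse transform is checked
    against 1e-10 of the field amplitude and discarded.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("field_fft requires a 3D mask")
    spacing = edge_length / mask.shape[0]
    kernel = dipole_kernel_k(mask.shape, spacing, b0)
    chi_k = np.fft.fftn(delta_chi * mask.astype(float))
    field = np.fft.ifftn(chi_k * kernel)
    scale = np.max(np.abs(field)) or 1.0
    if np.max(np.abs(field.imag)) > 1e-10 * scale:
        raise FloatingPointError("imaginary residual of the FFT field "
                                 "exceeds tolerance")
    return GriddedFieldMap(offsets=field.real, edge_length=edge_length,
                           b0=b0)


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def histogram_ppb(offsets: np.ndarray, b0: float, bin_width: float = 1.0,
                  limit: float = 300.0):
    """Unit-area histogram of offsets expressed in ppb of B0.

    Returns (bin_centers_ppb, density); density integrates to the fraction
    of samples within +-limit ppb (all of them for typical networks).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rel = np.asarray(offsets).ravel() / b0 * 1e9
    edges = np.arange(-limit, limit + bin_width, bin_width)
    counts, edges = np.histogram(rel, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (rel.size * bin_width)
    return centers, density


def field_histogram(field: GriddedFieldMap, mask: np.ndarray,
                    bin_width: float = 1.0, limit: float = 300.0) -> dict:
    """Per-compartment (total / EV / IV) unit-area histograms in ppb of B0."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.offsets.shape:
        raise ValueError("mask and field grids are not congruent")
    out = {}
    for name, values in (("total", field.offsets),
                         ("ev", field.offsets[~mask]),
                         ("iv", field.offsets[mask])):
        out[name] = histogram_ppb(values, field.b0, bin_width, limit)
    return out


def average_histograms(histograms: list[dict]) -> dict:
    """Across-voxel mean and standard deviation of per-compartment histograms."""
    out = {}
    for name in ("total", "ev", "iv"):
        centers = histograms[0][name][0]
        stack = np.stack([h[name][1] for h in histograms])
        out[name] = (centers, stack.mean(axis=0), stack.std(axis=0, ddof=0))
    return out


def histogram_mode_ppb(centers: np.ndarray, density: np.ndarray) -> float:
    """Bin centre of the histogram peak."""
    return float(centers[np.argmax(density)])
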
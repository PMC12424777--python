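"""Vascular geometry: voxels, cylinder/segment networks, masks and file IO.

Two families of vessel geometry are supported.  Infinite cylinders are the
classic construction: in 3D they are isotropically oriented lines filling a
cubic voxel to a target blood volume fraction; in 2D they appear as circles
in a square voxel with every vessel perpendicular to the plane.  The second
family is a simplified vascular-anatomical-network (VAN) stand-in: a bed of
tortuous chains of finite, non-overlapping segments of a single radius grown
by a correlated random walk.

Coordinates are in micrometres with the voxel centred on the origin.  2D
geometry lives in the z=0 plane (circle centres have z=0 and the shared
cylinder axis is +z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels

Z_AXIS = np.array([0.0, 0.0, 1.0])


class NetworkFileError(ValueError):
    """Raised when a vessel-network file fails validation."""


@dataclass
class Voxel:
    dimensionality: int
    edge_length: float                       # um
    grid_points_per_side: int | None = None

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")
        if self.grid_points_per_side is not None and \
                self.grid_points_per_side < 2:
            raise ValueError("grid_points_per_side must be >= 2")

    @property
    def volume(self) -> float:
        return self.edge_length ** self.dimensionality


@dataclass
class Cylinder:
    """An infinite cylinder (a circle when the network is 2D).

    ``theta_b``/``phi_b`` are the polar/azimuthal angles of this vessel's own
    B0 direction, used by the 2D modes where the vessel axis is fixed
    out-of-plane and the field direction varies per vessel.  They are None
    for 3D networks, where B0 is the global +z axis.
    """

    anchor: np.ndarray          # (3,) point on the axis, um
    axis: np.ndarray            # (3,) unit vector
    radius: float               # um
    theta_b: float | None = None   # rad, in [0, pi]
    phi_b: float | None = None     # rad, in [0, 2*pi)

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.theta_b is not None and not 0 <= self.theta_b <= np.pi:
            raise ValueError("theta_b must lie in [0, pi]")


@dataclass
class VanSegment:
    """A finite vessel segment of a VAN, with graph connectivity."""

    endpoint_a: np.ndarray
    endpoint_b: np.ndarray
    radius: float
    node_a: int = -1
    node_b: int = -1

    def __post_init__(self) -> None:
        self.endpoint_a = np.asarray(self.endpoint_a, dtype=float)
        self.endpoint_b = np.asarray(self.endpoint_b, dtype=float)
        if np.allclose(self.endpoint_a, self.endpoint_b):
            raise ValueError("segment endpoints must be distinct")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.endpoint_b - self.endpoint_a))


@dataclass
class VesselNetwork:
    voxel: Voxel
    vessels: list = field(default_factory=list)
    blood_volume_fraction: float = 0.0   # achieved in-voxel fraction
    base_radius: float = 1.0             # um, reference radius of this build

    def __post_init__(self) -> None:
        if self.vessels:
            if not 0 < self.blood_volume_fraction < 1:
                raise ValueError("blood_volume_fraction must lie in (0, 1)")
        elif self.blood_volume_fraction != 0:
            raise ValueError("an empty network has zero volume fraction")

    @property
    def kind(self) -> str:
        if self.vessels and isinstance(self.vessels[0], VanSegment):
            return "segments"
        return "cylinders"

    @property
    def n_vessels(self) -> int:
        return len(self.vessels)

    def label_periods(self) -> np.ndarray:
        """Per-axis minimum-image periods used for compartment tests.

        2D networks are treated as periodic in-plane (a circle protruding
        through one edge re-enters from the opposite edge, consistent with
        the cyclic boundary applied to diffusing spins).  3D cylinder
        networks are not wrapped: the generator retains vessels beyond the
        voxel which already provide the surround, and VAN segments are
        contained in the voxel.
        """
        L = self.voxel.edge_length
        if self.voxel.dimensionality == 2:
            return np.array([L, L, 0.0])
        return np.zeros(3)

    # -- array views used by the compiled kernels --------------------------

    def cylinder_arrays(self):
        if self.kind != "cylinders":
            raise ValueError("network does not hold cylinders")
        anchors = np.array([c.anchor for c in self.vessels], dtype=float)
        axes = np.array([c.axis for c in self.vessels], dtype=float)
        radii = np.array([c.radius for c in self.vessels], dtype=float)
        return anchors, axes, radii

    def invoxel_cylinder_arrays(self):
        """Cylinder arrays restricted to vessels that can reach the voxel.

        3D generation retains cylinders whose axes miss the cube (they
        supply the surround field); for compartment tests and masks only
        cylinders whose inflated (edge + 2R) cube chord is nonzero can
        contain an in-voxel point, so the rest are filtered out once.
        """
        cached = getattr(self, "_invoxel_arrays", None)
        if cached is None:
            anchors, axes, radii = self.cylinder_arrays()
            if self.voxel.dimensionality == 3:
                keep = np.array([
                    chord_length_in_cube(
                        a, x, self.voxel.edge_length + 2 * r) > 0.0
                    for a, x, r in zip(anchors, axes, radii)])
                cached = anchors[keep], axes[keep], radii[keep]
            else:
                cached = anchors, axes, radii
            self._invoxel_arrays = cached
        return cached

    def segment_arrays(self):
        if self.kind != "segments":
            raise ValueError("network does not hold segments")
        a = np.array([s.endpoint_a for s in self.vessels], dtype=float)
        b = np.array([s.endpoint_b for s in self.vessels], dtype=float)
        radii = np.array([s.radius for s in self.vessels], dtype=float)
        return a, b, radii


# ---------------------------------------------------------------------------
# sampling and generation
# ---------------------------------------------------------------------------

def sample_orientation(rng: np.random.Generator) -> tuple[float, float]:
    """Draw an isotropic orientation: theta = acos(2u-1), phi ~ U[0, 2pi).

    The inverse-CDF construction makes cos(theta) uniform on [-1, 1], the
    area-uniform distribution on the sphere.
    """
    theta = float(np.arccos(2.0 * rng.random() - 1.0))
    phi = float(rng.random() * 2.0 * np.pi)
    return theta, phi


def spherical_to_unit(theta: float, phi: float) -> np.ndarray:
    return np.array([np.sin(theta) * np.cos(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(theta)])


def _orthonormal_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def chord_length_in_cube(point: np.ndarray, direction: np.ndarray,
                         edge_length: float) -> float:
    """Length of the intersection of the line point + t*direction with the
    cube [-L/2, L/2]^3 (slab clipping)."""
    half = edge_length / 2.0
    t0, t1 = -np.inf, np.inf
    for i in range(3):
        d = direction[i]
        if abs(d) < 1e-12:
            if abs(point[i]) > half:
                return 0.0
        else:
            a = (-half - point[i]) / d
            b = (half - point[i]) / d
            if a > b:
                a, b = b, a
            t0 = max(t0, a)
            t1 = min(t1, b)
    return max(0.0, t1 - t0)


def generate_network_3d(edge_length: float, radius: float,
                        target_fraction: float,
                        rng: np.random.Generator) -> VesselNetwork:
    """Fill a cubic voxel with isotropically oriented infinite cylinders.

    Orientations follow the sin(theta) distribution; for each cylinder a
    point its axis passes through is drawn uniformly on the square of
    half-width L*sqrt(3)/2 on the plane orthogonal to the axis through the
    voxel origin, which yields a uniform density of lines over the voxel.
    All candidates are retained — cylinders whose axes miss the cube still
    contribute extravascular field to spins near the faces, playing the role
    of the surrounding vasculature — and cylinders are added until the
    in-voxel volume (exact cube-chord length times pi*R^2) reaches the
    target fraction.  At the standard operating point (149 um edge, 1 um
    radius, 2%) this yields approximately 400 vessels per voxel.
    """
    if not 0 < target_fraction < 0.5:
        raise ValueError("target_fraction must lie in (0, 0.5)")
    if edge_length <= 0 or radius <= 0:
        raise ValueError("edge_length and radius must be positive")
    half_width = edge_length * np.sqrt(3.0) / 2.0
    target_volume = target_fraction * edge_length ** 3
    area = np.pi * radius ** 2
    vessels: list[Cylinder] = []
    volume = 0.0
    stalled = 0
    while volume < target_volume:
        theta, phi = sample_orientation(rng)
        n = spherical_to_unit(theta, phi)
        e1, e2 = _orthonormal_basis(n)
        u = rng.uniform(-half_width, half_width)
        v = rng.uniform(-half_width, half_width)
        point = u * e1 + v * e2
        chord = chord_length_in_cube(point, n, edge_length)
        vessels.append(Cylinder(anchor=point, axis=n, radius=radius))
        if chord > 0.0:
            volume += area * chord
            stalled = 0
        else:
            stalled += 1
            if stalled > 100_000:
                raise RuntimeError(
                    "3D network generation stalled: no candidate cylinder "
                    "intersected the voxel after 100000 consecutive draws; "
                    "check edge_length/radius/target_fraction")
    voxel = Voxel(3, edge_length)
    return VesselNetwork(voxel=voxel, vessels=vessels,
                         blood_volume_fraction=volume / edge_length ** 3,
                         base_radius=radius)


def generate_network_2d(edge_length: float, radius: float,
                        target_fraction: float, rng: np.random.Generator,
                        field_mode: str = "per_vessel_random_B0",
                        ) -> VesselNetwork:
    """Populate a square voxel with parallel vessels (circles in-plane).

    The count is the smallest N with N*pi*R^2/L^2 >= target_fraction; centres
    are uniform over the square.  In ``per_vessel_random_B0`` mode each
    circle receives its own B0 direction drawn from the isotropic
    distribution (the construction that reproduces the 3D field-offset
    statistics in 2D); in ``three_B0`` mode no per-vessel angles are stored
    and the field solver applies the orientation-averaged (1/3 parallel +
    2/3 perpendicular) rule instead.
    """
    if field_mode not in ("per_vessel_random_B0", "three_B0"):
        raise ValueError(f"unknown field_mode {field_mode!r}")
    if edge_length <= 0 or radius <= 0 or target_fraction <= 0:
        raise ValueError("inputs must be positive")
    area_frac = np.pi * radius ** 2 / edge_length ** 2
    n = int(np.ceil(target_fraction / area_frac))
    vessels = []
    for _ in range(n):
        cx, cy = rng.uniform(-edge_length / 2, edge_length / 2, size=2)
        if field_mode == "per_vessel_random_B0":
            theta_b, phi_b = sample_orientation(rng)
        else:
            theta_b = phi_b = None
        vessels.append(Cylinder(anchor=np.array([cx, cy, 0.0]),
                                axis=Z_AXIS.copy(), radius=radius,
                                theta_b=theta_b, phi_b=phi_b))
    voxel = Voxel(2, edge_length)
    return VesselNetwork(voxel=voxel, vessels=vessels,
                         blood_volume_fraction=n * area_frac,
                         base_radius=radius)


def single_vessel_network(edge_length: float, radius: float,
                          theta: float) -> VesselNetwork:
    """One vessel at the centre of a 2D voxel with B0 at polar angle theta.

    theta (radians) is the angle between B0 and the out-of-plane vessel
    axis; theta = pi/2 puts B0 in-plane, the maximal-dephasing orientation.
    """
    if not 0 < theta <= np.pi / 2:
        raise ValueError("theta must lie in (0, pi/2]")
    vessel = Cylinder(anchor=np.zeros(3), axis=Z_AXIS.copy(), radius=radius,
                      theta_b=float(theta), phi_b=0.0)
    voxel = Voxel(2, edge_length)
    zeta = np.pi * radius ** 2 / edge_length ** 2
    return VesselNetwork(voxel=voxel, vessels=[vessel],
                         blood_volume_fraction=zeta, base_radius=radius)


def scale_network_for_radius(network: VesselNetwork,
                             new_radius: float) -> VesselNetwork:
    """Rescale a base network to a new vessel radius.

    Every length (coordinates, radii, voxel edge) is multiplied by
    new_radius / base_radius, so the vessel arrangement — and hence the
    blood volume fraction — is preserved exactly while the physical scale
    changes.  This is how one set of random voxels serves the whole radius
    sweep.
    """
    if new_radius <= 0:
        raise ValueError("new_radius must be positive")
    f = new_radius / network.base_radius
    voxel = Voxel(network.voxel.dimensionality,
                  network.voxel.edge_length * f,
                  network.voxel.grid_points_per_side)
    vessels = []
    for v in network.vessels:
        if isinstance(v, Cylinder):
            vessels.append(Cylinder(anchor=v.anchor * f, axis=v.axis.copy(),
                                    radius=v.radius * f, theta_b=v.theta_b,
                                    phi_b=v.phi_b))
        else:
            vessels.append(VanSegment(endpoint_a=v.endpoint_a * f,
                                      endpoint_b=v.endpoint_b * f,
                                      radius=v.radius * f,
                                      node_a=v.node_a, node_b=v.node_b))
    return VesselNetwork(voxel=voxel, vessels=vessels,
                         blood_volume_fraction=network.blood_volume_fraction,
                         base_radius=network.base_radius * f)


def synthesize_simple_van(edge_length: float, radius: float,
                          target_fraction: float, segment_density: float,
                          rng: np.random.Generator,
                          persistence: float = 4.0) -> VesselNetwork:
    """Grow a simplified capillary bed of tortuous, non-overlapping chains.

    This is a stand-in for full anatomical VAN synthesis: chains of finite
    segments of one fixed radius are grown by a correlated random walk whose
    stiffness (``persistence``) controls tortuosity; occasional chains start
    from existing nodes, creating junctions.  Segment length is chosen so
    that ``segment_density`` (segments per mm^3) and ``target_fraction`` are
    reached together; growth stops when the accumulated vessel volume
    reaches the target.  Candidate segments overlapping an existing vessel
    (closer than one diameter, parent segment excluded) are rejected.
    """
    if segment_density <= 0:
        raise ValueError("segment_density must be positive (segments per mm^3)")
    if not 0 < target_fraction < 0.5:
        raise ValueError("target_fraction must lie in (0, 0.5)")
    volume_um3 = edge_length ** 3
    n_target = max(1, int(round(segment_density * volume_um3 * 1e-9)))
    seg_len = target_fraction * volume_um3 / (n_target * np.pi * radius ** 2)
    lo, hi = -edge_length / 2 + radius, edge_length / 2 - radius
    if hi <= lo or seg_len <= 2 * radius:
        raise ValueError("voxel too small for the requested VAN parameters")

    segments: list[VanSegment] = []
    nodes: list[np.ndarray] = []
    incident: list[list[int]] = []       # node index -> incident segments
    target_volume = target_fraction * volume_um3
    seg_volume = np.pi * radius ** 2 * seg_len
    volume = 0.0
    global_stall = 0

    def clear_of_others(p_new: np.ndarray, p_old: np.ndarray,
                        skip: set[int]) -> bool:
        keep = [i for i in range(len(segments)) if i not in skip]
        if not keep:
            return True
        a = np.array([segments[i].endpoint_a for i in keep])
        b = np.array([segments[i].endpoint_b for i in keep])
        for frac in (0.34, 0.67, 1.0):
            probe = p_old + frac * (p_new - p_old)
            if _kernels.min_distance_to_segments(probe, a, b) < 2 * radius:
                return False
        return True

    def fresh_start():
        for _ in range(200):
            p = rng.uniform(lo, hi, size=3)
            if clear_of_others(p, p, set()):
                return p
        return None

    while volume < target_volume:
        # start a chain from an existing node (a junction) or a fresh point
        if nodes and rng.random() < 0.15:
            start_idx = int(rng.integers(len(nodes)))
            start = nodes[start_idx]
            skip = set(incident[start_idx])
        else:
            start = fresh_start()
            if start is None:
                global_stall += 1
                if global_stall > 200:
                    raise RuntimeError(
                        "VAN growth stalled: could not place a "
                        "non-overlapping segment after 200 consecutive "
                        "chain attempts")
                continue
            nodes.append(start)
            incident.append([])
            start_idx = len(nodes) - 1
            skip = set()
        theta, phi = sample_orientation(rng)
        direction = spherical_to_unit(theta, phi)
        head, head_idx = start, start_idx
        chain_len = int(rng.integers(4, 12))
        grew = False
        for _ in range(chain_len):
            placed = False
            for _try in range(50):
                step_dir = persistence * direction + rng.standard_normal(3)
                step_dir /= np.linalg.norm(step_dir)
                tip = head + seg_len * step_dir
                if np.any(tip < lo) or np.any(tip > hi):
                    # steer back toward the interior
                    direction = -head / (np.linalg.norm(head) + 1e-12)
                    continue
                if clear_of_others(tip, head, skip):
                    placed = True
                    break
            if not placed:
                break
            nodes.append(tip)
            incident.append([])
            seg_idx = len(segments)
            segments.append(VanSegment(endpoint_a=head.copy(),
                                       endpoint_b=tip.copy(),
                                       radius=radius, node_a=head_idx,
                                       node_b=len(nodes) - 1))
            incident[head_idx].append(seg_idx)
            incident[-1].append(seg_idx)
            skip = {seg_idx}
            head, head_idx = tip, len(nodes) - 1
            direction = step_dir
            volume += seg_volume
            grew = True
            if volume >= target_volume:
                break
        if grew:
            global_stall = 0
        else:
            global_stall += 1
            if global_stall > 200:
                raise RuntimeError(
                    "VAN growth stalled: could not place a non-overlapping "
                    "segment after 200 consecutive chain attempts")
    voxel = Voxel(3, edge_length)
    return VesselNetwork(voxel=voxel, vessels=segments,
                         blood_volume_fraction=volume / volume_um3,
                         base_radius=radius)


# ---------------------------------------------------------------------------
# masks and compartment labels
# ---------------------------------------------------------------------------

def grid_centers_1d(edge_length: float, n: int) -> np.ndarray:
    """Cell-centred coordinates of an n-point grid spanning [-L/2, L/2]."""
    spacing = edge_length / n
    return -edge_length / 2 + (np.arange(n) + 0.5) * spacing


def label_points(network: VesselNetwork, points: np.ndarray) -> np.ndarray:
    """Boolean intravascular label for an (N, 3) or (N, 2) point array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    out = np.empty(len(pts), dtype=np.bool_)
    if network.kind == "cylinders":
        anchors, axes, radii = network.invoxel_cylinder_arrays()
        if len(radii) == 0:
            return np.zeros(len(pts), dtype=bool)
        _kernels.inside_any_cylinder(pts, anchors, axes, radii ** 2,
                                     network.label_periods(), out)
    else:
        a, b, radii = network.segment_arrays()
        _kernels.inside_any_segment(pts, a, b, radii ** 2, out)
    return out


def point_compartment(network: VesselNetwork, point) -> str:
    """'IV' if the point lies inside any vessel, else 'EV'."""
    return "IV" if bool(label_points(network, np.asarray(point))[0]) else "EV"


def voxelize_mask(network: VesselNetwork,
                  grid_points_per_side: int) -> np.ndarray:
    """Boolean vessel mask on a cell-centred grid (True = intravascular).

    A grid element is intravascular iff its centre lies within a vessel
    (perpendicular distance to a cylinder axis <= R, or distance to a
    segment <= R).  Returns (n, n) for 2D networks and (n, n, n) for 3D,
    indexed [ix, iy(, iz)].
    """
    if grid_points_per_side < 2:
        raise ValueError("grid_points_per_side must be >= 2")
    n = grid_points_per_side
    c = grid_centers_1d(network.voxel.edge_length, n)
    if network.voxel.dimensionality == 2:
        xx, yy = np.meshgrid(c, c, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(),
                               np.zeros(xx.size)])
        return label_points(network, pts).reshape(n, n)
    mask = np.empty((n, n, n), dtype=np.bool_)
    xx, yy = np.meshgrid(c, c, indexing="ij")
    for iz in range(n):        # slice-wise to bound memory
        pts = np.column_stack([xx.ravel(), yy.ravel(),
                               np.full(xx.size, c[iz])])
        mask[:, :, iz] = label_points(network, pts).reshape(n, n)
    return mask


def monte_carlo_volume_fraction(network: VesselNetwork, n_points: int,
                                rng: np.random.Generator) -> float:
    """Hit-count estimate of the intravascular volume fraction (test oracle)."""
    L = network.voxel.edge_length
    dim = network.voxel.dimensionality
    pts = rng.uniform(-L / 2, L / 2, size=(n_points, dim))
    return float(np.mean(label_points(network, pts)))


# ---------------------------------------------------------------------------
# file round-trip
# ---------------------------------------------------------------------------

_CYL_COLS = ["anchor_x", "anchor_y", "anchor_z", "axis_x", "axis_y", "axis_z",
             "radius", "theta_b", "phi_b"]
_SEG_COLS = ["x0", "y0", "z0", "x1", "y1", "z1", "radius", "node_a", "node_b"]


def write_vessel_network(network: VesselNetwork, path: str | Path) -> None:
    """Write a network as CSV records plus a JSON sidecar with voxel metadata."""
    path = Path(path)
    if network.kind == "cylinders":
        rows = [[*c.anchor, *c.axis, c.radius,
                 np.nan if c.theta_b is None else c.theta_b,
                 np.nan if c.phi_b is None else c.phi_b]
                for c in network.vessels]
        df = pd.DataFrame(rows, columns=_CYL_COLS)
    else:
        rows = [[*s.endpoint_a, *s.endpoint_b, s.radius, s.node_a, s.node_b]
                for s in network.vessels]
        df = pd.DataFrame(rows, columns=_SEG_COLS)
    df.to_csv(path, index=False)
    meta = {
        "kind": network.kind,
        "dimensionality": network.voxel.dimensionality,
        "edge_length": network.voxel.edge_length,
        "grid_points_per_side": network.voxel.grid_points_per_side,
        "blood_volume_fraction": network.blood_volume_fraction,
        "base_radius": network.base_radius,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_vessel_network(path: str | Path) -> VesselNetwork:
    """Read a network written by :func:`write_vessel_network`.

    Malformed records raise :class:`NetworkFileError` naming the offending
    row.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise NetworkFileError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    expected = _CYL_COLS if meta["kind"] == "cylinders" else _SEG_COLS
    if list(df.columns) != expected:
        raise NetworkFileError(
            f"{path}: expected columns {expected}, found {list(df.columns)}")
    vessels = []
    for i, row in df.iterrows():
        if not row["radius"] > 0:
            raise NetworkFileError(f"{path}: record {i}: radius must be "
                                   f"positive, got {row['radius']}")
        try:
            if meta["kind"] == "cylinders":
                theta_b = None if np.isnan(row["theta_b"]) else row["theta_b"]
                phi_b = None if np.isnan(row["phi_b"]) else row["phi_b"]
                vessels.append(Cylinder(
                    anchor=row[["anchor_x", "anchor_y", "anchor_z"]].to_numpy(float),
                    axis=row[["axis_x", "axis_y", "axis_z"]].to_numpy(float),
                    radius=float(row["radius"]), theta_b=theta_b, phi_b=phi_b))
            else:
                vessels.append(VanSegment(
                    endpoint_a=row[["x0", "y0", "z0"]].to_numpy(float),
                    endpoint_b=row[["x1", "y1", "z1"]].to_numpy(float),
                    radius=float(row["radius"]),
                    node_a=int(row["node_a"]), node_b=int(row["node_b"])))
        except ValueError as exc:
            raise NetworkFileError(f"{path}: record {i}: {exc}") from exc
    voxel = Voxel(meta["dimensionality"], meta["edge_length"],
                  meta["grid_points_per_side"])
    return VesselNetwork(voxel=voxel, vessels=vessels,
                         blood_volume_fraction=meta["blood_volume_fraction"],
                         base_radius=meta["base_radius"])
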
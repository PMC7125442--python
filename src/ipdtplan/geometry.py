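"""Voxelized spherical tumor node and diffuser placement geometry.

The node is a sphere of the given diameter centred at the origin, voxelized
on a cubic grid of the given pitch: cells tile ``[-R, R]^3`` with centres at
half-pitch offsets, and a voxel belongs to the node when its centre lies
within the sphere.  Horizontal slices of one pitch thickness are indexed
1..n_slices from the bottom upward, so ``n_slices = diameter / pitch``.

Fiber placement follows the sector-gravity-center layout: one central fiber
along the vertical diameter, plus 3 (120 deg sectors) or 4 (90 deg sectors)
surrounding fibers whose axes pass through the centroids of the angular
sectors of the equatorial disc, with lengths fitted so that the fiber tips
touch the sphere surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .optics import CylindricalDiffuser

__all__ = [
    "NodeModel",
    "FiberPlacement",
    "build_node",
    "sector_gravity_center",
    "fit_surrounding_length",
    "place_fibers",
    "distance_to_fiber",
]

#: Azimuths (degrees) of the surrounding fibers for each supported count.
#: Coverage is nearly rotation-invariant; fixing them makes runs reproducible.
DEFAULT_AZIMUTHS = {3: (90.0, 210.0, 330.0), 4: (45.0, 135.0, 225.0, 315.0)}
SECTOR_ANGLES = {3: 120.0, 4: 90.0}


@dataclass(frozen=True)
class NodeModel:
    """Voxelized spherical node.

    Attributes
    ----------
    diameter, pitch : float
        Sphere diameter and voxel edge, cm.
    voxel_centers : (M, 3) ndarray
        Centres of the in-sphere voxels, cm.
    slice_index : (M,) ndarray of int
        1-based slice index per voxel, bottom slice first.
    n_slices : int
        ``round(diameter / pitch)``.
    """

    diameter: float
    pitch: float
    voxel_centers: np.ndarray
    slice_index: np.ndarray
    n_slices: int

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_centers)

    @property
    def equatorial_lower_slice(self) -> int:
        """Index of the slice just below (or containing, for odd counts) the equator."""
        return (self.n_slices + 1) // 2

    def slice_mask(self, index: int) -> np.ndarray:
        """Boolean mask of the voxels belonging to slice ``index``."""
        if not (1 <= index <= self.n_slices):
            raise ValueError(f"slice index must be in 1..{self.n_slices}, got {index}")
        return self.slice_index == index

    def slice_z_range(self, index: int) -> tuple[float, float]:
        """(z_min, z_max) of slice ``index``, cm."""
        z0 = -self.radius + (index - 1) * self.pitch
        return (z0, z0 + self.pitch)


def build_node(diameter: float, pitch: float = 0.1) -> NodeModel:
    """Voxelize a sphere of ``diameter`` cm on a grid of ``pitch`` cm.

    Cell centres sit at half-pitch offsets of ``[-R, R]`` per axis; membership
    is centre distance <= R.  This registration yields exactly
    ``diameter/pitch`` slices, matching odd slice counts such as 5 for a
    0.5 cm node.
    """
    if not (diameter > 0):
        raise ValueError(f"diameter must be > 0, got {diameter}")
    if not (0 < pitch < diameter):
        raise ValueError(f"pitch must satisfy 0 < pitch < diameter, got {pitch}")
    radius = diameter / 2.0
    n = int(round(diameter / pitch))
    centers_1d = -radius + (np.arange(n) + 0.5) * pitch
    gx, gy, gz = np.meshgrid(centers_1d, centers_1d, centers_1d, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = (pts**2).sum(axis=1) <= radius**2 + 1e-12
    pts = pts[inside]
    slice_index = np.rint((pts[:, 2] + radius) / pitch - 0.5).astype(int) + 1
    return NodeModel(
        diameter=float(diameter),
        pitch=float(pitch),
        voxel_centers=pts,
        slice_index=slice_index,
        n_slices=n,
    )


def sector_gravity_center(slice_radius: float, sector_angle: float) -> float:
    """Distance from the disc centre to the centroid of a circular sector, cm.

    For a sector of half-angle ``a`` (radians) cut from a disc of radius
    ``r``, the centroid lies at ``x = 2 r sin(a) / (3 a)``.  Monotone
    decreasing in the sector angle; tends to ``2r/3`` as the angle vanishes.

    Parameters
    ----------
    slice_radius : float
        Disc radius ``r``, cm; > 0.
    sector_angle : float
        Full sector angle, degrees, in (0, 360].
    """
    if not (slice_radius > 0):
        raise ValueError(f"slice radius must be > 0, got {slice_radius}")
    if not (0 < sector_angle <= 360):
        raise ValueError(f"sector angle must be in (0, 360] degrees, got {sector_angle}")
    a = math.radians(sector_angle) / 2.0
    return 2.0 * slice_radius * math.sin(a) / (3.0 * a)


def fit_surrounding_length(radius: float, gravity_distance: float) -> float:
    """Length of a vertical chord at radial offset ``gravity_distance``, cm.

    A surrounding fiber is centred on the equatorial plane; fitting its far
    tips to the sphere surface gives ``L = 2 sqrt(R^2 - x^2)``, i.e.
    ``x^2 + (L/2)^2 = R^2``.
    """
    if radius < 0 or not (0 <= gravity_distance <= radius):
        raise ValueError(
            f"need 0 <= gravity_distance <= radius, got {gravity_distance} vs {radius}"
        )
    return 2.0 * math.sqrt(radius**2 - gravity_distance**2)


@dataclass(frozen=True)
class FiberPlacement:
    """A set of vertically embedded diffusers inside the node."""

    fibers: tuple[CylindricalDiffuser, ...]
    n_surrounding: int
    sector_angle: float | None
    gravity_distance: float | None
    surrounding_length: float | None

    @property
    def central(self) -> CylindricalDiffuser:
        return self.fibers[0]

    @property
    def surrounding(self) -> tuple[CylindricalDiffuser, ...]:
        return self.fibers[1:]

    def with_powers(
        self, central_power: float, surrounding_power: float | None = None
    ) -> "FiberPlacement":
        """Copy of the placement with the given linear powers applied."""
        fibers = [self.central.with_power(central_power)]
        for f in self.surrounding:
            fibers.append(f.with_power(surrounding_power if surrounding_power is not None else 0.0))
        return FiberPlacement(
            fibers=tuple(fibers),
            n_surrounding=self.n_surrounding,
            sector_angle=self.sector_angle,
            gravity_distance=self.gravity_distance,
            surrounding_length=self.surrounding_length,
        )


def place_fibers(
    node: NodeModel,
    n_surrounding: int,
    *,
    n_points: int = 101,
    azimuths_deg: tuple[float, ...] | None = None,
) -> FiberPlacement:
    """Central fiber plus 0, 3 or 4 surrounding fibers at sector centroids.

    The central fiber spans the vertical diameter.  Surrounding fibers stand
    at the gravity-centre radius of the equatorial 120 deg (3 fibers) or
    90 deg (4 fibers) sectors, azimuthally equispaced, with sphere-fitted
    lengths.  All linear powers start at zero.
    """
    if n_surrounding not in (0, 3, 4):
        raise ValueError(f"n_surrounding must be 0, 3 or 4, got {n_surrounding}")
    central = CylindricalDiffuser(
        center=(0.0, 0.0, 0.0), length=node.diameter, n_points=n_points
    )
    if n_surrounding == 0:
        return FiberPlacement(
            fibers=(central,),
            n_surrounding=0,
            sector_angle=None,
            gravity_distance=None,
            surrounding_length=None,
        )
    sector = SECTOR_ANGLES[n_surrounding]
    x = sector_gravity_center(node.radius, sector)
    length = fit_surrounding_length(node.radius, x)
    azimuths = azimuths_deg if azimuths_deg is not None else DEFAULT_AZIMUTHS[n_surrounding]
    if len(azimuths) != n_surrounding:
        raise ValueError("one azimuth per surrounding fiber is required")
    fibers = [central]
    for az in azimuths:
        phi = math.radians(az)
        fibers.append(
            CylindricalDiffuser(
                center=(x * math.cos(phi), x * math.sin(phi), 0.0),
                length=length,
                n_points=n_points,
            )
        )
    return FiberPlacement(
        fibers=tuple(fibers),
        n_surrounding=n_surrounding,
        sector_angle=sector,
        gravity_distance=x,
        surrounding_length=length,
    )


def distance_to_fiber(
    points: np.ndarray, fiber: CylindricalDiffuser
) -> np.ndarray | float:
    """Euclidean distance from point(s) to the finite diffuser segment, cm.

    Perpendicular distance within the axial extent, distance to the nearer
    tip beyond it.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    rel = pts - np.asarray(fiber.center)
    axis = np.asarray(fiber.axis)
    axial = rel @ axis
    axial_clamped = np.clip(axial, -fiber.length / 2.0, fiber.length / 2.0)
    closest = axial_clamped[:, None] * axis
    d = np.linalg.norm(rel - closest, axis=1)
    return float(d[0]) if single else d
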
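"""Diffusion-approximation light transport for cylindrical diffusing fibers.

A cylindrical diffusing fiber (CDF) emits light radially along its terminal
segment.  In a turbid medium whose reduced scattering dominates absorption,
the fluence rate of a point source decays as ``exp(-mu_eff * r) / r``; a CDF
of length ``l`` is modelled as ``N`` point sources spread uniformly along its
axis, one always at the midpoint:

    phi(r) = 3 * s * l * musp / (4 * pi) * 1/(N-1) * sum_i exp(-mu_eff*r_i)/r_i

with ``s`` the linear power (mW/cm), ``r_i`` the distance from the i-th
source point to the observation point and ``mu_eff = sqrt(3*mua*(mua+musp))``.
Since ``l/(N-1)`` is the elemental segment length, the sum is a midpoint-rule
quadrature of the continuous line-source integral and converges once the
segment length drops below ~0.05 cm.

Doses are fluence rate integrated over the illumination time, reported in
J/cm^2 (hence the mW -> W factor of 1000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OpticalProperties",
    "CylindricalDiffuser",
    "BREAST_TUMOR_690NM",
    "HARDWARE_MAX_LINEAR_POWER",
    "effective_attenuation",
    "cdf_fluence_rate",
    "dose_from_fluence",
    "total_dose",
]

#: Maximum CW linear power density of the modelled diffuser hardware, mW/cm.
HARDWARE_MAX_LINEAR_POWER = 500.0

#: Segment length above which the point-source discretization is degraded, cm.
RECOMMENDED_MAX_DX = 0.05

#: Distances below this radius are clamped to avoid the 1/r singularity, cm.
#: Half the default voxel pitch; such voxels sit inside the near-source region
#: where the diffusion model is unreliable anyway.
SINGULARITY_CLAMP_RADIUS = 0.05

_POINT_CHUNK = 32768


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption / reduced-scattering pair of a homogeneous turbid medium.

    Parameters
    ----------
    mua : float
        Absorption coefficient, cm^-1.  Must be >= 0.
    musp : float
        Reduced scattering coefficient, cm^-1.  Must be > 0.

    The diffusion approximation assumes scattering dominates absorption;
    a :class:`UserWarning` is emitted when ``musp < 10 * mua``.
    """

    mua: float
    musp: float

    def __post_init__(self) -> None:
        if not (self.mua >= 0.0):
            raise ValueError(f"absorption coefficient must be >= 0, got {self.mua}")
        if not (self.musp > 0.0):
            raise ValueError(f"reduced scattering coefficient must be > 0, got {self.musp}")
        if self.musp < 10.0 * self.mua:
            warnings.warn(
                "diffusion approximation is questionable: musp "
                f"({self.musp}) < 10 * mua ({self.mua})",
                UserWarning,
                stacklevel=2,
            )

    @property
    def mu_eff(self) -> float:
        """Effective attenuation coefficient sqrt(3*mua*(mua+musp)), cm^-1."""
        return effective_attenuation(self)


#: Mean breast-tumor optical properties at 690 nm.
BREAST_TUMOR_690NM = OpticalProperties(mua=0.085, musp=16.0)


@dataclass(frozen=True)
class CylindricalDiffuser:
    """A finite linear light source embedded in tissue.

    Parameters
    ----------
    center : array-like of 3 floats
        Midpoint of the diffusing segment, cm.
    length : float
        Diffusing length ``l``, cm; > 0.
    linear_power : float
        Emitted power per unit length ``s``, mW/cm, within
        [0, :data:`HARDWARE_MAX_LINEAR_POWER`].
    axis : array-like of 3 floats, optional
        Direction of the fiber; normalised on construction.  Vertical (+z)
        by default.
    n_points : int, optional
        Number ``N`` of point sources in the discretization; odd, >= 3, so
        one point sits exactly at the midpoint.  Default 101.
    """

    center: tuple[float, float, float]
    length: float
    linear_power: float = 0.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    n_points: int = 101

    def __post_init__(self) -> None:
        center = tuple(float(c) for c in np.asarray(self.center, dtype=float))
        if len(center) != 3:
            raise ValueError("center must be a 3-vector")
        axis = np.asarray(self.axis, dtype=float)
        norm = float(np.linalg.norm(axis))
        if axis.shape != (3,) or norm == 0.0:
            raise ValueError("axis must be a nonzero 3-vector")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "axis", tuple(axis / norm))
        if not (self.length > 0.0):
            raise ValueError(f"diffuser length must be > 0, got {self.length}")
        if self.n_points < 3 or self.n_points % 2 == 0:
            raise ValueError(f"n_points must be an odd integer >= 3, got {self.n_points}")
        if not (0.0 <= self.linear_power <= HARDWARE_MAX_LINEAR_POWER):
            raise ValueError(
                f"linear_power must be within [0, {HARDWARE_MAX_LINEAR_POWER}] mW/cm, "
                f"got {self.linear_power}"
            )
        if self.dx > RECOMMENDED_MAX_DX:
            warnings.warn(
                f"elemental segment dx = {self.dx:.4f} cm exceeds "
                f"{RECOMMENDED_MAX_DX} cm; increase n_points for an accurate sum",
                UserWarning,
                stacklevel=2,
            )

    @property
    def dx(self) -> float:
        """Elemental segment length l/(N-1), cm."""
        return self.length / (self.n_points - 1)

    def source_points(self) -> np.ndarray:
        """(N, 3) coordinates of the discretized point sources, cm."""
        offsets = (np.arange(self.n_points) - (self.n_points - 1) / 2.0) * self.dx
        return np.asarray(self.center) + offsets[:, None] * np.asarray(self.axis)

    def with_power(self, linear_power: float) -> "CylindricalDiffuser":
        """Copy of this diffuser at a different linear power."""
        return replace(self, linear_power=float(linear_power))


def effective_attenuation(props: OpticalProperties) -> float:
    """Effective attenuation coefficient ``sqrt(3*mua*(mua+musp))``, cm^-1.

    Governs the far-field exponential decay of the fluence rate; strictly
    increasing in both optical coefficients.
    """
    return float(np.sqrt(3.0 * props.mua * (props.mua + props.musp)))


def cdf_fluence_rate(
    fiber: CylindricalDiffuser,
    points: np.ndarray,
    props: OpticalProperties,
    *,
    clamp_radius: float = SINGULARITY_CLAMP_RADIUS,
) -> np.ndarray | float:
    """Fluence rate of one diffuser at one or many observation points, mW/cm^2.

    Evaluates the discretized line-source kernel (module docstring).  Source
    distances below ``clamp_radius`` are clamped so the value stays finite on
    and next to the fiber; those locations fall inside the near-source region
    where the diffusion model underestimates the true fluence regardless.

    Parameters
    ----------
    points : (3,) or (M, 3) array
        Observation coordinates, cm.

    Returns
    -------
    float or (M,) ndarray
        Scalar for a single point, array otherwise.  Linear in
        ``fiber.linear_power``.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3:
        raise ValueError("points must have shape (3,) or (M, 3)")
    mu_eff = effective_attenuation(props)
    src = fiber.source_points()
    prefactor = (
        3.0 * fiber.linear_power * fiber.length * props.musp
        / (4.0 * np.pi)
        / (fiber.n_points - 1)
    )
    out = np.empty(len(pts))
    for lo in range(0, len(pts), _POINT_CHUNK):
        chunk = pts[lo : lo + _POINT_CHUNK]
        r = np.linalg.norm(chunk[:, None, :] - src[None, :, :], axis=2)
        np.maximum(r, clamp_radius, out=r)
        out[lo : lo + _POINT_CHUNK] = prefactor * (np.exp(-mu_eff * r) / r).sum(axis=1)
    return float(out[0]) if single else out


def dose_from_fluence(fluence: np.ndarray | float, time: float) -> np.ndarray | float:
    """Light dose in J/cm^2 from a fluence rate in mW/cm^2 over ``time`` seconds."""
    if time < 0:
        raise ValueError(f"illumination time must be >= 0, got {time}")
    return np.multiply(fluence, time / 1000.0)


def total_dose(
    fibers: list[CylindricalDiffuser],
    points: np.ndarray,
    props: OpticalProperties,
    time: float,
) -> np.ndarray | float:
    """Total light dose from all diffusers, J/cm^2.

    The diffusion equation is linear, so the dose at a point is simply the
    sum of the per-fiber doses.
    """
    if not fibers:
        raise ValueError("at least one diffuser is required")
    return sum(dose_from_fluence(cdf_fluence_rate(f, points, props), time) for f in fibers)
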
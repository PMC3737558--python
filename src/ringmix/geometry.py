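"""Spherocylindrical confinement geometry.

The container is a cylinder of diameter ``D`` capped by two hemispheres,
with ``L`` the total tip-to-tip length (caps included).  All lengths are
reduced: ``D = 1`` defines the length unit, so coordinates, bead radii and
overlap lengths are reported as fractions of the container diameter.  The
container axis is the z axis and the origin sits at the centroid, which
makes axial observables and the mirror symmetries of the system easy to
express.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfigurationError",
    "ConfinementGeometry",
    "spherocylinder_volume",
    "solve_bead_radius",
    "contains_bead",
]


class ConfigurationError(ValueError):
    """Raised when geometry or run parameters are inconsistent."""


def spherocylinder_volume(diameter: float, total_length: float) -> float:
    """Volume of a cylinder with hemispherical caps.

    ``total_length`` is tip to tip, so the straight body has length
    ``total_length - diameter`` and the two caps together form one full
    sphere: ``V = pi (D/2)^2 (L - D) + (4/3) pi (D/2)^3``.

    Raises
    ------
    ConfigurationError
        If ``total_length < diameter`` (the caps would not fit) or any
        input is non-positive.
    """
    if diameter <= 0 or total_length <= 0:
        raise ConfigurationError(
            f"dimensions must be positive, got D={diameter}, L={total_length}"
        )
    if total_length < diameter:
        raise ConfigurationError(
            f"total length {total_length} is shorter than diameter {diameter}; "
            "the hemispherical caps do not fit"
        )
    radius = 0.5 * diameter
    return math.pi * radius**2 * (total_length - diameter) + (4.0 / 3.0) * math.pi * radius**3


@dataclass(frozen=True)
class ConfinementGeometry:
    """The confining spherocylinder in reduced units.

    Parameters
    ----------
    diameter:
        Container diameter ``D``; the default 1.0 defines the length unit.
    aspect:
        Ratio ``L/D`` of total (tip-to-tip) length to diameter.  The
        rod-shaped cells the model mimics have aspect ratio about 4.
    """

    diameter: float = 1.0
    aspect: float = 4.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ConfigurationError(f"diameter must be positive, got {self.diameter}")
        if self.aspect < 1.0:
            raise ConfigurationError(
                f"aspect ratio must be >= 1 so the caps fit, got {self.aspect}"
            )

    @classmethod
    def from_total_length(cls, diameter: float, total_length: float) -> "ConfinementGeometry":
        if diameter <= 0:
            raise ConfigurationError(f"diameter must be positive, got {diameter}")
        return cls(diameter=diameter, aspect=total_length / diameter)

    @property
    def total_length(self) -> float:
        """Tip-to-tip length ``L = aspect * D`` (caps included)."""
        return self.aspect * self.diameter

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def cap_half_length(self) -> float:
        """Half-length of the straight cylindrical body, ``(L - D) / 2``.

        The cap hemisphere centres sit at ``z = +/- cap_half_length``.
        """
        return 0.5 * (self.total_length - self.diameter)

    @property
    def volume(self) -> float:
        return spherocylinder_volume(self.diameter, self.total_length)

    def contains(self, centers: np.ndarray, r: float) -> np.ndarray:
        """Vectorised whole-bead containment test.

        A bead of radius ``r`` lies inside iff its centre lies inside the
        spherocylinder eroded by ``r`` (diameter ``D - 2r``, total length
        ``L - 2r``).  The boundary counts as inside; comparisons carry a
        1e-12 relative slack so exact-boundary constructions do not fail
        on floating-point ties.
        """
        centers = np.atleast_2d(np.asarray(centers, dtype=float))
        inner = self.radius - r
        if inner <= 0:
            return np.zeros(len(centers), dtype=bool)
        zc = self.cap_half_length
        x, y, z = centers[:, 0], centers[:, 1], centers[:, 2]
        az = np.abs(z)
        rho2 = x * x + y * y
        limit2 = inner * inner * (1.0 + 1e-12)
        in_body = (az <= zc) & (rho2 <= limit2)
        dz = np.maximum(az - zc, 0.0)
        in_cap = (az > zc) & (rho2 + dz * dz <= limit2)
        return in_body | in_cap


def solve_bead_radius(n_total: int, phi: float, geom: ConfinementGeometry) -> float:
    """Bead radius giving a total bead volume fraction ``phi``.

    Solves ``n_total * (4/3) pi r^3 = phi * V`` in closed form, where ``V``
    is the container volume.  This pins the thickness of the chains: at
    fixed 5% occupancy, longer chains are thinner, and the diameter ratio
    ``D/d = D/(2r)`` grows as ``n_total**(1/3)``.

    Raises
    ------
    ConfigurationError
        If the resulting bead does not fit through the container
        (``2r >= D``), or inputs are out of range.
    """
    if n_total < 1:
        raise ConfigurationError(f"need at least one bead, got {n_total}")
    if not 0.0 < phi < 0.74:
        raise ConfigurationError(
            f"volume fraction must lie in (0, 0.74), got {phi}"
        )
    r = (phi * geom.volume * 3.0 / (4.0 * math.pi * n_total)) ** (1.0 / 3.0)
    if 2.0 * r >= geom.diameter:
        raise ConfigurationError(
            f"bead diameter {2 * r:.4g} does not fit in container diameter "
            f"{geom.diameter:.4g}; reduce phi or increase the bead count"
        )
    return r


def contains_bead(geom: ConfinementGeometry, center: np.ndarray, r: float) -> bool:
    """True iff a single bead of radius ``r`` lies entirely inside ``geom``."""
    return bool(geom.contains(np.asarray(center, dtype=float).reshape(1, 3), r)[0])
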
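"""Geometry and force primitives for spherocylindrical rods.

A rod of total length ``l`` (caps included) is the set of points within
``R`` of its centre-line "spine", a segment of length ``l - 2R``.  Two
rods interact through a Hertzian repulsion acting along the shortest
connection ``d`` between their spines,

    F(d) = Y * sqrt(R/8) * (2R - |d|)^{3/2} * d_hat     for |d| <= 2R,

and each rod is slightly compressible along its axis via an internal
Hertzian spring ``kc * (l_rest - l)^{3/2}``.  Translational and
rotational mobilities follow the Tirado-Garcia de la Torre
short-cylinder series in the aspect ratio ``l / 2R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import ModelParams

__all__ = [
    "Rod",
    "Contact",
    "MobilityTensor",
    "Wall",
    "segment_closest_points",
    "hertz_pair_force",
    "pair_contact",
    "wall_force",
    "internal_compression_force",
    "mobility",
    "mu_parallel",
    "DegenerateContactError",
]


class DegenerateContactError(ValueError):
    """Raised when two centre lines coincide and the force direction is
    undefined; the caller must perturb one of the rods."""


@dataclass
class Rod:
    """One growing spherocylindrical cell.

    ``l_rest`` is the uncompressed (rest) length, ``l`` the actual,
    possibly compressed, length; both include the caps.  The normalised
    age is ``g = 2 l_rest / lmax - 1``, running from 0 at birth to 1 at
    division.
    """

    id: int
    r: np.ndarray
    phi: float
    l_rest: float
    l: float
    gamma: float

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)

    def g(self, lmax: float) -> float:
        return 2.0 * self.l_rest / lmax - 1.0

    @property
    def axis(self) -> np.ndarray:
        return np.array([math.cos(self.phi), math.sin(self.phi)])

    def spine(self, use_rest: bool = False, R: float = 0.5):
        """Endpoints of the centre-line segment (length l - 2R)."""
        half = 0.5 * (self.l_rest if use_rest else self.l) - R
        half = max(half, 0.0)
        u = self.axis
        return self.r - half * u, self.r + half * u


@dataclass
class Contact:
    """A resolved pair interaction.

    ``d`` is the shortest connection between the two centre lines
    (pointing from rod l to rod k), ``F_kl`` the force on k exerted by
    l, and ``r_kl = r_k - r_l`` the centre-to-centre vector.
    """

    ids: tuple
    d: np.ndarray
    F_kl: np.ndarray
    r_kl: np.ndarray


@dataclass(frozen=True)
class MobilityTensor:
    """Anisotropic overdamped mobilities of a rod in its body frame."""

    mu_par: float
    mu_perp: float
    mu_rot: float

    def lab_frame(self, phi: float) -> np.ndarray:
        """Translational mobility tensor rotated to the lab frame."""
        c, s = math.cos(phi), math.sin(phi)
        u = np.array([c, s])
        n = np.array([-s, c])
        return self.mu_par * np.outer(u, u) + self.mu_perp * np.outer(n, n)


@dataclass(frozen=True)
class Wall:
    """An axis-aligned confining line.

    ``axis`` is the coordinate the wall constrains (0 for a vertical
    wall x = position), ``side`` is +1 when the interior lies below
    ``position`` and -1 when it lies above.
    """

    axis: int
    position: float
    side: int


def segment_closest_points(seg_a, seg_b):
    """Closest points between two segments.

    Parameters are endpoint pairs ``((x0, y0), (x1, y1))``.  Returns
    ``(point_on_a, point_on_b, d)`` with ``d = point_on_a - point_on_b``
    the shortest connection.  Exactly parallel overlapping segments
    contact at the midpoint of their overlap interval.
    """
    (p1, q1), (p2, q2) = seg_a, seg_b
    ax, ay, bx, by = _kernels.seg_closest_points(
        float(p1[0]), float(p1[1]), float(q1[0]), float(q1[1]),
        float(p2[0]), float(p2[1]), float(q2[0]), float(q2[1]))
    pa = np.array([ax, ay])
    pb = np.array([bx, by])
    return pa, pb, pa - pb


def hertz_pair_force(d: np.ndarray, params: ModelParams) -> np.ndarray:
    """Hertzian contact force for connection vector d (force on the rod
    that d points towards); zero when the rods do not overlap."""
    d = np.asarray(d, dtype=float)
    dist = float(np.hypot(d[0], d[1]))
    two_R = 2.0 * params.R
    if dist > two_R:
        return np.zeros(2)
    if dist < 1e-12:
        raise DegenerateContactError(
            "coincident centre lines: contact direction undefined; "
            "perturb one rod")
    ov = two_R - dist
    return params.hertz_prefactor * ov ** 1.5 * d / dist


def pair_contact(rod_k: Rod, rod_l: Rod, params: ModelParams) -> Contact | None:
    """Resolve the contact between two rods, or None when separated."""
    pa, pb, d = segment_closest_points(
        rod_k.spine(R=params.R), rod_l.spine(R=params.R))
    if np.hypot(d[0], d[1]) > 2.0 * params.R:
        return None
    F = hertz_pair_force(d, params)
    return Contact(ids=(rod_k.id, rod_l.id), d=d, F_kl=F,
                   r_kl=rod_k.r - rod_l.r)


def wall_force(rod: Rod, wall: Wall, params: ModelParams):
    """Hertzian wall force on a rod.

    The same force law as rod-rod contacts applies, with ``d`` the
    shortest connection from the rod's centre line to the wall; the
    force acts at the closest spine point, producing a consistent
    torque about the rod centre.  Returns ``(force, torque, point)``.
    """
    if wall.axis != 0:
        raise NotImplementedError("only vertical walls (axis=0) occur in "
                                  "channel domains")
    p, q = rod.spine(R=params.R)
    two_R = 2.0 * params.R
    if wall.side > 0:  # interior at x < position
        xc = max(p[0], q[0])
        dist = wall.position - xc
        direction = -1.0
    else:
        xc = min(p[0], q[0])
        dist = xc - wall.position
        direction = 1.0
    if dist >= two_R:
        return np.zeros(2), 0.0, None
    if abs(q[0] - p[0]) < 1e-9:
        point = rod.r.copy()  # parallel to the wall: midpoint tie-break
    else:
        point = (q if (q[0] > p[0]) == (wall.side > 0) else p).copy()
    ov = two_R - dist
    F = np.array([direction * params.hertz_prefactor * ov ** 1.5, 0.0])
    lever = point - rod.r
    torque = lever[0] * F[1] - lever[1] * F[0]
    return F, torque, point


def internal_compression_force(rod: Rod, params: ModelParams) -> float:
    """Magnitude of the axial restoring force kc (l_rest - l)^{3/2}."""
    if rod.l > rod.l_rest + 1e-12:
        raise ValueError("actual length exceeds rest length")
    return params.kc * max(rod.l_rest - rod.l, 0.0) ** 1.5


def mobility(rod_or_length, params: ModelParams) -> MobilityTensor:
    """Tirado short-cylinder mobilities for a rod (or a length)."""
    l = rod_or_length.l if isinstance(rod_or_length, Rod) else float(rod_or_length)
    if l < 2.0 * params.R:
        raise ValueError("aspect ratio l / 2R must be >= 1")
    mp, mq, mr = _kernels.tirado_mobilities(l, params.R, params.zeta0)
    return MobilityTensor(mu_par=mp, mu_perp=mq, mu_rot=mr)


def mu_parallel(l, params: ModelParams):
    """Vectorised parallel mobility mu_par(l), used by the column theory."""
    l = np.asarray(l, dtype=float)
    p = l / (2.0 * params.R)
    if np.any(p < 1.0):
        raise ValueError("aspect ratio l / 2R must be >= 1")
    nu = -0.207 + 0.980 / p - 0.133 / p**2
    return (np.log(p) + nu) / (2.0 * np.pi * params.zeta0 * l)
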
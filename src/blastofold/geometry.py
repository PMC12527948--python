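"""Semi-elliptical embryo geometry and discretization of the blastoderm.

The early fly embryo is modelled in cross-section: the blastoderm epithelium
is an elastic rod lying on the upper half of an ellipse with semi-major axis
``L`` and aspect ratio ``beta`` (semi-minor / semi-major).  Germ-band
extension is represented as a static shortening of the available boundary
arc: the posterior end of the tissue sits at the parametric angle
``u' = arccos(1 - 2g)`` where ``g`` is the fraction of the embryo length
covered by the extended germ band.  The tissue itself is discretized into
particles connected by springs of a common rest length derived from the
*full* (stress-free) semi-elliptical arc, so that any ``g > 0`` leaves the
chain uniformly compressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "EmbryoShape",
    "GermBandSpec",
    "DiscretizedTissue",
    "semi_ellipse_arc_length",
    "germ_band_angle",
    "initialize_tissue",
    "embryo_length_fraction",
    "arc_coordinates",
]

# number of nodes in the dense cumulative arc-length table used for
# equal-arc-length particle placement
_ARC_TABLE_NODES = 2000


@dataclass(frozen=True)
class EmbryoShape:
    """Rigid semi-elliptical confinement (the vitelline envelope).

    Parameters
    ----------
    L : float
        Semi-major axis (model length unit).
    beta : float
        Aspect ratio semi-minor/semi-major, ``0 < beta <= 1``.
    """

    L: float = 1.0
    beta: float = 0.4

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"semi-major axis must be positive, got {self.L}")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError(f"aspect ratio must be in (0, 1], got {self.beta}")

    @property
    def e(self) -> float:
        """Eccentricity ``sqrt(1 - beta**2)``."""
        return float(np.sqrt(1.0 - self.beta**2))

    @property
    def semi_minor(self) -> float:
        return self.L * self.beta

    def boundary_point(self, u):
        """Point ``(L cos u, beta L sin u)`` on the elliptical boundary."""
        u = np.asarray(u, dtype=float)
        return np.stack([self.L * np.cos(u), self.beta * self.L * np.sin(u)], axis=-1)

    def contains(self, points, tol: float = 1e-9):
        """Whether points satisfy ``x^2/L^2 + y^2/(beta L)^2 <= 1 + tol``."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        q = (p[:, 0] / self.L) ** 2 + (p[:, 1] / (self.beta * self.L)) ** 2
        out = q <= 1.0 + tol
        return out if np.ndim(points) > 1 else bool(out[0])


def germ_band_angle(g: float) -> float:
    """Boundary angle ``u' = arccos(1 - 2g)`` of the posterior tissue end.

    ``g`` is the projection of the germ-band arc length onto the embryo
    mid-axis, normalized by the embryo length ``2L``; ``g = 0`` means no
    extension (end at the posterior pole, ``u' = 0``).
    """
    if not (0.0 <= g < 1.0):
        raise ValueError(f"germ-band extension g must lie in [0, 1), got {g}")
    return float(np.arccos(1.0 - 2.0 * g))


@dataclass(frozen=True)
class GermBandSpec:
    """Germ-band extension state: fraction ``g`` and derived end angle."""

    g: float = 0.0

    def __post_init__(self) -> None:
        germ_band_angle(self.g)  # validates

    @property
    def u_prime(self) -> float:
        return germ_band_angle(self.g)


def semi_ellipse_arc_length(shape: EmbryoShape, u0: float, u1: float) -> float:
    """Elliptic arc length ``L * integral_{u0}^{u1} sqrt(1 - e^2 cos^2 u) du``.

    Computed by adaptive quadrature; additive over subintervals and exact
    for circles (``beta = 1``).
    """
    if not (0.0 <= u0 <= u1 <= np.pi):
        raise ValueError(
            f"angles must satisfy 0 <= u0 <= u1 <= pi, got u0={u0}, u1={u1}"
        )
    if u0 == u1:
        return 0.0
    e2 = shape.e**2
    val, _ = quad(lambda u: np.sqrt(1.0 - e2 * np.cos(u) ** 2), u0, u1,
                  epsabs=1e-12, epsrel=1e-12, limit=200)
    return float(shape.L * val)


def _cumulative_arc_table(shape: EmbryoShape, u0: float, u1: float,
                          nodes: int = _ARC_TABLE_NODES):
    """Dense (u, cumulative-arc) table over [u0, u1] for inverse interpolation."""
    u = np.linspace(u0, u1, nodes + 1)
    integrand = shape.L * np.sqrt(1.0 - shape.e**2 * np.cos(u) ** 2)
    # composite trapezoid on a dense uniform grid; endpoint values rescaled to
    # the adaptive-quadrature total so placement error is purely interpolation
    ds = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(u))])
    total = semi_ellipse_arc_length(shape, u0, u1)
    if ds[-1] > 0:
        ds *= total / ds[-1]
    return u, ds


@dataclass
class DiscretizedTissue:
    """Particle-spring discretization of the blastoderm.

    ``positions[0]`` is the anterior end (angle ``pi``, x = -L) and
    ``positions[-1]`` the posterior/germ-band end (angle ``u'``).  The first
    and last two particles are fixed in space.  ``rest_length`` is the
    common stress-free spring length ``Delta r_o = L0 / n_segments`` where
    ``L0`` is the full semi-ellipse arc length, independent of ``g``.
    """

    positions: np.ndarray            # (N, 2) float64
    rest_length: float               # Delta r_o
    preferred_curvature: np.ndarray  # (N,) float64, kappa_{o,i}
    L0: float                        # stress-free total arc length
    n_fixed_each_end: int = 2

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.preferred_curvature = np.ascontiguousarray(
            self.preferred_curvature, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if self.preferred_curvature.shape[0] != self.positions.shape[0]:
            raise ValueError("preferred_curvature length must match particle count")
        if self.N < 8:
            raise ValueError(f"need at least 8 particles, got {self.N}")

    @property
    def N(self) -> int:
        """Particle count."""
        return self.positions.shape[0]

    @property
    def fixed_indices(self) -> np.ndarray:
        k = self.n_fixed_each_end
        return np.r_[np.arange(k), np.arange(self.N - k, self.N)]

    @property
    def free_mask(self) -> np.ndarray:
        m = np.ones(self.N, dtype=bool)
        m[self.fixed_indices] = False
        return m

    def spring_lengths(self) -> np.ndarray:
        """Current lengths ``Delta r_i`` of the N-1 springs."""
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def copy(self) -> "DiscretizedTissue":
        return DiscretizedTissue(
            positions=self.positions.copy(),
            rest_length=self.rest_length,
            preferred_curvature=self.preferred_curvature.copy(),
            L0=self.L0,
            n_fixed_each_end=self.n_fixed_each_end,
        )


def initialize_tissue(shape: EmbryoShape, n_segments: int = 200,
                      gb: GermBandSpec | None = None) -> DiscretizedTissue:
    """Place the tissue on the boundary at equal arc-length spacing.

    The available arc ``[u', pi]`` is divided into ``n_segments`` equal
    segments (``n_segments + 1`` particles), so every initial spring length
    equals ``Delta r(0) = arc(u', pi) / n_segments``, while the rest length
    is ``Delta r_o = arc(0, pi) / n_segments``.  For ``g = 0`` the two agree
    and the tissue is stress-free; for ``g > 0`` it is uniformly compressed.

    Particle order runs from the anterior pole (angle ``pi``) to the
    germ-band end (angle ``u'``).  Preferred curvatures start at zero.
    """
    if n_segments < 8:
        raise ValueError(f"need at least 8 segments, got {n_segments}")
    gb = gb or GermBandSpec(0.0)
    u_prime = gb.u_prime

    L0 = semi_ellipse_arc_length(shape, 0.0, np.pi)
    arc_avail = semi_ellipse_arc_length(shape, u_prime, np.pi)
    u_tab, s_tab = _cumulative_arc_table(shape, u_prime, np.pi)
    targets = np.linspace(0.0, arc_avail, n_segments + 1)
    u_vals = np.interp(targets, s_tab, u_tab)
    # order anterior (u = pi) -> posterior (u = u'); pin exact endpoints
    u_vals = u_vals[::-1]
    u_vals[0], u_vals[-1] = np.pi, u_prime

    return DiscretizedTissue(
        positions=shape.boundary_point(u_vals),
        rest_length=L0 / n_segments,
        preferred_curvature=np.zeros(n_segments + 1),
        L0=L0,
    )


def embryo_length_fraction(x, shape: EmbryoShape):
    """Map x-coordinates to the axis position in fractions of embryo length.

    0 is the posterior pole (x = +L), 1 the anterior pole (x = -L); the
    wild-type cephalic furrow sits near 0.65 (anterior of the midpoint).
    """
    return (shape.L - np.asarray(x, dtype=float)) / (2.0 * shape.L)


def arc_coordinates(tissue: DiscretizedTissue) -> np.ndarray:
    """Cumulative chord-length coordinate of each particle, from the anterior end."""
    seg = np.linalg.norm(np.diff(tissue.positions, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])
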
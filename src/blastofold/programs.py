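"""Morphogenetic perturbations: germ band, mitotic domains, cephalic furrow.

Three programmed events act on the particle-spring blastoderm:

* **Germ-band extension** enters only through initialization (the posterior
  tissue end is static within a run; see :func:`blastofold.geometry.initialize_tissue`).
* **Mitotic domains** model patches of dividing, apically expanding cells:
  at onset ``t_MD`` (in units of 1e5 timesteps) a new particle is inserted
  at the midpoint of every spring inside the specified regions, and both
  daughter springs keep the global rest length ``Delta r_o`` — the region's
  preferred length doubles and it is instantaneously compressed.
* **The cephalic furrow** is a narrow region given an intrinsic negative
  (inward) preferred curvature ``-kappa_cf``, which tends to invaginate.

Axis positions are fractions of embryo length (0 = posterior pole,
1 = anterior pole); the wild-type furrow sits at 0.65.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    DiscretizedTissue,
    EmbryoShape,
    arc_coordinates,
    embryo_length_fraction,
    semi_ellipse_arc_length,
)

__all__ = [
    "MitoticDomainSpec",
    "CephalicFurrowSpec",
    "default_mitotic_domains",
    "insert_mitotic_particles",
    "apply_cephalic_furrow",
    "build_schedule",
    "MD_TIME_UNIT",
]

# one mitotic-domain time unit t_MD = 1 corresponds to 1e5 computational steps
MD_TIME_UNIT = 100_000


@dataclass(frozen=True)
class MitoticDomainSpec:
    """Mitotic-domain regions and onset time.

    ``regions`` are disjoint ``(lo, hi)`` intervals in fractions of embryo
    length; each default region spans an arc length of 0.5 L (see
    :func:`default_mitotic_domains`).  ``t_MD`` is the insertion onset in
    units of 1e5 timesteps.
    """

    regions: tuple = ()
    t_MD: float = 0.0

    def __post_init__(self) -> None:
        regs = tuple(tuple(map(float, r)) for r in self.regions)
        object.__setattr__(self, "regions", regs)
        for lo, hi in regs:
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"region ({lo}, {hi}) must satisfy 0 <= lo < hi <= 1")
        for (lo1, hi1), (lo2, hi2) in zip(sorted(regs), sorted(regs)[1:]):
            if hi1 > lo2:
                raise ValueError("mitotic-domain regions must be disjoint")
        if self.t_MD < 0:
            raise ValueError("t_MD must be >= 0")

    @property
    def onset_iteration(self) -> int:
        return int(round(self.t_MD * MD_TIME_UNIT))


@dataclass(frozen=True)
class CephalicFurrowSpec:
    """Programmed furrow: intrinsic negative curvature over a narrow region.

    ``center`` is the axis position (fraction of embryo length), ``width``
    the arc length of the region in model length units (default 0.05 L, the
    span of the initiator-cell rows), and ``onset`` the activation iteration.

    ``kappa_cf`` is the furrow strength: the preferred *turning angle per
    particle joint* in radians, i.e. the preferred curvature applied to the
    region is ``-kappa_cf / rest_length`` (magnitude in units of the inverse
    rest segment length).  This per-joint reading is what makes the quoted
    strengths (0.1–2.0) strong enough to drive an invagination past the fold
    threshold; read as a continuum curvature in 1/L, the same numbers are
    geometrically capped at a depth of order ``kappa_cf * width^2 / 8``
    (~0.005 L), an order of magnitude below the fold threshold, for any
    admissible width.
    """

    center: float = 0.65
    width: float = 0.05
    kappa_cf: float = 2.0
    onset: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.center < 1.0):
            raise ValueError(f"furrow center must be in (0, 1), got {self.center}")
        if self.width <= 0:
            raise ValueError("furrow width must be positive")
        if self.kappa_cf < 0:
            raise ValueError("kappa_cf is a magnitude and must be >= 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")


def _axis_to_angle(shape: EmbryoShape, f: float) -> float:
    """Parametric angle of the boundary point at axis fraction ``f``."""
    x = shape.L * (1.0 - 2.0 * f)
    return float(np.arccos(np.clip(x / shape.L, -1.0, 1.0)))


def arc_window(shape: EmbryoShape, center: float, arc_width: float) -> tuple[float, float]:
    """Axis interval (fractions of embryo length) spanning a given arc length.

    Returns the ``(lo, hi)`` axis positions of the boundary window of arc
    length ``arc_width`` centred (in arc length) on axis position ``center``.
    """
    u_c = _axis_to_angle(shape, center)
    # arc length measured from the posterior pole (u = 0)
    s_c = semi_ellipse_arc_length(shape, 0.0, u_c)
    total = semi_ellipse_arc_length(shape, 0.0, np.pi)
    lo_s = np.clip(s_c - arc_width / 2.0, 0.0, total)
    hi_s = np.clip(s_c + arc_width / 2.0, 0.0, total)
    # invert arc length -> angle on a dense table
    u = np.linspace(0.0, np.pi, 2001)
    integ = shape.L * np.sqrt(1.0 - shape.e**2 * np.cos(u) ** 2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (integ[1:] + integ[:-1]) * np.diff(u))])
    u_lo = np.interp(lo_s, s, u)
    u_hi = np.interp(hi_s, s, u)
    f_lo = float(embryo_length_fraction(shape.L * np.cos(u_lo), shape))
    f_hi = float(embryo_length_fraction(shape.L * np.cos(u_hi), shape))
    return min(f_lo, f_hi), max(f_lo, f_hi)


def default_mitotic_domains(shape: EmbryoShape, t_MD: float = 0.0) -> MitoticDomainSpec:
    """Canonical mitotic-domain layout: a head patch and a posterior patch.

    Each region spans an arc length of 0.5 L: one anterior of the canonical
    furrow position (centred at 0.80 embryo length, the head mitotic
    domains, clear of the furrow region) and one in the trunk/posterior
    (centred at 0.35).  Insertion doubles each region's preferred length, so
    the default layout adds 1.0 L of material to the 2.3 L tissue.
    """
    regions = [
        arc_window(shape, 0.80, 0.50 * shape.L),
        arc_window(shape, 0.35, 0.50 * shape.L),
    ]
    # guard against numerical overlap of the two adjacent head windows
    regions = sorted(regions)
    merged: list[tuple[float, float]] = []
    for lo, hi in regions:
        if merged and lo < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return MitoticDomainSpec(regions=tuple(merged), t_MD=t_MD)


def insert_mitotic_particles(tissue: DiscretizedTissue, spec: MitoticDomainSpec,
                             shape: EmbryoShape) -> DiscretizedTissue:
    """Insert a midpoint particle into every spring inside the MD regions.

    Pre-existing particle positions are untouched; new particles carry zero
    preferred curvature; both daughter springs keep the global rest length,
    so the stretching energy strictly increases (each affected spring sits
    at roughly half its rest length).
    """
    pos = tissue.positions
    el_lo = embryo_length_fraction(pos[:, 0].max(), shape)
    el_hi = embryo_length_fraction(pos[:, 0].min(), shape)
    for lo, hi in spec.regions:
        if hi < el_lo - 1e-9 or lo > el_hi + 1e-9:
            raise ValueError(
                f"mitotic region ({lo}, {hi}) lies outside the tissue arc "
                f"[{el_lo:.3f}, {el_hi:.3f}]")
    mid = 0.5 * (pos[:-1] + pos[1:])
    mid_el = embryo_length_fraction(mid[:, 0], shape)
    hit = np.zeros(len(mid), dtype=bool)
    for lo, hi in spec.regions:
        hit |= (mid_el >= lo) & (mid_el <= hi)
    # never split springs incident to the fixed end particles
    k = tissue.n_fixed_each_end
    hit[: k] = False
    hit[len(mid) - k:] = False
    if not hit.any():
        return tissue.copy()

    new_pos = []
    new_kap = []
    for i in range(tissue.N - 1):
        new_pos.append(pos[i])
        new_kap.append(tissue.preferred_curvature[i])
        if hit[i]:
            new_pos.append(mid[i])
            new_kap.append(0.0)
    new_pos.append(pos[-1])
    new_kap.append(tissue.preferred_curvature[-1])
    return DiscretizedTissue(
        positions=np.asarray(new_pos),
        rest_length=tissue.rest_length,
        preferred_curvature=np.asarray(new_kap),
        L0=tissue.L0,
        n_fixed_each_end=tissue.n_fixed_each_end,
    )


def furrow_particle_mask(tissue: DiscretizedTissue, spec: CephalicFurrowSpec,
                         shape: EmbryoShape) -> np.ndarray:
    """Particles within arc distance ``width/2`` of the furrow centre."""
    el = embryo_length_fraction(tissue.positions[:, 0], shape)
    if not (el.min() - 1e-9 <= spec.center <= el.max() + 1e-9):
        raise ValueError(
            f"furrow centre {spec.center} lies outside the tissue arc "
            f"[{el.min():.3f}, {el.max():.3f}]")
    s = arc_coordinates(tissue)
    centre_idx = int(np.argmin(np.abs(el - spec.center)))
    return np.abs(s - s[centre_idx]) <= spec.width / 2.0 + 1e-12


def apply_cephalic_furrow(tissue: DiscretizedTissue, spec: CephalicFurrowSpec,
                          shape: EmbryoShape) -> DiscretizedTissue:
    """Set the preferred curvature to ``-kappa_cf`` over the furrow region.

    Idempotent; all particles outside the region keep their preferred
    curvature.
    """
    out = tissue.copy()
    mask = furrow_particle_mask(out, spec, shape)
    out.preferred_curvature[mask] = -spec.kappa_cf / tissue.rest_length
    return out


def build_schedule(md: MitoticDomainSpec | None = None,
                   cf: CephalicFurrowSpec | None = None):
    """Ordered ``(iteration, event)`` list for :func:`blastofold.dynamics.run`.

    The germ band enters only through initialization and never appears as an
    event.  Raises if the same component is scheduled twice.
    """
    events = []
    if cf is not None:
        events.append((int(cf.onset), _FurrowEvent(cf)))
    if md is not None and md.regions:
        events.append((md.onset_iteration, _InsertionEvent(md)))
    names = [type(ev).__name__ for _, ev in events]
    if len(set(names)) != len(names):
        raise ValueError("duplicate events for the same morphogenetic component")
    return sorted(events, key=lambda e: e[0])


class _FurrowEvent:
    def __init__(self, spec: CephalicFurrowSpec):
        self.spec = spec

    def __call__(self, tissue, shape):
        return apply_cephalic_furrow(tissue, self.spec, shape)

    def __repr__(self):
        return f"CephalicFurrow(kappa={self.spec.kappa_cf}, center={self.spec.center})"


class _InsertionEvent:
    def __init__(self, spec: MitoticDomainSpec):
        self.spec = spec

    def __call__(self, tissue, shape):
        return insert_mitotic_particles(tissue, self.spec, shape)

    def __repr__(self):
        return f"MitoticDomains(t_MD={self.spec.t_MD}, n_regions={len(self.spec.regions)})"
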
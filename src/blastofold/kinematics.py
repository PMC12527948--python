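"""Tissue-kinematics statistics and their synthetic-data generators.

These are the image-derived measurements of epithelial deformation that
complement the simulations: the strain-rate magnitude of a velocity field
(from particle image velocimetry, consumed here as gridded data), the
tortuosity of an epithelium outline (a deformation proxy), and the recoil
velocity after laser ablation (initial slope of the edge-to-edge distance).

The synthetic generators produce inputs with known ground truth — linear
velocity fields with prescribed divergence/shear/rotation, outlines of
known tortuosity, and kymograph series of known recoil slope — so the whole
measurement pipeline is testable without any imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VelocityField",
    "StrainRateMap",
    "OutlineTrace",
    "KymographSeries",
    "strain_rate",
    "region_mean_strain",
    "tortuosity",
    "recoil_velocity",
    "make_synthetic_velocity_field",
    "make_synthetic_outline",
    "make_synthetic_kymograph",
    "read_velocity_field_csv",
    "write_velocity_field_csv",
    "read_trace_csv",
]


@dataclass(frozen=True)
class VelocityField:
    """2D velocity vectors on a regular lattice.

    ``vx``/``vy`` are (ny, nx) arrays; row index increases with y, column
    index with x.  ``spacing`` is the lattice pitch in length units;
    velocities are length/time (per minute for the canonical analysis).
    """

    vx: np.ndarray
    vy: np.ndarray
    spacing: float = 1.0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        vx = np.asarray(self.vx, dtype=float)
        vy = np.asarray(self.vy, dtype=float)
        object.__setattr__(self, "vx", vx)
        object.__setattr__(self, "vy", vy)
        if vx.ndim != 2 or vx.shape != vy.shape:
            raise ValueError("vx and vy must be 2D arrays of identical shape")
        if not (np.isfinite(vx).all() and np.isfinite(vy).all()):
            raise ValueError("velocity field contains non-finite values")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vx.shape


@dataclass(frozen=True)
class StrainRateMap:
    """Scalar strain-rate magnitude E >= 0 per lattice cell (1/time)."""

    E: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", E)
        if (E < 0).any():
            raise ValueError("strain-rate magnitude must be nonnegative")


@dataclass(frozen=True)
class OutlineTrace:
    """Ordered polyline of an epithelium outline (length units)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)
        if pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("outline needs at least two 2D points")


@dataclass(frozen=True)
class KymographSeries:
    """Edge-to-edge distance versus time after an ablation cut."""

    time: np.ndarray     # seconds, strictly increasing
    distance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.distance, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "distance", d)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("time and distance must be 1D arrays of equal length")
        if not (np.diff(t) > 0).all():
            raise ValueError("time must be strictly increasing")


def strain_rate(field: VelocityField) -> StrainRateMap:
    """Strain-rate magnitude ``E = |div(v)/2 + (dvy/dx + dvx/dy)/2|``.

    Combines the isotropic (divergence) and anisotropic (shear) parts of
    the velocity gradient; a rigid rotation contributes nothing.  Spatial
    derivatives are central differences, one-sided at the lattice edges.
    """
    ny, nx = field.shape
    if ny < 3 or nx < 3:
        raise ValueError(f"grid must be at least 3x3, got {ny}x{nx}")
    h = field.spacing
    dvx_dx = np.gradient(field.vx, h, axis=1)
    dvx_dy = np.gradient(field.vx, h, axis=0)
    dvy_dx = np.gradient(field.vy, h, axis=1)
    dvy_dy = np.gradient(field.vy, h, axis=0)
    E = np.abs(0.5 * (dvx_dx + dvy_dy) + 0.5 * (dvy_dx + dvx_dy))
    return StrainRateMap(E=E, spacing=h)


def region_mean_strain(srmap: StrainRateMap, region: tuple[int, int, int, int]) -> float:
    """Mean strain rate over a lattice rectangle ``(row0, row1, col0, col1)``.

    Bounds are half-open (numpy slicing); this is the dorsoventral-averaged
    regional statistic used for head–trunk and trunk–germ comparisons.
    """
    r0, r1, c0, c1 = region
    ny, nx = srmap.E.shape
    if not (0 <= r0 < r1 <= ny and 0 <= c0 < c1 <= nx):
        raise ValueError(f"region {region} empty or outside the {ny}x{nx} grid")
    return float(srmap.E[r0:r1, c0:c1].mean())


def tortuosity(trace: OutlineTrace) -> float:
    """Arc-length-to-chord ratio of an outline polyline (>= 1).

    1.0 for a straight line; pi/2 for a half-circle traced between the
    ends of its diameter.  Invariant under rigid motions and uniform
    scaling.
    """
    pts = trace.points
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0.0:
        raise ValueError("outline endpoints coincide; tortuosity undefined")
    arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return arc / chord


def recoil_velocity(series: KymographSeries, window: float = 30.0) -> float:
    """Recoil velocity: OLS slope of distance vs time over the first ``window`` s.

    The window is measured from the first sample (the cut).
    """
    t0 = series.time[0]
    sel = series.time <= t0 + window
    if sel.sum() < 3:
        raise ValueError(
            f"need at least 3 samples within {window} time units, got {int(sel.sum())}")
    slope, _ = np.polyfit(series.time[sel], series.distance[sel], 1)
    return float(slope)


def make_synthetic_velocity_field(divergence: float = 0.0, shear: float = 0.0,
                                  rotation: float = 0.0, noise_sigma: float = 0.0,
                                  grid: tuple[int, int] = (21, 21), spacing: float = 1.0,
                                  seed: int | None = None):
    """Linear velocity field with prescribed gradient components plus noise.

    ``v = (D/2 x + (S - W)/2 y,  (S + W)/2 x + D/2 y)`` with divergence
    ``D``, total shear ``S = dvy/dx + dvx/dy`` and vorticity ``W``, plus
    i.i.d. Gaussian noise on each component.  Returns ``(field, E_true)``
    where ``E_true = |D/2 + S/2|`` is the noise-free strain-rate magnitude.
    """
    ny, nx = grid
    if ny < 3 or nx < 3:
        raise ValueError("grid must be at least 3x3")
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    X, Y = np.meshgrid(x, y)
    vx = 0.5 * divergence * X + 0.5 * (shear - rotation) * Y
    vy = 0.5 * (shear + rotation) * X + 0.5 * divergence * Y
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vx = vx + rng.normal(0.0, noise_sigma, size=vx.shape)
        vy = vy + rng.normal(0.0, noise_sigma, size=vy.shape)
    E_true = abs(0.5 * divergence + 0.5 * shear)
    return VelocityField(vx=vx, vy=vy, spacing=spacing), E_true


def make_synthetic_outline(amplitude: float = 0.2, wavelength: float = 1.0,
                           n_periods: int = 1, n_points: int = 2001):
    """Sinusoidal outline of known tortuosity.

    ``y = A sin(2 pi x / lambda)`` sampled over ``n_periods`` full periods.
    Returns ``(trace, tortuosity_true)`` with the ground truth computed by
    dense quadrature of the arc-length integral.
    """
    if n_points < 2:
        raise ValueError("need at least 2 points")
    span = n_periods * wavelength
    x = np.linspace(0.0, span, n_points)
    k = 2.0 * np.pi / wavelength
    y = amplitude * np.sin(k * x)
    # arc length by quadrature of sqrt(1 + (A k cos(k x))^2) on a fine grid
    xf = np.linspace(0.0, span, 200_001)
    arc = np.trapezoid(np.sqrt(1.0 + (amplitude * k * np.cos(k * xf)) ** 2), xf)
    return OutlineTrace(points=np.column_stack([x, y])), float(arc / span)


def make_synthetic_kymograph(slope: float = 0.2, intercept: float = 5.0,
                             noise_sigma: float = 0.0, duration: float = 30.0,
                             dt: float = 0.2, seed: int | None = None) -> KymographSeries:
    """Edge-distance series ``d(t) = d0 + v t`` with optional Gaussian noise."""
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    d = intercept + slope * t
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        d = d + rng.normal(0.0, noise_sigma, size=t.shape)
    return KymographSeries(time=t, distance=d)


# ---------------------------------------------------------------------------
# delimited-text I/O (long-format CSV with x, y, vx, vy columns)

def write_velocity_field_csv(field: VelocityField, path) -> None:
    ny, nx = field.shape
    X, Y = np.meshgrid(np.arange(nx) * field.spacing, np.arange(ny) * field.spacing)
    pd.DataFrame({
        "x": X.ravel(), "y": Y.ravel(),
        "vx": field.vx.ravel(), "vy": field.vy.ravel(),
    }).to_csv(path, index=False)


def read_velocity_field_csv(path) -> VelocityField:
    df = pd.read_csv(path)
    xs = np.unique(df["x"].to_numpy())
    ys = np.unique(df["y"].to_numpy())
    if len(df) != len(xs) * len(ys):
        raise ValueError("velocity-field CSV is not a complete rectangular grid")
    piv_x = df.pivot_table(index="y", columns="x", values="vx").to_numpy()
    piv_y = df.pivot_table(index="y", columns="x", values="vy").to_numpy()
    spacing = float(xs[1] - xs[0]) if len(xs) > 1 else 1.0
    return VelocityField(vx=piv_x, vy=piv_y, spacing=spacing)


def read_trace_csv(path) -> OutlineTrace:
    df = pd.read_csv(path)
    return OutlineTrace(points=df.iloc[:, :2].to_numpy(dtype=float))
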
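"""Overdamped noisy relaxation of the discretized blastoderm.

The particle motion is the explicit-Euler discretization of

    dr_i/dt = -(L / (K_s tau)) dW*/dr_i + zeta_i

with ``W*`` the discretized stretching + bending energy, timestep
``dt = 1e-5 * tau K_s / L`` and a ground level of Gaussian noise of
per-step, per-component standard deviation ``1e-5 * L``.  Proposed moves
that leave the rigid semi-elliptical shell are repositioned onto the
boundary along the proposed displacement segment.  The first and last two
particles never move.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .geometry import DiscretizedTissue, EmbryoShape

__all__ = [
    "ModelParameters",
    "EnergyBreakdown",
    "SimulationResult",
    "discrete_curvature",
    "total_energy",
    "forces",
    "project_to_boundary",
    "step",
    "run",
    "NumericalInstabilityError",
]


class NumericalInstabilityError(RuntimeError):
    """Raised when particle coordinates stop being finite during integration."""


@dataclass(frozen=True)
class ModelParameters:
    """Mechanical parameters and integration constants.

    The single control parameter of the model is the dimensionless bending
    rigidity ``K_b* = K_b / (K_s L^2)``.  ``dt`` and ``noise_sigma`` default
    to the canonical values ``1e-5 * tau K_s / L`` and ``1e-5 * L`` and are
    overridable only explicitly.
    """

    K_s: float = 1.0
    K_b_star: float = 1.0e-4
    L: float = 1.0
    tau: float = 1.0
    dt: float | None = None
    noise_sigma: float | None = None
    seed: int = 0

    @property
    def K_b(self) -> float:
        return self.K_b_star * self.K_s * self.L**2

    @property
    def timestep(self) -> float:
        return self.dt if self.dt is not None else 1.0e-5 * self.tau * self.K_s / self.L

    @property
    def noise(self) -> float:
        return self.noise_sigma if self.noise_sigma is not None else 1.0e-5 * self.L

    @property
    def mobility(self) -> float:
        """Damping prefactor ``L / (K_s tau)`` of the equation of motion."""
        return self.L / (self.K_s * self.tau)

    def with_seed(self, seed: int) -> "ModelParameters":
        return replace(self, seed=int(seed))


class EnergyBreakdown(NamedTuple):
    W_s: float
    W_b: float

    @property
    def W_T(self) -> float:
        return self.W_s + self.W_b


def discrete_curvature(tissue: DiscretizedTissue, i: int) -> float:
    """Signed discrete curvature at interior particle ``i``.

    Positive for bending that follows the convex boundary, negative for an
    invagination toward the embryo interior; magnitude converges to ``1/R``
    on a circle of radius ``R``.
    """
    if not (1 <= i <= tissue.N - 2):
        raise IndexError(
            f"curvature needs both neighbours: 1 <= i <= {tissue.N - 2}, got {i}")
    p = tissue.positions
    return float(_kernels.signed_curvature(
        p[i, 0] - p[i - 1, 0], p[i, 1] - p[i - 1, 1],
        p[i + 1, 0] - p[i, 0], p[i + 1, 1] - p[i, 1]))


def total_energy(tissue: DiscretizedTissue, params: ModelParameters) -> EnergyBreakdown:
    """Discretized stretching and bending energy per unit length."""
    grad = np.empty_like(tissue.positions)
    Ws, Wb = _kernels.energy_and_forces(
        tissue.positions, tissue.preferred_curvature, tissue.rest_length,
        params.K_s, params.K_b, grad)
    return EnergyBreakdown(float(Ws), float(Wb))


def forces(tissue: DiscretizedTissue, params: ModelParameters) -> np.ndarray:
    """Per-particle force ``-dW*/dr_i`` (zero at the fixed particles)."""
    grad = np.empty_like(tissue.positions)
    _kernels.energy_and_forces(
        tissue.positions, tissue.preferred_curvature, tissue.rest_length,
        params.K_s, params.K_b, grad)
    f = -grad
    f[tissue.fixed_indices] = 0.0
    return f


def project_to_boundary(previous, proposed, shape: EmbryoShape):
    """Confine a proposed particle move to the rigid elliptical shell."""
    previous = np.asarray(previous, dtype=float)
    proposed = np.asarray(proposed, dtype=float)
    if not shape.contains(previous, tol=1e-9):
        raise ValueError(
            "previous position lies outside the rigid boundary; "
            "the integrator invariant is broken")
    x, y = _kernels.project_point(
        previous[0], previous[1], proposed[0], proposed[1],
        shape.L, shape.beta * shape.L)
    return np.array([x, y])


def step(tissue: DiscretizedTissue, params: ModelParameters, shape: EmbryoShape,
         rng: np.random.Generator | int | None = None) -> DiscretizedTissue:
    """Advance the tissue by a single timestep (convenience wrapper).

    ``rng`` seeds the per-step noise; an integer or Generator is accepted.
    The heavy lifting for long runs happens in :func:`run`.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(params.seed if rng is None else int(rng))
    out = tissue.copy()
    free_idx = np.flatnonzero(out.free_mask)
    noise = rng.standard_normal((1, 2 * len(free_idx)))
    rec_pos = np.empty((1, out.N, 2))
    rec_energy = np.empty((1, 2))
    status, it, _ = _kernels.run_chunk(
        out.positions, free_idx, out.preferred_curvature, out.rest_length,
        params.K_s, params.K_b, shape.L, shape.beta,
        params.timestep * params.mobility, params.noise,
        noise, 0, 1, rec_pos, rec_energy, 0)
    if status != _kernels.STATUS_OK:
        raise NumericalInstabilityError(f"non-finite positions at iteration {it}")
    return out


@dataclass
class SimulationResult:
    """Recorded trajectory and energy trace of one simulation run.

    ``frames[k]`` holds particle positions at ``iterations[k]``; after a
    mitotic-domain insertion the particle count changes, so frames are kept
    as a list rather than a single array.  ``energies`` is indexed by
    iteration with raw ``W_s/W_b/W_T`` columns plus columns normalized by
    the initial total energy (NaN when the run starts at zero energy).
    """

    iterations: np.ndarray
    frames: list
    energies: pd.DataFrame
    tissue: DiscretizedTissue
    shape: EmbryoShape
    params: ModelParameters
    record_every: int

    @property
    def n_steps(self) -> int:
        return int(self.iterations[-1])

    def to_hdf5(self, path) -> None:
        """Write the trajectory and energy trace to an HDF5 container.

        Frames are stored as one dataset per recorded iteration (particle
        counts may change at mitotic insertions); the energy trace is a
        column group mirroring :attr:`energies`.
        """
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["record_every"] = self.record_every
            fh.attrs["seed"] = self.params.seed
            fh.attrs["K_b_star"] = self.params.K_b_star
            fh.create_dataset("iterations", data=self.iterations)
            grp = fh.create_group("frames")
            for it, frame in zip(self.iterations, self.frames):
                grp.create_dataset(str(int(it)), data=frame)
            egrp = fh.create_group("energies")
            for col in self.energies.columns:
                egrp.create_dataset(col, data=self.energies[col].to_numpy())


def run(tissue: DiscretizedTissue, shape: EmbryoShape, params: ModelParameters,
        schedule: Sequence[tuple[int, object]] | None = None,
        n_steps: int = 300_000, record_every: int = 100) -> SimulationResult:
    """Run the noisy relaxation, applying scheduled events at their iterations.

    ``schedule`` is an iterable of ``(iteration, event)`` pairs (see
    :mod:`blastofold.programs`); an event scheduled at iteration ``k`` is
    applied after ``k`` completed steps (``k = 0``: before any stepping).
    Fully reproducible for a given ``params.seed``.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    events = sorted(schedule or [], key=lambda e: e[0])
    for it, ev in events:
        if it < 0:
            raise ValueError(f"event scheduled at negative iteration {it}")
        if it > n_steps:
            warnings.warn(
                f"event {ev!r} scheduled at iteration {it} > n_steps={n_steps}; skipped",
                stacklevel=2)
    events = [(it, ev) for it, ev in events if it <= n_steps]

    work = tissue.copy()
    seed_rng = np.random.default_rng(params.seed)

    iterations = [0]
    frames: list[np.ndarray] = []
    energy_rows: list[tuple[float, float]] = []

    def snapshot():
        frames.append(work.positions.copy())
        e = total_energy(work, params)
        energy_rows.append((e.W_s, e.W_b))

    # apply iteration-0 events before the initial snapshot
    pending = list(events)
    while pending and pending[0][0] == 0:
        _, ev = pending.pop(0)
        work = ev(work, shape)
    snapshot()

    current = 0
    chunk_steps = 4096
    boundaries = sorted({it for it, _ in pending} | {n_steps})
    for stop in boundaries:
        seg = stop - current
        if seg > 0:
            # recorded iterations are global multiples of record_every
            n_rec = stop // record_every - current // record_every
            rec_pos = np.empty((max(n_rec, 1), work.N, 2))
            rec_energy = np.empty((max(n_rec, 1), 2))
            free_idx = np.flatnonzero(work.free_mask)
            nf = len(free_idx)
            pref = params.timestep * params.mobility
            step0 = current
            rec_k = 0
            remaining = seg
            while remaining > 0:
                n_sub = min(chunk_steps, remaining)
                if params.noise > 0:
                    noise = seed_rng.standard_normal((n_sub, 2 * nf))
                else:
                    noise = np.zeros((n_sub, 2 * nf))
                status, it, rec_k = _kernels.run_chunk(
                    work.positions, free_idx, work.preferred_curvature,
                    work.rest_length, params.K_s, params.K_b, shape.L,
                    shape.beta, pref, params.noise,
                    noise, step0, record_every, rec_pos, rec_energy, rec_k)
                if status != _kernels.STATUS_OK:
                    raise NumericalInstabilityError(
                        f"non-finite positions at iteration {it}")
                step0 += n_sub
                remaining -= n_sub
            first_rec = (current // record_every + 1) * record_every
            for k in range(rec_k):
                iterations.append(first_rec + k * record_every)
                frames.append(rec_pos[k].copy())
                energy_rows.append((rec_energy[k, 0], rec_energy[k, 1]))
            # a final iteration off the record grid is snapshotted so the
            # trace always ends at n_steps
            if stop == n_steps and stop % record_every != 0:
                iterations.append(stop)
                snapshot()
        current = stop
        fired = [ev for it, ev in pending if it == stop]
        if fired:
            for ev in fired:
                work = ev(work, shape)
            pending = [(it, ev) for it, ev in pending if it > stop]
            iterations.append(stop)
            snapshot()

    # an iteration may appear twice around an event (pre- and post-event
    # snapshots at the same step); downstream consumers group by iteration
    energies = pd.DataFrame(energy_rows, columns=["W_s", "W_b"])
    energies.insert(0, "iteration", np.asarray(iterations))
    energies["W_T"] = energies["W_s"] + energies["W_b"]
    w0 = energies["W_T"].iloc[0]
    for col in ("W_s", "W_b", "W_T"):
        energies[f"{col}_norm"] = energies[col] / w0 if w0 > 0 else np.nan

    return SimulationResult(
        iterations=np.asarray(iterations), frames=frames, energies=energies,
        tissue=work, shape=shape, params=params, record_every=record_every)
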
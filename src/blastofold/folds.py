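"""Fold detection and per-condition summary statistics.

A fold is a contiguous cluster of particles whose Euclidean distance to the
rigid elliptical boundary exceeds a threshold (0.035 L by construction: the
maximum excursion a stress-free tissue reaches under the ground noise; see
:func:`calibrate_threshold`).  Folds inside the cephalic-furrow region are
labelled ``"cephalic_furrow"``, all others ``"ectopic"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .dynamics import ModelParameters, SimulationResult, run
from .geometry import (
    DiscretizedTissue,
    EmbryoShape,
    GermBandSpec,
    embryo_length_fraction,
    initialize_tissue,
)

__all__ = [
    "FoldEvent",
    "FOLD_THRESHOLD_FACTOR",
    "boundary_distance",
    "detect_folds",
    "fold_history",
    "final_folds",
    "calibrate_threshold",
    "bending_energy_peak",
    "summarize_replicates",
]

# fold-detection threshold in units of L (calibrated stress-free excursion)
FOLD_THRESHOLD_FACTOR = 0.035


@dataclass(frozen=True)
class FoldEvent:
    """One detected fold: a maximal above-threshold particle cluster."""

    particle_indices: tuple
    position: float          # axis position of the deepest particle (EL fraction)
    depth: float             # max particle-to-boundary distance in the cluster
    onset_iteration: int | None = None


def boundary_distance(points, shape: EmbryoShape) -> np.ndarray:
    """Distance of each point to the elliptical boundary (Newton projection)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty(len(p))
    _kernels.boundary_distances(p, shape.L, shape.beta * shape.L, out)
    return out


def _clusters(above: np.ndarray):
    """Maximal runs of consecutive True entries."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    return np.split(idx, breaks + 1)


def detect_folds(positions, shape: EmbryoShape,
                 threshold: float | None = None) -> list[FoldEvent]:
    """Detect folds in a single configuration.

    ``positions`` may be a DiscretizedTissue or an (N, 2) array.  Returns
    one :class:`FoldEvent` per maximal contiguous cluster of particles whose
    boundary distance exceeds ``threshold`` (default 0.035 L).
    """
    if isinstance(positions, DiscretizedTissue):
        positions = positions.positions
    if threshold is None:
        threshold = FOLD_THRESHOLD_FACTOR * shape.L
    d = boundary_distance(positions, shape)
    events = []
    for cluster in _clusters(d > threshold):
        deepest = cluster[np.argmax(d[cluster])]
        events.append(FoldEvent(
            particle_indices=tuple(int(i) for i in cluster),
            position=float(embryo_length_fraction(positions[deepest, 0], shape)),
            depth=float(d[deepest]),
        ))
    return events


def fold_history(result: SimulationResult, threshold: float | None = None) -> pd.DataFrame:
    """Per-recorded-frame fold count and maximum excursion."""
    if threshold is None:
        threshold = FOLD_THRESHOLD_FACTOR * result.shape.L
    rows = []
    for it, frame in zip(result.iterations, result.frames):
        d = boundary_distance(frame, result.shape)
        rows.append((it, len(_clusters(d > threshold)), float(d.max())))
    return pd.DataFrame(rows, columns=["iteration", "n_folds", "max_depth"])


def final_folds(result: SimulationResult, threshold: float | None = None) -> list[FoldEvent]:
    """Folds of the final configuration, with onset iterations.

    The onset of a fold is the first recorded iteration at which any
    particle of its final cluster exceeded the threshold (resolution:
    ``record_every`` steps).  Particle indices refer to the final frame;
    onset tracking matches clusters by axis position, which is adequate
    because inserted particles appear at spring midpoints and folds do not
    migrate along the axis.
    """
    if threshold is None:
        threshold = FOLD_THRESHOLD_FACTOR * result.shape.L
    events = detect_folds(result.frames[-1], result.shape, threshold)
    if not events:
        return []
    out = []
    for ev in events:
        onset = None
        for it, frame in zip(result.iterations, result.frames):
            d = boundary_distance(frame, result.shape)
            above = d > threshold
            if not above.any():
                continue
            el = embryo_length_fraction(frame[:, 0], result.shape)
            # axis tolerance for matching an early excursion to this fold
            span = 0.05
            if np.any(above & (np.abs(el - ev.position) <= span)):
                onset = int(it)
                break
        out.append(FoldEvent(ev.particle_indices, ev.position, ev.depth, onset))
    return out


def calibrate_threshold(params: ModelParameters, shape: EmbryoShape,
                        n_segments: int = 200, n_reps: int = 20,
                        n_steps: int = 100_000, record_every: int = 100,
                        seed: int = 0) -> float:
    """Maximum stress-free excursion, in units of L.

    Runs ``n_reps`` stress-free simulations (g = 0, no mitotic domains, no
    furrow) and returns the maximum particle-to-boundary distance over all
    replicates, recorded iterations and particles, divided by L.  This is
    the model's fold-detection threshold (0.035 by construction at the
    default noise level).
    """
    best = 0.0
    for r in range(n_reps):
        tissue = initialize_tissue(shape, n_segments, GermBandSpec(0.0))
        res = run(tissue, shape, params.with_seed(seed + r),
                  n_steps=n_steps, record_every=record_every)
        stack = np.asarray(res.frames)
        best = max(best, float(_kernels.max_boundary_excursion(
            stack, shape.L, shape.beta * shape.L)))
    threshold = best / shape.L
    return threshold


def bending_energy_peak(trace: pd.DataFrame, window: int = 50) -> int:
    """Iteration of the (smoothed) global maximum of the bending energy.

    ``trace`` must carry ``iteration`` and ``W_b`` columns.  The trace is
    smoothed with a centred moving average over ``window`` recorded points;
    ties break to the earliest iteration.
    """
    if len(trace) == 0:
        raise ValueError("empty energy trace")
    wb = trace["W_b"].to_numpy(dtype=float)
    if window > 1 and len(wb) > 1:
        w = min(window, len(wb))
        smooth = pd.Series(wb).rolling(w, center=True, min_periods=1).mean().to_numpy()
    else:
        smooth = wb
    return int(trace["iteration"].to_numpy()[int(np.argmax(smooth))])


def summarize_replicates(results: list[SimulationResult],
                         threshold: float | None = None,
                         peak_window: int = 50) -> dict:
    """Per-condition statistics over replicate runs.

    Returns a dict with the mean/SD of the final fold count, the buckling
    probability (fraction of runs with at least one fold), the mean
    time-to-folding (first fold onset, folding runs only), the pooled fold
    positions, and the replicate energy traces aligned at each run's
    bending-energy peak.
    """
    if not results:
        raise ValueError("need at least one run")
    counts, onsets, positions = [], [], []
    aligned = []
    for res in results:
        folds = final_folds(res, threshold)
        counts.append(len(folds))
        positions.extend(f.position for f in folds)
        run_onsets = [f.onset_iteration for f in folds if f.onset_iteration is not None]
        if run_onsets:
            onsets.append(min(run_onsets))
        peak = bending_energy_peak(res.energies, window=peak_window)
        tr = res.energies.copy()
        tr["offset"] = tr["iteration"] - peak
        aligned.append(tr)
    counts = np.asarray(counts, dtype=float)
    pooled = pd.concat(aligned, ignore_index=True)
    energy_aligned = pooled.groupby("offset")[["W_s", "W_b", "W_T"]].agg(["mean", "std"])
    return {
        "n": len(results),
        "mean_folds": float(counts.mean()),
        "sd_folds": float(counts.std(ddof=0)),
        "buckling_probability": float((counts > 0).mean()),
        "mean_time_to_folding": float(np.mean(onsets)) if onsets else np.nan,
        "fold_positions": np.asarray(positions),
        "energy_aligned": energy_aligned,
    }
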
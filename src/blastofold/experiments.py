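"""In-silico experiment campaigns: phase-diagram sweeps and furrow experiments.

Each campaign runs replicate simulations over a parameter grid, detects
folds, and summarizes fold statistics per condition.  Replicate ``r`` of
every cell uses seed ``base_seed + r``, so conditions are compared at
matched seeds and any campaign is exactly reproducible from its config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import ModelParameters, run
from .folds import final_folds
from .geometry import EmbryoShape, GermBandSpec, initialize_tissue
from .programs import (
    CephalicFurrowSpec,
    MitoticDomainSpec,
    build_schedule,
    default_mitotic_domains,
)

__all__ = [
    "ExperimentConfig",
    "RunSummary",
    "SweepResult",
    "single_run",
    "sweep_phase_diagram",
    "find_reference_rigidity",
    "cf_buffering_experiment",
    "cf_position_experiment",
    "DEFAULT_KB_GRID",
    "DEFAULT_G_GRID",
    "DEFAULT_KAPPA_GRID",
]

log = logging.getLogger(__name__)

DEFAULT_KB_GRID = tuple(np.round(np.arange(0.2e-4, 2.01e-4, 0.2e-4), 10))
DEFAULT_G_GRID = (0.0, 0.1, 0.2, 0.3, 0.4)
DEFAULT_KAPPA_GRID = (0.1, 0.3, 0.5, 1.0, 2.0)

CONDITIONS = ("GB_only", "MD_only", "GB_plus_MD", "CF_variants")


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of a simulation campaign."""

    condition: str = "GB_only"
    K_b_star_grid: tuple = DEFAULT_KB_GRID
    g_grid: tuple = DEFAULT_G_GRID
    kappa_cf_grid: tuple = DEFAULT_KAPPA_GRID
    cf_positions: tuple = (0.65,)
    t_MD: float = 0.0            # mitotic-domain onset, units of 1e5 steps
    n_replicates: int = 20
    base_seed: int = 0
    n_steps: int = 300_000
    n_segments: int = 200
    record_every: int = 2000
    shape: EmbryoShape = field(default_factory=EmbryoShape)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for grid, name in ((self.K_b_star_grid, "K_b_star_grid"),
                           (self.g_grid, "g_grid"),
                           (self.kappa_cf_grid, "kappa_cf_grid")):
            if len(grid) == 0:
                raise ValueError(f"{name} must be non-empty")


@dataclass
class RunSummary:
    """Fold statistics of a single run."""

    seed: int
    n_folds: int
    n_ectopic: int
    n_cf: int
    positions: tuple
    depths: tuple
    first_fold_iteration: float  # NaN if no fold


@dataclass
class SweepResult:
    """Per-cell statistics of a campaign, as a tidy DataFrame.

    ``table`` has one row per grid cell with columns ``K_b_star``, ``g``,
    ``mean_folds``, ``sd_folds``, ``buckling_probability``,
    ``mean_time_to_folding``, ``mean_ectopic`` and ``n``.
    """

    table: pd.DataFrame
    condition: str
    runs: pd.DataFrame  # one row per replicate (fold table)

    def cell(self, K_b_star: float, g: float) -> pd.Series:
        t = self.table
        sel = (np.isclose(t["K_b_star"], K_b_star)) & (np.isclose(t["g"], g))
        if not sel.any():
            raise KeyError(f"no cell at K_b_star={K_b_star}, g={g}")
        return t[sel].iloc[0]


def single_run(shape: EmbryoShape, K_b_star: float, g: float,
               md: MitoticDomainSpec | None, cf: CephalicFurrowSpec | None,
               seed: int, n_steps: int, n_segments: int = 200,
               record_every: int = 2000,
               threshold: float | None = None) -> RunSummary:
    """One simulation under a condition; returns its fold summary.

    A fold is "cephalic furrow" if its position falls inside the furrow
    region of ``cf`` (when given); all other folds are ectopic.  In
    conditions without a programmed furrow every fold is ectopic.
    """
    tissue = initialize_tissue(shape, n_segments, GermBandSpec(g))
    schedule = build_schedule(md=md, cf=cf)
    params = ModelParameters(K_b_star=K_b_star, L=shape.L, seed=seed)
    res = run(tissue, shape, params, schedule=schedule,
              n_steps=n_steps, record_every=record_every)
    folds = final_folds(res, threshold)
    if cf is not None:
        half = cf.width / (4.0 * shape.L) + 0.025  # axis half-window of the region
        is_cf = [abs(f.position - cf.center) <= half for f in folds]
    else:
        is_cf = [False] * len(folds)
    onsets = [f.onset_iteration for f in folds if f.onset_iteration is not None]
    return RunSummary(
        seed=seed,
        n_folds=len(folds),
        n_ectopic=int(sum(1 for c in is_cf if not c)),
        n_cf=int(sum(is_cf)),
        positions=tuple(round(f.position, 4) for f in folds),
        depths=tuple(round(f.depth, 5) for f in folds),
        first_fold_iteration=float(min(onsets)) if onsets else float("nan"),
    )


def _summarize_cell(summaries: list[RunSummary]) -> dict:
    counts = np.array([s.n_folds for s in summaries], dtype=float)
    ect = np.array([s.n_ectopic for s in summaries], dtype=float)
    onsets = np.array([s.first_fold_iteration for s in summaries], dtype=float)
    folding = onsets[np.isfinite(onsets)]
    return {
        "mean_folds": counts.mean(),
        "sd_folds": counts.std(ddof=0),
        "mean_ectopic": ect.mean(),
        "buckling_probability": float((counts > 0).mean()),
        "mean_time_to_folding": float(folding.mean()) if folding.size else float("nan"),
        "n": len(summaries),
    }


def _cell_key(condition, K_b_star, g, kappa, center, t_MD):
    return f"{condition}|{K_b_star:.6e}|{g:.3f}|{kappa:.3f}|{center:.3f}|{t_MD:.3f}"


class _Checkpoint:
    """JSON-lines checkpoint so an interrupted sweep resumes per cell."""

    def __init__(self, path: Path | None):
        self.path = Path(path) if path else None
        self.done: dict[str, dict] = {}
        if self.path and self.path.exists():
            for line in self.path.read_text().splitlines():
                if line.strip():
                    rec = json.loads(line)
                    self.done[rec["key"]] = rec

    def get(self, key):
        return self.done.get(key)

    def put(self, key, cell, runs) -> None:
        rec = {"key": key, "cell": cell, "runs": runs}
        self.done[key] = rec
        if self.path:
            with self.path.open("a") as fh:
                fh.write(json.dumps(rec) + "\n")


def sweep_phase_diagram(config: ExperimentConfig,
                        checkpoint: str | Path | None = None) -> SweepResult:
    """Replicated sweep over (K_b*, g) for the configured condition.

    ``GB_only`` runs without mitotic domains; ``MD_only`` forces g = 0 and
    inserts the default mitotic domains at ``t_MD``; ``GB_plus_MD`` varies
    both.  Failed runs are logged and the cell's ``n`` reduced.
    """
    shape = config.shape
    if config.condition == "MD_only":
        cells = [(kb, 0.0) for kb in config.K_b_star_grid]
    else:
        cells = [(kb, g) for g in config.g_grid for kb in config.K_b_star_grid]
    md = (default_mitotic_domains(shape, t_MD=config.t_MD)
          if config.condition in ("MD_only", "GB_plus_MD") else None)

    ckpt = _Checkpoint(checkpoint)
    rows, run_rows = [], []
    for kb, g in cells:
        key = _cell_key(config.condition, kb, g, 0.0, 0.0, config.t_MD)
        cached = ckpt.get(key)
        if cached is not None:
            cell, runs = cached["cell"], cached["runs"]
        else:
            summaries = []
            for r in range(config.n_replicates):
                seed = config.base_seed + r
                try:
                    summaries.append(single_run(
                        shape, kb, g, md, None, seed,
                        config.n_steps, config.n_segments, config.record_every))
                except Exception:
                    log.exception("run failed: K_b*=%g g=%g seed=%d", kb, g, seed)
            cell = _summarize_cell(summaries)
            runs = [asdict(s) for s in summaries]
            ckpt.put(key, cell, runs)
        rows.append({"K_b_star": kb, "g": g, **cell})
        for rec in runs:
            run_rows.append({"K_b_star": kb, "g": g, **rec})
    return SweepResult(table=pd.DataFrame(rows), condition=config.condition,
                       runs=pd.DataFrame(run_rows))


class NoSolutionError(RuntimeError):
    """The criterion is not met anywhere on the sweep grid."""


def find_reference_rigidity(md_only: SweepResult, gb_only: SweepResult,
                            fold_criterion: float = 1.0) -> dict:
    """Smallest grid K_b* with mean fold count below ``fold_criterion`` in
    both the mitotic-domain-only and the germ-band-only (maximum g) sweeps.

    Mirrors the criterion used to place the real embryo in the phase space:
    neither mitotic domains nor the germ band alone may drive ectopic
    folding.  Returns the value and its bracketing grid neighbours.
    """
    md_t = md_only.table[np.isclose(md_only.table["g"], 0.0)]
    g_max = gb_only.table["g"].max()
    gb_t = gb_only.table[np.isclose(gb_only.table["g"], g_max)]
    grid = np.asarray(sorted(set(np.round(md_t["K_b_star"], 12))
                             & set(np.round(gb_t["K_b_star"], 12))))
    if grid.size == 0:
        raise ValueError("sweeps share no K_b* grid values")
    md_mean = md_t.set_index(np.round(md_t["K_b_star"], 12))["mean_folds"]
    gb_mean = gb_t.set_index(np.round(gb_t["K_b_star"], 12))["mean_folds"]
    for i, kb in enumerate(grid):
        if md_mean[kb] < fold_criterion and gb_mean[kb] < fold_criterion:
            return {
                "K_b_star": float(kb),
                "bracket_low": float(grid[i - 1]) if i > 0 else float("nan"),
                "bracket_high": float(grid[i + 1]) if i + 1 < len(grid) else float("nan"),
                "g_max": float(g_max),
            }
    profile = pd.DataFrame({"K_b_star": grid,
                            "md_mean": md_mean.loc[grid].to_numpy(),
                            "gb_mean": gb_mean.loc[grid].to_numpy()})
    raise NoSolutionError(
        f"mean fold count never falls below {fold_criterion} on the grid:\n{profile}")


def cf_buffering_experiment(config: ExperimentConfig,
                            kappa_cf: float = 2.0,
                            K_b_star: float | None = None,
                            g: float = 0.0,
                            delay_t_MD: float = 1.0) -> pd.DataFrame:
    """Three-condition furrow experiment: MD only, MD+CF, delayed MD+CF.

    Runs matched-seed replicates of (i) mitotic domains alone, (ii) mitotic
    domains and cephalic furrow starting together, (iii) cephalic furrow
    first with mitotic domains delayed by ``delay_t_MD`` (1 unit = 1e5
    steps).  Returns a tidy table of per-replicate ectopic/furrow fold
    counts and positions per condition.
    """
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    shape = config.shape
    kb = K_b_star if K_b_star is not None else config.K_b_star_grid[0]
    cf = CephalicFurrowSpec(kappa_cf=kappa_cf)
    conditions = {
        "MD_only": (default_mitotic_domains(shape, 0.0), None),
        "MD_plus_CF": (default_mitotic_domains(shape, 0.0), cf),
        "delayed_MD_plus_CF": (default_mitotic_domains(shape, delay_t_MD), cf),
    }
    rows = []
    for name, (md, cf_spec) in conditions.items():
        for r in range(config.n_replicates):
            seed = config.base_seed + r
            s = single_run(shape, kb, g, md, cf_spec, seed,
                           config.n_steps, config.n_segments, config.record_every)
            head = sum(1 for p, d in zip(s.positions, s.depths)
                       if p >= 0.5 and not (cf_spec is not None and abs(p - cf.center) <= 0.05))
            rows.append({"condition": name, "seed": seed, "K_b_star": kb, "g": g,
                         "kappa_cf": kappa_cf if cf_spec else 0.0,
                         "n_folds": s.n_folds, "n_ectopic": s.n_ectopic,
                         "n_cf": s.n_cf, "n_head_ectopic": head,
                         "positions": s.positions})
    return pd.DataFrame(rows)


def cf_robustness_sweep(config: ExperimentConfig,
                        K_b_star: float = 1.0e-4,
                        g: float = 0.0,
                        with_md: bool = True) -> pd.DataFrame:
    """Sweep the furrow strength and score invagination robustness.

    For each ``kappa_cf`` in the grid, runs matched-seed replicates at the
    reference rigidity with the furrow programmed from iteration 0 (by
    default alongside the mitotic domains, whose compression supplies the
    material the invagination absorbs — without any compression source no
    intrinsic-curvature invagination can exceed the fold threshold in this
    model).  A strength is *robust* when every replicate ends with exactly
    one fold, located at the furrow.  The returned frame carries a
    ``robust_threshold`` attr: the smallest robust strength on the grid
    (NaN when none qualifies).
    """
    shape = config.shape
    md = default_mitotic_domains(shape, t_MD=0.0) if with_md else None
    rows = []
    for kappa in config.kappa_cf_grid:
        cf = CephalicFurrowSpec(kappa_cf=kappa)
        for r in range(config.n_replicates):
            seed = config.base_seed + r
            s = single_run(shape, K_b_star, g, md, cf, seed,
                           config.n_steps, config.n_segments, config.record_every)
            rows.append({"kappa_cf": kappa, "seed": seed, "n_folds": s.n_folds,
                         "n_cf": s.n_cf, "n_ectopic": s.n_ectopic,
                         "positions": s.positions})
    df = pd.DataFrame(rows)
    robust = (df.assign(ok=(df["n_folds"] == 1) & (df["n_cf"] == 1))
              .groupby("kappa_cf")["ok"].all())
    df.attrs["robust_by_kappa"] = robust.to_dict()
    qualifying = [k for k, ok in sorted(robust.items()) if ok]
    df.attrs["robust_threshold"] = float(qualifying[0]) if qualifying else float("nan")
    return df


def cf_position_experiment(config: ExperimentConfig,
                           kappa_cf: float = 2.0,
                           K_b_star: float = 1.0e-4,
                           g_values: tuple = (0.0, 0.4)) -> pd.DataFrame:
    """Effect of the furrow's axis position on ectopic folding.

    For every position in ``config.cf_positions`` and every germ-band state
    in ``g_values``, runs matched-seed replicates with mitotic domains and
    a furrow at that position; reports mean ectopic folds (total, head
    region >= 0.5, posterior < 0.5) per cell and flags the positions
    minimizing ectopic folding for each g.
    """
    shape = config.shape
    md = default_mitotic_domains(shape, t_MD=config.t_MD)
    rows = []
    for g in g_values:
        for center in config.cf_positions:
            cf = CephalicFurrowSpec(kappa_cf=kappa_cf, center=center)
            for r in range(config.n_replicates):
                seed = config.base_seed + r
                s = single_run(shape, K_b_star, g, md, cf, seed,
                               config.n_steps, config.n_segments,
                               config.record_every)
                ect = [p for p, c in zip(s.positions, [abs(p - center) <= 0.05 for p in s.positions]) if not c]
                rows.append({"g": g, "cf_position": center, "seed": seed,
                             "n_folds": s.n_folds, "n_ectopic": s.n_ectopic,
                             "n_cf": s.n_cf,
                             "n_head_ectopic": sum(1 for p in ect if p >= 0.5),
                             "n_posterior_ectopic": sum(1 for p in ect if p < 0.5)})
    df = pd.DataFrame(rows)
    summary = (df.groupby(["g", "cf_position"])["n_ectopic"].mean()
               .rename("mean_ectopic").reset_index())
    best = summary.loc[summary.groupby("g")["mean_ectopic"].idxmin()]
    df.attrs["summary"] = summary
    df.attrs["best_positions"] = {float(r["g"]): float(r["cf_position"])
                                  for _, r in best.iterrows()}
    return df
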
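"""Monte-Carlo size/power study over the scenario grid.

For each scenario cell (treatment-effect scenario x latent correlation x
censoring level x misclassification setting) the runner simulates many
trials, applies the three tests to both causes of death and tallies the
empirical rejection probability at the nominal level.  Cells where both
null hypotheses hold report empirical size; the others report empirical
power.  Determinism is guaranteed by per-cell, per-replication seed
derivation, never by execution order.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .compare import _battery_statistics
from .dataset import read_dataset, write_dataset
from .simdata import ScenarioConfig, calibrate_censoring_bound, preset, simulate_trial

__all__ = ["RejectionTable", "run_scenario", "run_grid", "read_dataset",
           "write_dataset", "read_results", "write_results",
           "RHO_GRID", "CENSOR_TARGETS", "MISCLASS_PROBS"]

log = logging.getLogger("crtests.study")

TESTS = ("Pe", "CS", "Gr")
CAUSES = ("cancer", "noncancer")

#: The study grids: five latent correlations, three censoring levels, with
#: and without a 20% misrecorded cause of death.
RHO_GRID = (-0.75, -0.375, 0.0, 0.375, 0.75)
CENSOR_TARGETS = (0.0, 0.25, 0.5)
MISCLASS_PROBS = (0.0, 0.2)


@dataclass
class RejectionTable:
    """Empirical rejection probabilities for one scenario cell.

    ``cells`` maps (test, cause, rho) -> rejection probability; failures
    counts replications where a statistic was undefined (tallied as
    non-rejections).
    """

    scenario: str
    censor_target: float
    misclass_prob: float
    level: float
    n_reps: int
    cells: Dict[Tuple[str, str, float], float]
    failures: Dict[Tuple[str, str, float], int]

    def cell(self, test: str, cause: str, rho: float) -> float:
        return self.cells[(test, cause, float(rho))]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"scenario": self.scenario, "censor_target": self.censor_target,
             "misclass_prob": self.misclass_prob, "level": self.level,
             "n_reps": self.n_reps, "test": t, "cause": c, "rho": r,
             "reject_prob": p,
             "n_undefined": self.failures.get((t, c, r), 0)}
            for (t, c, r), p in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RejectionTable":
        first = frame.iloc[0]
        cells = {(row.test, row.cause, float(row.rho)): float(row.reject_prob)
                 for row in frame.itertuples()}
        failures = {(row.test, row.cause, float(row.rho)): int(row.n_undefined)
                    for row in frame.itertuples()}
        return cls(scenario=str(first["scenario"]),
                   censor_target=float(first["censor_target"]),
                   misclass_prob=float(first["misclass_prob"]),
                   level=float(first["level"]), n_reps=int(first["n_reps"]),
                   cells=cells, failures=failures)


def run_scenario(config: ScenarioConfig,
                 rho_grid: Sequence[float] = RHO_GRID,
                 level: float = 0.05,
                 progress: bool = False) -> RejectionTable:
    """Run one (scenario, censoring, misclassification) cell over a rho grid.

    For every rho and replication a fresh trial is simulated, the three
    tests are applied to both causes and rejections at ``level`` are
    tallied.  Undefined statistics count as non-rejections and are logged.
    """
    if not rho_grid:
        raise ValueError("rho_grid must be non-empty")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    threshold = chi2.isf(level, 1)
    cells: Dict[Tuple[str, str, float], float] = {}
    failures: Dict[Tuple[str, str, float], int] = {}
    for rho in rho_grid:
        cfg = replace(config, rho=float(rho))
        bound = calibrate_censoring_bound(cfg)
        counts = {(t, c): 0 for t in TESTS for c in CAUSES}
        nans = {(t, c): 0 for t in TESTS for c in CAUSES}
        for rep in range(cfg.n_reps):
            data = simulate_trial(cfg, rep, censor_bound=bound)
            stats = _battery_statistics(data.time, data.status, data.arm,
                                        data.rec_time)
            for key, value in stats.items():
                if np.isnan(value):
                    nans[key] += 1
                elif value > threshold:
                    counts[key] += 1
        for (t, c), k in counts.items():
            cells[(t, c, float(rho))] = k / cfg.n_reps
            failures[(t, c, float(rho))] = nans[(t, c)]
            if nans[(t, c)]:
                log.warning("%s/%s rho=%s: %d undefined statistics",
                            t, c, rho, nans[(t, c)])
        if progress:
            print(f"  rho={rho:+.3f} done ({cfg.n_reps} reps)",
                  file=sys.stderr, flush=True)
    return RejectionTable(scenario=config.name or "custom",
                          censor_target=config.censor_target,
                          misclass_prob=config.misclass_prob, level=level,
                          n_reps=config.n_reps, cells=cells, failures=failures)


def _table_filename(scenario: str, censor: float, mis: float) -> str:
    return f"rejection_{scenario}_cens{int(round(censor * 100)):02d}" \
           f"_mis{int(round(mis * 100)):02d}.csv"


def run_grid(presets: Iterable[str] = tuple(f"scenario{i}" for i in (1, 2, 3, 4)),
             censor_targets: Sequence[float] = CENSOR_TARGETS,
             misclass_probs: Sequence[float] = MISCLASS_PROBS,
             rho_grid: Sequence[float] = RHO_GRID,
             n_reps: int = 10_000,
             seed: int = 0,
             n_subjects: int = 1000,
             level: float = 0.05,
             out_dir: Optional[str] = None,
             progress: bool = False) -> List[RejectionTable]:
    """Run the full experiment grid; one RejectionTable per cell.

    With ``out_dir`` set, each table is written as soon as it is computed
    and pre-existing tables are loaded instead of recomputed, so an
    interrupted run resumes where it stopped.
    """
    presets = list(presets)
    if not presets or not censor_targets or not list(misclass_probs):
        raise ValueError("presets, censor_targets and misclass_probs must be non-empty")
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    tables: List[RejectionTable] = []
    for name, cens, mis in product(presets, censor_targets, misclass_probs):
        target = out / _table_filename(name, cens, mis) if out else None
        if target and target.exists():
            log.info("reusing %s", target)
            tables.append(read_results(target))
            continue
        if progress:
            print(f"cell {name} censoring={cens} misclass={mis}",
                  file=sys.stderr, flush=True)
        cfg = preset(name, censor_target=cens, misclass_prob=mis,
                     n_reps=n_reps, seed=seed, n_subjects=n_subjects)
        table = run_scenario(cfg, rho_grid, level, progress=progress)
        tables.append(table)
        if target:
            write_results(table, target)
    return tables


def write_results(table: RejectionTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_results(path) -> RejectionTable:
    return RejectionTable.from_frame(pd.read_csv(path))
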
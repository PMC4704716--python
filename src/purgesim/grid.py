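"""Experiment-grid driver: burn-ins plus derived lines over a parameter grid.

A grid cell is one combination of deleterious effect (s, h), genome length
(L or free recombination), line size N and maintenance scenario.  Per cell
the driver simulates replicate base populations, summarizes their equilibrium
genetics (mean fitness, inbreeding load, diversity, associative
overdominance, adjacent-site LD and recombination), estimates the realized
inbreeding depression rate from early N = 2 MSD lines, and aggregates
replicate line trajectories.  All outputs are TSV; a finished cell is
skipped on re-run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import popgen_stats as ps
from .config import LineConfig, Scenario, SimulationConfig
from .engine import burn_in, recombination_fraction
from .ip_theory import estimate_delta
from .line_experiment import aggregate_lines, run_line
from .io import write_table

__all__ = ["ExperimentGrid", "run_grid"]

log = logging.getLogger("purgesim.grid")

_FREE = "FR"  # marker for free recombination in L_values


@dataclass
class ExperimentGrid:
    """Cartesian experiment grid with scaled-down defaults.

    The default base size and burn-in (N_b = 200, 2000 generations) keep the
    analytic equilibrium targets of the full-scale study: the genomic
    deleterious rate stays at 0.1 so mean fitness tends to exp(-2 U_del h>0),
    and the neutral rate is rescaled to preserve 4 N_b mu = 0.02 so the
    mutation-drift diversity expectation stays 0.0196.
    """

    s_values: tuple = (0.1,)
    h_values: tuple = (0.5,)
    L_values: tuple = (_FREE,)  # "FR" or a map length in Morgans
    N_values: tuple = (10,)
    scenarios: tuple = (Scenario.MSD, Scenario.MD)
    N_b: int = 200
    T_burnin: int = 2000
    U_del: float = 0.1
    U_neu: float = 0.025
    n_s: int = 20000
    n_n: int = 1000
    n_base_replicates: int = 20
    n_lines_per_base: int = 10
    T_lines: int = 100
    n_delta_lines: int = 50
    master_seed: int = 0

    def cells(self):
        idx = 0
        for s in self.s_values:
            for h in self.h_values:
                for L in self.L_values:
                    yield idx, (s, h, L)
                    idx += 1

    def cell_config(self, s: float, h: float, L, seed: int) -> SimulationConfig:
        free = L == _FREE
        return SimulationConfig(
            s=s, h=h,
            L=None if free else float(L),
            free_recombination=free,
            n_s=self.n_s, n_n=self.n_n,
            N_b=self.N_b,
            U_del=self.U_del, U_neu=self.U_neu,
            T_burnin=self.T_burnin,
            seed=seed,
        )


def _cell_name(s: float, h: float, L) -> str:
    L_tag = "FR" if L == _FREE else f"L{L}"
    return f"s{s}_h{h}_{L_tag}"


def _base_summary(pop, config: SimulationConfig) -> dict:
    q_sel = ps.site_frequencies(pop, selective=True)
    q_neu = ps.site_frequencies(pop, selective=False)
    c_adj = recombination_fraction(config.L, config.n_sites, config.free_recombination)
    return {
        "w": float(np.mean(pop.fitness)),
        "B": ps.inbreeding_load(q_sel, config.d),
        "H": ps.neutral_diversity(q_neu, config.n_n),
        "r_wH": ps.corr_fitness_heterozygosity(pop),
        "ld_r": ps.mean_adjacent_ld(pop),
        "c": ps.mean_adjacent_c(pop, c_adj),
    }


def run_grid(grid: ExperimentGrid, out_dir, progress: bool = False) -> pd.DataFrame:
    """Execute every cell and return the combined equilibrium summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = []
    for idx, (s, h, L) in grid.cells():
        name = _cell_name(s, h, L)
        cell_dir = out_dir / name
        summary_path = cell_dir / "summary.tsv"
        if summary_path.exists():
            log.info("cell %s already finished; skipping", name)
            summaries.append(pd.read_csv(summary_path, sep="\t"))
            continue
        try:
            summaries.append(_run_cell(grid, idx, s, h, L, cell_dir, progress))
        except Exception:
            log.exception("cell %s failed; continuing with the next cell", name)
    combined = (
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    )
    write_table(combined, out_dir / "summary.tsv")
    return combined


def _run_cell(grid, idx, s, h, L, cell_dir: Path, progress: bool) -> pd.DataFrame:
    cell_dir.mkdir(parents=True, exist_ok=True)
    name = _cell_name(s, h, L)
    cell_seed = grid.master_seed + 100_000 * idx

    bases = []
    stats = []
    iterator = range(grid.n_base_replicates)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc=f"{name} burn-in")
    for r in iterator:
        config = grid.cell_config(s, h, L, seed=cell_seed + r)
        rng = np.random.default_rng(config.seed)
        pop = burn_in(config, rng)
        bases.append((pop, config))
        stats.append(_base_summary(pop, config))
        log.info("cell %s base %d/%d done", name, r + 1, grid.n_base_replicates)
    base_frame = pd.DataFrame(stats)

    delta = _realized_delta(grid, bases, cell_seed)

    row = {"s": s, "h": h, "d": s * (0.5 - h), "L": "FR" if L == _FREE else L}
    for col in base_frame.columns:
        values = base_frame[col].to_numpy(dtype=float)
        ok = ~np.isnan(values)
        if not ok.any():
            log.warning("cell %s: statistic %s undefined in every base", name, col)
        row[f"{col}_mean"] = float(np.mean(values[ok])) if ok.any() else np.nan
        row[f"{col}_se"] = (
            float(np.std(values[ok], ddof=1) / np.sqrt(ok.sum())) if ok.sum() > 1 else np.nan
        )
    row["delta"] = delta
    summary = pd.DataFrame([row])
    write_table(summary, cell_dir / "summary.tsv")

    for N in grid.N_values:
        for scenario in grid.scenarios:
            scenario = Scenario(scenario)
            trajectories = []
            for b, (pop, config) in enumerate(bases):
                line_config = LineConfig(
                    N=N,
                    T=grid.T_lines,
                    scenario=scenario,
                    n_replicates=grid.n_lines_per_base,
                    seed=cell_seed + 10_000 + 97 * b,
                )
                for r in range(line_config.n_replicates):
                    rng = np.random.default_rng(line_config.seed + r)
                    traj, _ = run_line(pop, line_config, config, rng)
                    trajectories.append(traj)
            agg = aggregate_lines(trajectories)
            write_table(agg, cell_dir / f"trajectory_N{N}_{scenario.value}.tsv")
            log.info("cell %s lines N=%d %s done", name, N, scenario.value)
    return summary


def _realized_delta(grid, bases, cell_seed: int) -> float:
    """Inbreeding depression rate from t = 3 fitness in N = 2 MSD lines."""
    w0 = float(np.mean([np.mean(pop.fitness) for pop, _ in bases]))
    w3 = []
    for b, (pop, config) in enumerate(bases):
        line_config = LineConfig(
            N=2, T=3, scenario=Scenario.MSD,
            n_replicates=grid.n_delta_lines,
            seed=cell_seed + 50_000 + 89 * b,
        )
        for r in range(line_config.n_replicates):
            rng = np.random.default_rng(line_config.seed + r)
            traj, _ = run_line(pop, line_config, config, rng)
            w3.append(traj["w_mean"][3])
    w3_mean = float(np.mean(w3))
    if w3_mean <= 0:
        return float("nan")
    return estimate_delta(w0, w3_mean)
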
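"""Reduced-size lines derived from a base population.

Each generation a line's ``N`` breeders produce ``n_offspring`` individuals
(parent draws fitness-weighted under MSD, uniform under MD); all statistics
are computed on that full offspring cohort; ``N`` offspring are then sampled
uniformly as the next breeders, and the gametes each breeder contributed to
the chosen breeding pool are counted for ``V_k``.  The pedigree of every
produced individual is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import popgen_stats as ps
from .config import LineConfig, SimulationConfig
from .engine import Population, advance_generation
from .inbreeding_metrics import CoancestryState, f_from_ne_series, f_wright, ne_from_vk

__all__ = [
    "LineTrajectory",
    "PedigreeRecord",
    "found_line",
    "run_line",
    "run_replicate_lines",
    "aggregate_lines",
]

_STAT_COLUMNS = [
    "w_mean", "H", "B", "f_p", "f_N", "f_Vk", "Vk", "Ne", "V_A", "V_D", "r_wH",
]


@dataclass
class PedigreeRecord:
    """Recorded pedigree of one line.

    ``table`` has columns (generation, id, parent1, parent2) with 1-based ids
    and 0 marking a founder's unknown parents; parents always belong to the
    previous generation's breeder set.
    """

    table: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.table, columns=["generation", "id", "parent1", "parent2"]
        )

    def parent_indices(self) -> np.ndarray:
        """(n, 2) 0-based parent array suitable for ``pedigree_inbreeding``."""
        return self.table[:, 2:4].astype(np.int64) - 1


@dataclass
class LineTrajectory:
    """Per-generation statistics of one line (index 0 is the founder set).

    ``w0`` and ``H0`` are the base population's mean fitness and neutral
    diversity at founding, the reference points for predictions and for
    relative diversity ``H_t/H_0``.
    """

    w0: float
    H0: float
    data: pd.DataFrame = field(repr=False)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    @property
    def T(self) -> int:
        return len(self.data) - 1


def found_line(base: Population, N: int, rng: np.random.Generator) -> Population:
    """Sample ``N`` founders uniformly without replacement from the base."""
    if N > base.size:
        raise ValueError(f"cannot found a line of {N} from a base of {base.size}")
    chosen = rng.choice(base.size, size=N, replace=False)
    return base.subset(np.sort(chosen))


def _cohort_stats(pop: Population, sim_config: SimulationConfig) -> dict:
    q_sel = ps.site_frequencies(pop, selective=True)
    q_neu = ps.site_frequencies(pop, selective=False)
    va, vd = ps.variance_components(q_sel, sim_config.s, sim_config.h)
    try:
        r_wh = ps.corr_fitness_heterozygosity(pop)
    except ValueError:
        r_wh = float("nan")
    return {
        "w_mean": float(np.mean(pop.fitness)),
        "H": ps.neutral_diversity(q_neu, pop.n_n),
        "B": ps.inbreeding_load(q_sel, sim_config.d),
        "V_A": va,
        "V_D": vd,
        "r_wH": r_wh,
    }


def run_line(
    base: Population,
    line_config: LineConfig,
    sim_config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[LineTrajectory, PedigreeRecord]:
    """Found and run one line for ``T`` generations; record everything."""
    N = line_config.N
    breeders = found_line(base, N, rng)
    coancestry = CoancestryState.founders(N)
    w0 = float(np.mean(base.fitness))
    h0 = ps.neutral_diversity(ps.site_frequencies(base, selective=False), base.n_n)

    rows = []
    founder_row = _cohort_stats(breeders, sim_config)
    founder_row.update(f_p=0.0, f_N=0.0, f_Vk=0.0,
                       Vk=float("nan"), Ne=float("nan"))
    rows.append(founder_row)

    pedigree = [np.column_stack([
        np.zeros(N, dtype=np.int64),
        np.arange(1, N + 1),
        np.zeros(N, dtype=np.int64),
        np.zeros(N, dtype=np.int64),
    ])]
    breeder_ids = np.arange(1, N + 1)
    next_id = N + 1

    ne_series: list[float] = []
    for t in range(1, line_config.T + 1):
        offspring, _, parent_pairs = advance_generation(
            breeders, sim_config, line_config.scenario, line_config.n_offspring, rng
        )
        stats = _cohort_stats(offspring, sim_config)
        stats["f_p"] = float(np.mean(coancestry.offspring_inbreeding(parent_pairs)))
        stats["f_N"] = f_wright(N, t)

        n_off = line_config.n_offspring
        ids = np.arange(next_id, next_id + n_off)
        next_id += n_off
        pedigree.append(np.column_stack([
            np.full(n_off, t, dtype=np.int64),
            ids,
            breeder_ids[parent_pairs[:, 0]],
            breeder_ids[parent_pairs[:, 1]],
        ]))

        chosen = np.sort(rng.choice(n_off, size=N, replace=False))
        k = np.bincount(parent_pairs[chosen].ravel(), minlength=N)
        vk = float(np.var(k, ddof=1)) if N > 1 else float("nan")
        ne = ne_from_vk(N, vk) if N > 1 else float("nan")
        if N > 1:
            ne_series.append(ne)
            stats["f_Vk"] = f_from_ne_series(ne_series)
        else:
            stats["f_Vk"] = float("nan")
        stats["Vk"] = vk
        stats["Ne"] = ne
        rows.append(stats)

        coancestry = coancestry.next_generation(parent_pairs[chosen])
        breeders = offspring.subset(chosen)
        breeder_ids = ids[chosen]

    data = pd.DataFrame(rows, columns=_STAT_COLUMNS)
    data.insert(0, "t", np.arange(line_config.T + 1))
    trajectory = LineTrajectory(w0=w0, H0=h0, data=data)
    return trajectory, PedigreeRecord(table=np.concatenate(pedigree, axis=0))


def run_replicate_lines(
    base: Population,
    line_config: LineConfig,
    sim_config: SimulationConfig,
    keep_pedigrees: bool = False,
) -> list:
    """Run ``line_config.n_replicates`` lines; replicate r uses seed
    ``line_config.seed + r``."""
    out = []
    for r in range(line_config.n_replicates):
        rng = np.random.default_rng(line_config.seed + r)
        traj, ped = run_line(base, line_config, sim_config, rng)
        out.append((traj, ped) if keep_pedigrees else traj)
    return out


def aggregate_lines(trajectories) -> pd.DataFrame:
    """Element-wise mean and standard error across replicate lines.

    Returns a tidy frame with one row per (generation, statistic) and columns
    ``mean`` and ``se``.  NaN entries of a statistic (e.g. an undefined
    correlation) are excluded from that cell's average.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    lengths = {traj.T for traj in trajectories}
    if len(lengths) != 1:
        raise ValueError("trajectories have unequal lengths")
    records = []
    t = trajectories[0]["t"]
    for stat in _STAT_COLUMNS:
        stack = np.vstack([traj[stat] for traj in trajectories])
        valid = ~np.isnan(stack)
        n_eff = valid.sum(axis=0)
        sums = np.where(valid, stack, 0.0).sum(axis=0)
        mean = np.where(n_eff > 0, sums / np.maximum(n_eff, 1), np.nan)
        dev = np.where(valid, (stack - mean) ** 2, 0.0).sum(axis=0)
        var = np.where(n_eff > 1, dev / np.maximum(n_eff - 1, 1), np.nan)
        se = np.sqrt(var / np.maximum(n_eff, 1))
        for i in range(stack.shape[1]):
            records.append((int(t[i]), stat, mean[i], se[i]))
    return pd.DataFrame(records, columns=["generation", "statistic", "mean", "se"])
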
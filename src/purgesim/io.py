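"""Snapshot and table formats.

Base populations are stored as ``.npz`` containers (haplotype matrix,
positions, fixation ledger, fitness and an embedded JSON copy of the
configuration, plus a format version).  Pedigrees and all result tables are
tab-separated text with headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .engine import Population

__all__ = [
    "save_population",
    "load_population",
    "write_pedigree",
    "read_pedigree",
    "write_table",
]

_FORMAT_VERSION = 1


def save_population(pop: Population, config: SimulationConfig, path) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        format_version=np.int64(_FORMAT_VERSION),
        haplotypes=pop.haplotypes,
        positions=pop.positions,
        n_fixed_del=np.int64(pop.n_fixed_del),
        retired=np.array(sorted(pop.retired), dtype=np.int64),
        fitness=pop.fitness if pop.fitness is not None else np.empty(0),
        config_json=np.bytes_(config.to_json().encode()),
    )


def load_population(path) -> tuple[Population, SimulationConfig]:
    with np.load(Path(path)) as data:
        version = int(data["format_version"])
        if version != _FORMAT_VERSION:
            raise ValueError(f"unsupported snapshot format version {version}")
        config = SimulationConfig.from_json(bytes(data["config_json"]).decode())
        fitness = data["fitness"]
        pop = Population(
            haplotypes=data["haplotypes"],
            positions=data["positions"],
            n_s=config.n_s,
            n_n=config.n_n,
            n_fixed_del=int(data["n_fixed_del"]),
            retired=set(int(p) for p in data["retired"]),
            fitness=fitness if fitness.size else None,
        )
    return pop, config


def write_pedigree(pedigree, path) -> None:
    """Tab-separated pedigree: generation, id, parent1, parent2 (founders 0)."""
    frame = pedigree.to_frame() if hasattr(pedigree, "to_frame") else pd.DataFrame(
        pedigree, columns=["generation", "id", "parent1", "parent2"]
    )
    frame.to_csv(Path(path), sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep="\t")
    expected = ["generation", "id", "parent1", "parent2"]
    if list(frame.columns) != expected:
        raise ValueError(f"pedigree file must have columns {expected}")
    return frame


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")
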
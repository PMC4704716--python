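"""Run configuration for the forward simulator.

Two dataclasses describe a study: :class:`SimulationConfig` fixes the genetic
architecture and the base-population burn-in, :class:`LineConfig` the derived
small lines.  Both are plain, validated containers; all randomness is driven
by explicit ``numpy`` generators created from the configured seeds.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field

__all__ = [
    "Scenario",
    "SimulationConfig",
    "LineConfig",
    "replicate_rng",
]


class Scenario(str, enum.Enum):
    """Line-maintenance regime.

    ``MSD`` keeps the full mutation–selection–drift life cycle (parents drawn
    with probability proportional to fitness); ``MD`` disables selection
    (uniform parent draws) while mutation and drift continue.
    """

    MSD = "MSD"
    MD = "MD"


def _as_scenario(value: "Scenario | str") -> Scenario:
    if isinstance(value, Scenario):
        return value
    return Scenario(str(value).upper())


@dataclass
class SimulationConfig:
    """Parameters of a base-population run.

    The simulated genome is a single chromosome of ``n_s`` selective sites and
    ``n_n`` neutral marker sites arranged as repeating batches of 20 selective
    sites followed by one neutral site.  Deleterious genotypes ++, +m and mm
    have fitness 1, 1-hs and 1-s; individual fitness is multiplicative over
    selective sites.  ``L`` is the map length in Morgans; with
    ``free_recombination`` adjacent sites assort independently (c = 0.5).

    Parameters
    ----------
    s, h
        Selection coefficient against the mutant homozygote and dominance
        coefficient of the deleterious allele.
    L
        Genome length in Morgans (ignored when ``free_recombination``).
    free_recombination
        If true, adjacent sites recombine with fraction 0.5.
    n_s, n_n
        Numbers of selective and neutral sites; ``n_s == 20 * n_n``.
    N_b
        Base (burn-in) census size, diploid individuals.
    U_del, U_neu
        Genomic mutation rates per haploid genome and generation for the
        deleterious and the neutral class.
    T_burnin
        Burn-in generations run to approach the mutation-selection-drift
        balance.
    seed
        Base RNG seed; replicate ``r`` uses ``seed + r``.
    """

    s: float = 0.1
    h: float = 0.5
    L: float | None = None
    free_recombination: bool = False
    n_s: int = 20000
    n_n: int = 1000
    N_b: int = 1000
    U_del: float = 0.1
    U_neu: float = 0.005
    T_burnin: int = 10000
    seed: int = 0
    d: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must lie in [0, 1], got {self.s}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"h must lie in [0, 1], got {self.h}")
        if not self.free_recombination:
            if self.L is None:
                raise ValueError("either L or free_recombination is required")
            if self.L < 0:
                raise ValueError(f"genome length L must be >= 0, got {self.L}")
        if self.n_s != 20 * self.n_n:
            raise ValueError(
                f"site layout requires n_s == 20*n_n, got n_s={self.n_s}, n_n={self.n_n}"
            )
        if self.N_b < 1:
            raise ValueError("N_b must be positive")
        if self.U_del < 0 or self.U_neu < 0:
            raise ValueError("mutation rates must be non-negative")
        if self.T_burnin < 0:
            raise ValueError("T_burnin must be >= 0")
        # purging coefficient: recessive component of the deleterious effect
        self.d = self.s * (0.5 - self.h)

    @property
    def n_sites(self) -> int:
        return self.n_s + self.n_n

    def mu_per_site(self, selective: bool = True) -> float:
        """Per-site mutation rate of a class (U spread over its sites)."""
        return self.U_del / self.n_s if selective else self.U_neu / self.n_n

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (``d`` re-derived)."""
        return dataclasses.replace(self, **kwargs)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("d", None)
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls(**json.loads(text))


@dataclass
class LineConfig:
    """Parameters of the reduced-size lines derived from a base population.

    Each generation the current ``N`` potential breeders produce
    ``n_offspring`` individuals on which all statistics are computed; ``N`` of
    them are then drawn uniformly as the next breeders.
    """

    N: int = 10
    n_offspring: int = 100
    T: int = 100
    scenario: Scenario = Scenario.MSD
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.scenario = _as_scenario(self.scenario)
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.N > self.n_offspring:
            raise ValueError(
                f"N ({self.N}) cannot exceed offspring cohort size ({self.n_offspring})"
            )
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def replicate_rng(seed: int, replicate: int):
    """RNG for replicate ``replicate`` of a run with base ``seed``."""
    import numpy as np

    return np.random.default_rng(seed + replicate)
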
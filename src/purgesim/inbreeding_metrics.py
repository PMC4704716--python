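"""Three inbreeding measures for a line.

* ``f_wright`` — the neutral expectation from census size alone,
  ``f_N = 1 - (1 - 1/2N)^t``.
* ``f_Vk`` — the same recursion driven by the realized effective size
  ``Ne = (4N - 2)/(2 + V_k)`` computed from the variance of gametic
  contributions to each generation's breeding pool.
* ``f_p`` — pedigree inbreeding by the tabular (coancestry matrix) method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "f_wright",
    "ne_from_vk",
    "f_from_ne_series",
    "CoancestryState",
    "pedigree_inbreeding",
]


def f_wright(N: int, t: int | np.ndarray) -> float | np.ndarray:
    """Wright's inbreeding coefficient expected from census size alone."""
    if N < 1:
        raise ValueError("N must be >= 1")
    t = np.asarray(t)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = 1.0 - (1.0 - 1.0 / (2.0 * N)) ** t
    return float(out) if out.ndim == 0 else out


def ne_from_vk(N: int, Vk: float) -> float:
    """Effective size from the variance of gametic contributions,
    ``Ne = (4N - 2) / (2 + V_k)``.

    ``V_k = 2`` (near-multinomial contributions) gives the ideal
    ``Ne = N - 1/2``; equalized contributions (``V_k = 0``) roughly double
    the effective size.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if Vk < 0:
        raise ValueError("Vk must be >= 0")
    return (4.0 * N - 2.0) / (2.0 + Vk)


def f_from_ne_series(ne_series) -> float:
    """Cumulative inbreeding from a sequence of per-generation effective
    sizes: ``f_t = 1 - prod(1 - 1/(2 Ne_tau))``.

    With constant ``Ne`` this reduces to Wright's closed form.  The empty
    series gives 0.
    """
    ne = np.asarray(list(ne_series), dtype=float)
    if ne.size == 0:
        return 0.0
    if np.any(ne <= 0.5):
        raise ValueError("all Ne must exceed 0.5")
    return float(1.0 - np.prod(1.0 - 1.0 / (2.0 * ne)))


@dataclass
class CoancestryState:
    """Pairwise coancestries among the current breeders of a line.

    ``theta[i, j]`` is the coancestry of breeders i and j;
    ``theta[i, i] = (1 + f_i)/2`` where ``f_i`` is i's own inbreeding.
    Updated generation by generation from the recorded parent pairs, which is
    the tabular method restricted to the living cohort.
    """

    theta: np.ndarray

    @classmethod
    def founders(cls, n: int) -> "CoancestryState":
        """Unrelated, non-inbred founders: theta = I/2."""
        return cls(theta=np.eye(n) / 2.0)

    def offspring_inbreeding(self, parent_pairs: np.ndarray) -> np.ndarray:
        """f of offspring with the given (parent1, parent2) index pairs: the
        coancestry of the two parents (selfing: parent1 == parent2)."""
        pairs = np.asarray(parent_pairs)
        return self.theta[pairs[:, 0], pairs[:, 1]]

    def next_generation(self, parent_pairs: np.ndarray) -> "CoancestryState":
        """Coancestry matrix of an offspring cohort bred from the current one."""
        pairs = np.asarray(parent_pairs)
        a, b = pairs[:, 0], pairs[:, 1]
        half = 0.5 * (self.theta[a, :] + self.theta[b, :])  # (n_new, n_old)
        theta_new = 0.5 * (half[:, a] + half[:, b])
        f_new = self.theta[a, b]
        np.fill_diagonal(theta_new, 0.5 * (1.0 + f_new))
        return CoancestryState(theta=theta_new)


def pedigree_inbreeding(parents: np.ndarray) -> np.ndarray:
    """Per-individual inbreeding coefficients by the tabular method.

    ``parents`` is an ``(n, 2)`` integer array: row i holds the 0-based
    indices of individual i's parents, or -1 for a founder (both entries must
    then be -1).  Parents must precede their offspring (topological order);
    a forward reference raises.  Selfing is expressed by equal parents.

    The full coancestry table is built row by row:
    ``theta(new, j) = [theta(p1, j) + theta(p2, j)] / 2`` for previous j,
    ``f(new) = theta(p1, p2)`` and ``theta(new, new) = (1 + f)/2``.

    Memory is O(n^2); intended for recorded pedigrees up to a few thousand
    individuals.
    """
    parents = np.asarray(parents, dtype=np.int64)
    if parents.ndim != 2 or parents.shape[1] != 2:
        raise ValueError("parents must be an (n, 2) array")
    n = parents.shape[0]
    theta = np.zeros((n, n))
    f = np.zeros(n)
    for i in range(n):
        p1, p2 = parents[i]
        if (p1 < 0) != (p2 < 0):
            raise ValueError(f"individual {i}: both parents must be known or both unknown")
        if p1 < 0:
            theta[i, i] = 0.5
            continue
        if p1 >= i or p2 >= i:
            raise ValueError(f"individual {i} references a parent not yet defined")
        if i > 0:
            row = 0.5 * (theta[p1, :i] + theta[p2, :i])
            theta[i, :i] = row
            theta[:i, i] = row
        f[i] = theta[p1, p2]
        theta[i, i] = 0.5 * (1.0 + f[i])
    return f
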
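"""Independent oracles used by the test suite.

These deliberately re-derive quantities by different routes than the package
(path counting instead of the tabular recursion, weighted least squares
instead of closed-form variance components) so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def path_counting_inbreeding(parents: np.ndarray) -> np.ndarray:
    """Wright's path-counting inbreeding coefficients.

    ``F_X = sum over common ancestors A and over pairs of ancestral paths
    (one from each parent of X, sharing no individual except A) of
    (1/2)^(L1 + L2 + 1) (1 + F_A)``, with path lengths counted in edges.
    Ancestor inbreeding is obtained by applying the same formula in
    topological order.  Exponential in pedigree size; fine for <= ~12.
    """
    parents = np.asarray(parents, dtype=np.int64)
    n = parents.shape[0]
    f = np.zeros(n)

    def ascending_paths(x: int):
        """All edge-paths from x upward: (ancestor, length, visited-set)."""
        out = [(x, 0, frozenset([x]))]
        p1, p2 = parents[x]
        if p1 >= 0:
            for parent in (p1, p2):  # two parent edges, possibly parallel
                for anc, length, nodes in ascending_paths(parent):
                    out.append((anc, length + 1, nodes | {x}))
        return out

    for x in range(n):
        p1, p2 = parents[x]
        if p1 < 0:
            continue
        total = 0.0
        for anc1, l1, nodes1 in ascending_paths(p1):
            for anc2, l2, nodes2 in ascending_paths(p2):
                if anc1 == anc2 and nodes1 & nodes2 == frozenset([anc1]):
                    total += 0.5 ** (l1 + l2 + 1) * (1.0 + f[anc1])
        f[x] = total
    return f


def brute_force_variance_components(q: float, s: float, h: float) -> tuple[float, float]:
    """One-locus V_A and V_D by weighted least squares.

    Genotype values (1, 1-hs, 1-s) at Hardy-Weinberg frequencies are
    regressed on mutant-allele dosage; the regression sum of squares is the
    additive variance, the residual the dominance variance.
    """
    p = 1.0 - q
    freq = np.array([p * p, 2 * p * q, q * q])
    dosage = np.array([0.0, 1.0, 2.0])
    value = np.array([1.0, 1.0 - h * s, 1.0 - s])
    mean_x = freq @ dosage
    mean_y = freq @ value
    cov = freq @ ((dosage - mean_x) * (value - mean_y))
    var_x = freq @ (dosage - mean_x) ** 2
    beta = cov / var_x if var_x > 0 else 0.0
    fitted = mean_y + beta * (dosage - mean_x)
    va = freq @ (fitted - mean_y) ** 2
    vd = freq @ (value - fitted) ** 2
    return float(va), float(vd)


def purged_inbreeding_reference(N: int, d: float, T: int) -> list[float]:
    """Purged-inbreeding recursion written independently (scalar python)."""
    g = [0.0]
    for t in range(1, T + 1):
        f_prev = 1.0 - (1.0 - 1.0 / (2.0 * N)) ** (t - 1)
        g.append(((1.0 - 1.0 / (2.0 * N)) * g[t - 1] + 1.0 / (2.0 * N))
                 * (1.0 - 2.0 * d * f_prev))
    return g
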
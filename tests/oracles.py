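"""Independent brute-force oracles: naive triple-loop implementations of every
effect statistic, kept deliberately separate from the package's vectorized
paths."""

from __future__ import annotations

import math


def outdeg(A, j):
    return sum(A[j][h] for h in range(len(A)))


def indeg(A, j):
    return sum(A[h][j] for h in range(len(A)))


def brute_network_stat(name, A, i, *, values=None, value_range=None,
                       sim_mean=0.0, limited=None):
    n = len(A)
    if name == "out-degree":
        return float(sum(A[i][j] for j in range(n)))
    if name == "reciprocity":
        return float(sum(A[i][j] * A[j][i] for j in range(n)))
    if name == "transitive triplets":
        return float(sum(A[i][j] * A[i][h] * A[h][j]
                         for j in range(n) for h in range(n)))
    if name == "3-cycles":
        return float(sum(A[i][j] * A[j][h] * A[h][i]
                         for j in range(n) for h in range(n)))
    if name == "out-degree popularity":
        return float(sum(A[i][j] * outdeg(A, j) for j in range(n)))
    if name == "in-degree popularity":
        return float(sum(A[i][j] * indeg(A, j) for j in range(n)))
    if name == "out-out sqrt assortativity":
        return float(math.sqrt(outdeg(A, i))
                     * sum(A[i][j] * math.sqrt(outdeg(A, j))
                           for j in range(n)))
    if name == "in-in sqrt assortativity":
        return float(math.sqrt(indeg(A, i))
                     * sum(A[i][j] * math.sqrt(indeg(A, j))
                           for j in range(n)))
    if name in ("covariate similarity", "behavior similarity"):
        return float(sum(
            A[i][j] * ((1.0 - abs(values[i] - values[j]) / value_range)
                       - sim_mean)
            for j in range(n)))
    if name == "limited nomination ego":
        return float(limited[i] * sum(A[i][j] for j in range(n)))
    raise KeyError(name)


def brute_behavior_stat(name, A, z, i, *, z_mean=0.0, value_range=None,
                        sim_mean=0.0, cov=None, cov_mean=0.0, other=None,
                        other_mean=0.0):
    n = len(A)
    zt = z[i] - z_mean
    if name == "linear shape":
        return float(zt)
    if name == "quadratic shape":
        return float(zt * zt)
    if name == "in-degree":
        return float(zt * indeg(A, i))
    if name == "peer influence":
        oi = outdeg(A, i)
        if oi == 0:
            return 0.0
        tot = sum(A[i][j] * ((1.0 - abs(z[i] - z[j]) / value_range)
                             - sim_mean) for j in range(n))
        return float(tot / oi)
    if name == "covariate main":
        return float(zt * (cov[i] - cov_mean))
    if name == "other behavior":
        return float(zt * (other[i] - other_mean))
    if name == "friends using other substance":
        return float(zt * sum(A[i][j] for j in range(n) if other[j] >= 1))
    raise KeyError(name)
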
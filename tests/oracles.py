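"""Independent brute-force oracles used to cross-check the estimators.

Everything here evaluates the defining sums directly over explicit
probability dictionaries, with no shared code with the package internals.
"""

import itertools
import math


def probs_from_counts(counts):
    n = sum(counts.values())
    return {k: c / n for k, c in counts.items() if c > 0}


def entropy_oracle(p):
    """H = -sum p log2 p by direct summation."""
    return -sum(v * math.log2(v) for v in p.values() if v > 0)


def marginal(p, dims):
    out = {}
    for key, v in p.items():
        sub = tuple(key[d] for d in dims)
        out[sub] = out.get(sub, 0.0) + v
    return out


def conditional_entropy_oracle(p, target_dims, cond_dims):
    """H(X|Y) = -sum_{x,y} p(x,y) log2 p(x|y), summed cell by cell."""
    py = marginal(p, cond_dims)
    total = 0.0
    for key, v in p.items():
        if v <= 0:
            continue
        y = tuple(key[d] for d in cond_dims)
        p_x_given_y = v_joint(p, key, target_dims, cond_dims) / py[y]
        total -= v * math.log2(p_x_given_y)
    return total


def v_joint(p, key, target_dims, cond_dims):
    """p(x, y) for the (target, cond) sub-tuple of one cell's key."""
    dims = tuple(target_dims) + tuple(cond_dims)
    sub = tuple(key[d] for d in dims)
    return marginal(p, dims)[sub]


def mutual_information_oracle(p, dims_x, dims_y):
    """I(X;Y) = sum p(x,y) log2 [ p(x,y) / (p(x) p(y)) ]."""
    pxy = marginal(p, tuple(dims_x) + tuple(dims_y))
    px = marginal(p, dims_x)
    py = marginal(p, dims_y)
    total = 0.0
    for key, v in pxy.items():
        if v <= 0:
            continue
        x = key[: len(dims_x)]
        y = key[len(dims_x):]
        total += v * math.log2(v / (px[x] * py[y]))
    return total


def conditional_mutual_information_oracle(p, dims_x, dims_y, dims_z):
    """I(X;Y|Z) = H(X|Z) - H(X|Y,Z) via the conditional-entropy oracle."""
    if not dims_z:
        return mutual_information_oracle(p, dims_x, dims_y)
    keep = tuple(dims_x) + tuple(dims_y) + tuple(dims_z)
    q = marginal(p, keep)
    nx, ny = len(dims_x), len(dims_y)
    x_dims = tuple(range(nx))
    y_dims = tuple(range(nx, nx + ny))
    z_dims = tuple(range(nx + ny, len(keep)))
    return conditional_entropy_oracle(q, x_dims, z_dims) - conditional_entropy_oracle(
        q, x_dims, y_dims + z_dims
    )


def exhaustive_tables(max_symbols, arity, total, limit=None):
    """Yield all count tables over a full grid with the given total count."""
    cells = list(itertools.product(range(max_symbols), repeat=arity))
    for combo in _compositions(total, len(cells)):
        counts = {cell: c for cell, c in zip(cells, combo) if c > 0}
        if counts:
            yield counts


def _compositions(total, k):
    if k == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, k - 1):
            yield (first,) + rest
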
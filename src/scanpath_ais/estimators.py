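"""Plug-in information estimators for discrete data.

All quantities are computed from empirical frequency tables ("plug-in"
estimation) and reported in bits (log base 2).  Plug-in entropy is negatively
biased at small sample sizes; two analytic first-order corrections are
provided: the classic Miller--Madow term and a refined variant that first
estimates the size of the underlying support from the bin-occupancy pattern
(in the spirit of Panzeri & Treves' bias estimate for neural data).

The :class:`DistributionTable` container is the canonical interface; the
``*_of_codes`` helpers are fast array paths over integer-coded samples used by
the embedding machinery and are cross-checked against the table route in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DistributionTable",
    "InfoEstimate",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "bias_correction",
    "entropy_of_codes",
    "joint_code",
]

_LN2 = float(np.log(2.0))


class EmptyTableError(ValueError):
    """Raised when an estimator is given a table with no observations."""


@dataclass(frozen=True)
class DistributionTable:
    """Joint frequency table over tuples of discrete symbols.

    Parameters
    ----------
    counts
        Mapping from length-``arity`` symbol tuples to positive counts.
    arity
        Number of joint dimensions.
    n
        Total number of observations (must equal the sum of counts).
    """

    counts: Mapping[tuple[int, ...], int]
    arity: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1 or not self.counts:
            raise EmptyTableError("distribution table has no observations")
        if any(len(k) != self.arity for k in self.counts):
            raise ValueError("all tuples must have length = arity")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if sum(self.counts.values()) != self.n:
            raise ValueError("counts must sum to n")

    @classmethod
    def from_counts(cls, counts: Mapping[tuple[int, ...], int]) -> "DistributionTable":
        counts = {tuple(k): int(v) for k, v in counts.items() if v > 0}
        if not counts:
            raise EmptyTableError("no positive counts")
        arity = len(next(iter(counts)))
        return cls(counts=counts, arity=arity, n=sum(counts.values()))

    @classmethod
    def from_samples(cls, samples: Iterable[Sequence[int]]) -> "DistributionTable":
        """Build a table by counting rows of joint observations."""
        arr = np.atleast_2d(np.asarray(list(samples), dtype=np.int64))
        if arr.size == 0:
            raise EmptyTableError("no samples")
        uniq, cnt = np.unique(arr, axis=0, return_counts=True)
        return cls.from_counts({tuple(row): int(c) for row, c in zip(uniq, cnt)})

    def marginal(self, dims: Sequence[int]) -> "DistributionTable":
        """Marginalise onto the given dimensions (in the given order)."""
        dims = tuple(dims)
        out: dict[tuple[int, ...], int] = {}
        for key, c in self.counts.items():
            sub = tuple(key[d] for d in dims)
            out[sub] = out.get(sub, 0) + c
        return DistributionTable(counts=out, arity=len(dims), n=self.n)

    def support_size(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def count_values(self) -> np.ndarray:
        return np.fromiter((c for c in self.counts.values() if c > 0), dtype=np.int64)


@dataclass(frozen=True)
class InfoEstimate:
    """A scalar information estimate in bits, with bias-correction metadata."""

    value: float
    bias_correction: float
    n: int
    corrected: bool

    @property
    def uncorrected(self) -> float:
        return self.value - self.bias_correction if self.corrected else self.value


# ---------------------------------------------------------------------------
# fast paths on integer codes


def joint_code(*columns: np.ndarray) -> np.ndarray:
    """Collapse columns of non-negative integers into a single code column."""
    cols = [np.asarray(c, dtype=np.int64) for c in columns]
    code = cols[0]
    for c in cols[1:]:
        k = int(c.max()) + 1 if c.size else 1
        code = code * k + c
    return code


def entropy_of_codes(codes: np.ndarray) -> float:
    """Plug-in entropy in bits of a 1-D integer-coded sample."""
    codes = np.asarray(codes)
    n = codes.size
    if n == 0:
        raise EmptyTableError("empty sample")
    if codes.max() < (1 << 20):
        c = np.bincount(codes)
        c = c[c > 0].astype(np.float64)
    else:  # sparse code range: relabel to a compact range first
        _, c = np.unique(codes, return_counts=True)
        c = c.astype(np.float64)
    return float(np.log2(n) - (c * np.log2(c)).sum() / n)


def _entropy_from_count_values(c: np.ndarray, n: int) -> float:
    c = np.asarray(c, dtype=np.float64)
    c = c[c > 0]
    return float(np.log2(n) - (c * np.log2(c)).sum() / n)


# ---------------------------------------------------------------------------
# bias corrections


def _support_size_estimate(count_values: np.ndarray, n: int) -> float:
    """Estimate the true support size from the occupancy pattern.

    Inverts the expected occupancy of ``R`` equiprobable bins after ``n``
    draws, E[observed] = R (1 - (1 - 1/R)^n), for R given the observed number
    of occupied bins.  When nearly every observation sits in its own bin the
    inversion has no finite solution and the observed support is returned
    (the sample is too small for the refinement to help).
    """
    r_obs = int((count_values > 0).sum())
    if r_obs <= 1 or n <= 1 or r_obs >= n:
        return float(r_obs)

    def f(r: float) -> float:
        return r * (1.0 - (1.0 - 1.0 / r) ** n) - r_obs

    if f(r_obs) >= 0.0:  # every expected bin already observed
        return float(r_obs)
    hi = float(r_obs)
    for _ in range(64):
        hi *= 2.0
        if f(hi) >= 0.0:
            return float(brentq(f, r_obs, hi))
    return float(r_obs)  # pathological; fall back to observed support


def _entropy_correction(count_values: np.ndarray, n: int, method: str) -> float:
    if method == "mm":
        support = float((count_values > 0).sum())
    elif method == "pt":
        support = _support_size_estimate(count_values, n)
    else:
        raise ValueError(f"unknown bias-correction method: {method!r}")
    return (support - 1.0) / (2.0 * n * _LN2)


def bias_correction(
    table: DistributionTable,
    quantity: str,
    *,
    dims_x: Sequence[int] | None = None,
    dims_y: Sequence[int] | None = None,
    method: str = "pt",
) -> float:
    """Additive first-order bias-correction term in bits.

    ``quantity`` is ``"entropy"`` (correction for the full joint table) or
    ``"mutual_information"`` (composed from the corrections of H(X), H(Y) and
    H(X,Y); ``dims_x``/``dims_y`` default to the first dimension versus the
    rest).  ``method`` selects the Miller--Madow form (``"mm"``) or the
    support-size-estimating form (``"pt"``, default).
    """
    if quantity == "entropy":
        return _entropy_correction(table.count_values(), table.n, method)
    if quantity == "mutual_information":
        if dims_x is None:
            dims_x = (0,)
        if dims_y is None:
            dims_y = tuple(d for d in range(table.arity) if d not in dims_x)
        hx = _entropy_correction(table.marginal(dims_x).count_values(), table.n, method)
        hy = _entropy_correction(table.marginal(dims_y).count_values(), table.n, method)
        hxy = _entropy_correction(table.count_values(), table.n, method)
        return hx + hy - hxy
    raise ValueError(f"unknown quantity: {quantity!r}")


# ---------------------------------------------------------------------------
# estimators


def entropy(
    table: DistributionTable, *, correct_bias: bool = False, method: str = "pt"
) -> InfoEstimate:
    """Plug-in Shannon entropy H(X) = -sum p log2 p with 0 log 0 := 0."""
    h = _entropy_from_count_values(table.count_values(), table.n)
    corr = bias_correction(table, "entropy", method=method) if correct_bias else 0.0
    return InfoEstimate(
        value=h + corr, bias_correction=corr, n=table.n, corrected=correct_bias
    )


def conditional_entropy(
    table: DistributionTable,
    target_dims: Sequence[int],
    cond_dims: Sequence[int],
) -> InfoEstimate:
    """Plug-in conditional entropy H(X|Y) = H(X,Y) - H(Y).

    For a table of (current fixation, previous fixation) pairs with
    ``target_dims`` the current and ``cond_dims`` the previous fixation this
    is the gaze transition entropy.
    """
    target_dims, cond_dims = tuple(target_dims), tuple(cond_dims)
    if set(target_dims) & set(cond_dims):
        raise ValueError("target and conditioning dimensions must be disjoint")
    if sorted(target_dims + cond_dims) != list(range(table.arity)):
        raise ValueError("dimensions must partition the table arity")
    h_joint = _entropy_from_count_values(table.count_values(), table.n)
    if not cond_dims:
        h_cond = 0.0
    else:
        h_cond = _entropy_from_count_values(
            table.marginal(cond_dims).count_values(), table.n
        )
    return InfoEstimate(
        value=h_joint - h_cond, bias_correction=0.0, n=table.n, corrected=False
    )


def mutual_information(
    table: DistributionTable,
    dims_x: Sequence[int],
    dims_y: Sequence[int],
    *,
    correct_bias: bool = False,
    method: str = "pt",
) -> InfoEstimate:
    """Plug-in mutual information I(X;Y) = H(X) + H(Y) - H(X,Y)."""
    dims_x, dims_y = tuple(dims_x), tuple(dims_y)
    if set(dims_x) & set(dims_y):
        raise ValueError("dimension groups must be disjoint")
    hx = _entropy_from_count_values(table.marginal(dims_x).count_values(), table.n)
    hy = _entropy_from_count_values(table.marginal(dims_y).count_values(), table.n)
    hxy = _entropy_from_count_values(
        table.marginal(dims_x + dims_y).count_values(), table.n
    )
    mi = hx + hy - hxy
    corr = (
        bias_correction(table, "mutual_information", dims_x=dims_x, dims_y=dims_y, method=method)
        if correct_bias
        else 0.0
    )
    return InfoEstimate(
        value=mi + corr, bias_correction=corr, n=table.n, corrected=correct_bias
    )


def conditional_mutual_information(
    table: DistributionTable,
    dims_x: Sequence[int],
    dims_y: Sequence[int],
    dims_z: Sequence[int],
) -> InfoEstimate:
    """Plug-in conditional MI I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z).

    With ``dims_z`` empty this reduces to the unconditional MI.  Used for the
    per-lag information gain during past-state selection, where Z holds the
    already-selected past variables.
    """
    dims_x, dims_y, dims_z = tuple(dims_x), tuple(dims_y), tuple(dims_z)
    groups = [dims_x, dims_y, dims_z]
    flat = [d for g in groups for d in g]
    if len(set(flat)) != len(flat):
        raise ValueError("dimension groups must be disjoint")
    n = table.n
    hxz = _entropy_from_count_values(table.marginal(dims_x + dims_z).count_values(), n)
    hyz = _entropy_from_count_values(table.marginal(dims_y + dims_z).count_values(), n)
    hxyz = _entropy_from_count_values(
        table.marginal(dims_x + dims_y + dims_z).count_values(), n
    )
    if dims_z:
        hz = _entropy_from_count_values(table.marginal(dims_z).count_values(), n)
    else:
        hz = 0.0
    return InfoEstimate(
        value=hxz + hyz - hz - hxyz, bias_correction=0.0, n=n, corrected=False
    )
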
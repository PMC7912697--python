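"""Active information storage with data-driven non-uniform embedding.

The past state of a discrete fixation process is selected per trial by greedy
forward selection over candidate lags 1..k_max: at each step the candidate
with the largest conditional-mutual-information gain (given the already
selected lags) is tested against a maximum-statistic permutation null, and
included only if significant.  Testing every inclusion gives an automatic
stopping rule and family-wise error control over the candidate set; if no
lag is ever significant the trial has no detectable temporal structure and
no AIS is reported.

AIS is then the plug-in mutual information between the selected past tuple
and the next symbol, optionally bias-corrected, together with the entropy of
the next fixation H(X_t) (used for normalization), the gaze transition
entropy H(X_t | X_{t-1}), and a final permutation significance test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import estimators as est
from .preprocessing import Scanpath

__all__ = [
    "PastStateSpec",
    "EmbeddedSample",
    "Embedding",
    "AISResult",
    "SurrogateTestResult",
    "InsufficientSamplesError",
    "embed",
    "optimize_past_state",
    "surrogate_test",
    "estimate_ais",
    "estimate_gte",
    "MIN_EMBEDDED_SAMPLES",
]

logger = logging.getLogger(__name__)

#: Minimum number of embedded samples required to attempt estimation.
MIN_EMBEDDED_SAMPLES = 10


class InsufficientSamplesError(ValueError):
    """Raised when a scanpath is too short for the requested embedding."""


@dataclass(frozen=True)
class PastStateSpec:
    """A selected set of past lags bounded by ``k_max``.

    ``lags`` is sorted and unique, every lag in [1, k_max].  An empty lag set
    means no past variable carried significant information.
    """

    lags: tuple[int, ...]
    k_max: int

    def __post_init__(self) -> None:
        lags = tuple(sorted(set(int(l) for l in self.lags)))
        object.__setattr__(self, "lags", lags)
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if lags and (lags[0] < 1 or lags[-1] > self.k_max):
            raise ValueError("lags must lie in [1, k_max]")

    def __bool__(self) -> bool:
        return bool(self.lags)

    @property
    def max_lag(self) -> int:
        return self.lags[-1] if self.lags else 0


@dataclass(frozen=True)
class EmbeddedSample:
    target: int
    past: tuple[int, ...]


class Embedding:
    """Array-backed view of (past tuple, target) realization pairs.

    ``past`` has one column per lag (ordered as ``lags``); row ``i`` pairs
    the target symbol at time ``t_i`` with the past symbols at ``t_i - lag``.
    """

    def __init__(self, target: np.ndarray, past: np.ndarray, lags: tuple[int, ...], alphabet_size: int):
        self.target = np.asarray(target, dtype=np.int64)
        self.past = np.asarray(past, dtype=np.int64)
        self.lags = tuple(lags)
        self.alphabet_size = int(alphabet_size)
        if self.past.shape != (self.target.size, len(self.lags)):
            raise ValueError("past matrix shape mismatch")

    def __len__(self) -> int:
        return int(self.target.size)

    def __getitem__(self, i: int) -> EmbeddedSample:
        return EmbeddedSample(int(self.target[i]), tuple(self.past[i]))

    def past_code(self, columns: tuple[int, ...] | None = None) -> np.ndarray:
        """Integer code of the (sub)tuple of past columns, one per sample."""
        cols = range(self.past.shape[1]) if columns is None else columns
        arrs = [self.past[:, c] for c in cols]
        if not arrs:
            return np.zeros(len(self), dtype=np.int64)
        return est.joint_code(*arrs)


def embed(
    scanpath: Scanpath,
    spec: PastStateSpec,
    k_ref: int | None = None,
) -> Embedding:
    """Embed a scanpath under a past-state spec.

    One sample is produced for each time point ``t > offset`` where
    ``offset`` is the spec's own maximum lag, or ``k_ref`` when an external
    reference lag is imposed (used to hold the sample count comparable
    across trials embedded with different specs).
    """
    if not spec.lags:
        raise ValueError("cannot embed with an empty past-state spec")
    offset = spec.max_lag if k_ref is None else int(k_ref)
    if offset < spec.max_lag:
        raise ValueError("k_ref must be >= the spec's maximum lag")
    n = len(scanpath)
    if n <= offset:
        raise InsufficientSamplesError(
            f"scanpath of length {n} too short for embedding offset {offset}"
        )
    sym = scanpath.symbols
    target = sym[offset:]
    past = np.column_stack([sym[offset - lag : n - lag] for lag in spec.lags])
    return Embedding(target, past, spec.lags, scanpath.alphabet_size)


# ---------------------------------------------------------------------------
# conditional-gain machinery (fast integer-code paths)


def _cmi_gain(target: np.ndarray, cand: np.ndarray, z_code: np.ndarray | None) -> float:
    """I(target; cand | z) in bits from integer-coded columns."""
    if z_code is None:
        h_x = est.entropy_of_codes(target)
        h_y = est.entropy_of_codes(cand)
        h_xy = est.entropy_of_codes(est.joint_code(cand, target))
        return h_x + h_y - h_xy
    h_xz = est.entropy_of_codes(est.joint_code(z_code, target))
    h_yz = est.entropy_of_codes(est.joint_code(z_code, cand))
    h_z = est.entropy_of_codes(z_code)
    h_xyz = est.entropy_of_codes(est.joint_code(z_code, cand, target))
    return h_xz + h_yz - h_z - h_xyz


@dataclass(frozen=True)
class SurrogateTestResult:
    """Observed per-candidate gains and maximum-statistic p-values."""

    gains: dict[int, float]
    p_values: dict[int, float]
    null_max: np.ndarray
    n_perm: int


def surrogate_test(
    embedding: Embedding,
    candidate_lags: tuple[int, ...],
    selected_lags: tuple[int, ...],
    n_perm: int,
    rng: int | np.random.Generator | None = None,
) -> SurrogateTestResult:
    """Maximum-statistic permutation test for candidate-lag inclusion.

    The null is built by permuting the target column uniformly at random
    while keeping all past tuples fixed; each permutation contributes the
    MAXIMUM conditional gain over all remaining candidates, which controls
    the family-wise error rate of the inclusion decision.  p-values use the
    add-one convention p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    lag_to_col = {lag: i for i, lag in enumerate(embedding.lags)}
    cand_cols = {lag: embedding.past[:, lag_to_col[lag]] for lag in candidate_lags}
    if selected_lags:
        z_code = embedding.past_code(tuple(lag_to_col[l] for l in selected_lags))
    else:
        z_code = None

    gains = {lag: _cmi_gain(embedding.target, col, z_code) for lag, col in cand_cols.items()}

    # Under target permutation only the entropy terms containing the target
    # change; precompute the rest once.
    target = embedding.target
    if z_code is None:
        yz_codes = list(cand_cols.values())
        base = [est.entropy_of_codes(y) for y in yz_codes]  # H(y)
    else:
        yz_codes = [est.joint_code(z_code, col) for col in cand_cols.values()]
        h_z = est.entropy_of_codes(z_code)
        base = [est.entropy_of_codes(yz) - h_z for yz in yz_codes]  # H(y|z)

    null_max = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(target)
        if z_code is None:
            h_x = est.entropy_of_codes(perm)
        else:
            h_x = est.entropy_of_codes(est.joint_code(z_code, perm))
        null_max[i] = max(
            h_x + b - est.entropy_of_codes(est.joint_code(yz, perm))
            for yz, b in zip(yz_codes, base)
        )
    p_values = {
        lag: float((1 + int((null_max >= g - 1e-12).sum())) / (1 + n_perm))
        for lag, g in gains.items()
    }
    return SurrogateTestResult(gains=gains, p_values=p_values, null_max=null_max, n_perm=n_perm)


def optimize_past_state(
    scanpath: Scanpath,
    k_max: int = 5,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> PastStateSpec:
    """Greedy forward selection of past lags with permutation gating.

    All candidate gains are evaluated on the fixed embedding at ``k_max``
    (constant sample count across steps).  At each step the candidate with
    the maximal conditional gain (ties -> smallest lag) is tested against
    the maximum-statistic null over the remaining candidates; selection
    stops at the first non-significant candidate.  Returns an empty spec when
    no lag is significant.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if n_perm < int(np.ceil(1.0 / alpha)) - 1:
        raise ValueError("n_perm too small to resolve alpha")
    rng = np.random.default_rng(seed)
    full = PastStateSpec(lags=tuple(range(1, k_max + 1)), k_max=k_max)
    embedding = embed(scanpath, full)
    if len(embedding) < MIN_EMBEDDED_SAMPLES:
        raise InsufficientSamplesError(
            f"only {len(embedding)} embedded samples; need >= {MIN_EMBEDDED_SAMPLES}"
        )

    selected: list[int] = []
    remaining = list(range(1, k_max + 1))
    while remaining:
        result = surrogate_test(
            embedding, tuple(remaining), tuple(selected), n_perm=n_perm, rng=rng
        )
        # maximal gain, ties broken toward the smallest lag
        best = max(remaining, key=lambda lag: (result.gains[lag], -lag))
        if result.p_values[best] < alpha:
            selected.append(best)
            remaining.remove(best)
        else:
            break
    return PastStateSpec(lags=tuple(sorted(selected)), k_max=k_max)


# ---------------------------------------------------------------------------
# AIS / GTE estimation


@dataclass(frozen=True)
class AISResult:
    """Per-trial predictability estimates.

    ``ais`` is NaN when ``selected`` is false (no significant past state, no
    AIS reported).  ``ais_normalized`` = AIS / H(X_t) when H(X_t) > 0.  All
    quantities are evaluated on the same embedded samples so the identities
    between them hold sample-exactly for the uncorrected values.
    """

    ais: float
    ais_normalized: float
    h_next: float
    gte: float
    spec: PastStateSpec
    selected: bool
    p_value: float
    n_samples: int
    bias_correction: float = 0.0
    participant_id: str = ""
    trial_id: str = ""
    condition: str = ""


def estimate_ais(
    scanpath: Scanpath,
    spec: PastStateSpec,
    correct_bias: bool = True,
    bias_method: str = "pt",
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
    k_ref: int | None = None,
    max_samples: int | None = None,
) -> AISResult:
    """Estimate AIS, H(X_t), normalized AIS and GTE for one trial.

    The bias correction (when enabled) is applied to the final AIS and
    entropy values only; the permutation significance test always uses the
    uncorrected plug-in statistic, since the correction is constant across
    permutations.  ``max_samples`` truncates the embedding from the start of
    the trial (newest samples kept) to equalize sample counts across trials.
    """
    if not spec:
        h, g = _h_and_gte(scanpath)
        return AISResult(
            ais=float("nan"),
            ais_normalized=float("nan"),
            h_next=h,
            gte=g,
            spec=spec,
            selected=False,
            p_value=float("nan"),
            n_samples=0,
            participant_id=scanpath.participant_id,
            trial_id=scanpath.trial_id,
            condition=scanpath.condition,
        )
    rng = np.random.default_rng(seed)
    embedding = embed(scanpath, spec, k_ref=k_ref)
    target = embedding.target
    past_code = embedding.past_code()
    if max_samples is not None:
        if max_samples < MIN_EMBEDDED_SAMPLES:
            raise InsufficientSamplesError("max_samples below the usable minimum")
        if max_samples > target.size:
            raise InsufficientSamplesError(
                f"trial provides {target.size} embedded samples < requested {max_samples}"
            )
        # discard samples at the *beginning* of the trial
        target = target[-max_samples:]
        past_code = past_code[-max_samples:]
        embedding = Embedding(
            target,
            embedding.past[-max_samples:],
            embedding.lags,
            embedding.alphabet_size,
        )
    n = target.size
    if n < MIN_EMBEDDED_SAMPLES:
        raise InsufficientSamplesError(
            f"only {n} embedded samples; need >= {MIN_EMBEDDED_SAMPLES}"
        )

    h_next = est.entropy_of_codes(target)
    h_past = est.entropy_of_codes(past_code)
    h_joint = est.entropy_of_codes(est.joint_code(past_code, target))
    ais = h_past + h_next - h_joint

    # GTE on the same samples: previous symbol of each target
    lag1_prev = scanpath.symbols[np.arange(len(scanpath) - n, len(scanpath)) - 1]
    gte = (
        est.entropy_of_codes(est.joint_code(lag1_prev, target))
        - est.entropy_of_codes(lag1_prev)
    )

    # final significance: permute the target, recompute the MI
    p_value = float("nan")
    if n_perm > 0:
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(target)
            null[i] = h_past + h_next - est.entropy_of_codes(
                est.joint_code(past_code, perm)
            )
        p_value = float((1 + int((null >= ais - 1e-12).sum())) / (1 + n_perm))

    correction = 0.0
    h_corr = 0.0
    if correct_bias:
        table = est.DistributionTable.from_samples(
            np.column_stack([past_code, target])
        )
        correction = est.bias_correction(
            table, "mutual_information", dims_x=(0,), dims_y=(1,), method=bias_method
        )
        h_corr = est.bias_correction(table.marginal((1,)), "entropy", method=bias_method)
    ais_out = ais + correction
    h_out = h_next + h_corr
    return AISResult(
        ais=float(ais_out),
        ais_normalized=float(ais_out / h_out) if h_out > 0 else 0.0,
        h_next=float(h_out),
        gte=float(gte),
        spec=spec,
        selected=True,
        p_value=p_value,
        n_samples=int(n),
        bias_correction=float(correction),
        participant_id=scanpath.participant_id,
        trial_id=scanpath.trial_id,
        condition=scanpath.condition,
    )


def _h_and_gte(scanpath: Scanpath) -> tuple[float, float]:
    sym = scanpath.symbols
    h = est.entropy_of_codes(sym)
    if sym.size < 2:
        return float(h), float("nan")
    gte = est.entropy_of_codes(est.joint_code(sym[:-1], sym[1:])) - est.entropy_of_codes(
        sym[:-1]
    )
    return float(h), float(gte)


def estimate_gte(scanpath: Scanpath) -> float:
    """Gaze transition entropy H(X_t | X_{t-1}) over consecutive fixations."""
    if len(scanpath) < 2:
        raise InsufficientSamplesError("GTE requires at least 2 fixations")
    return _h_and_gte(scanpath)[1]
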
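"""Synthetic scanpaths, gaze traces, and two-condition study designs.

This module generates every input the pipeline needs, with known ground
truth:

* Markov chains of configurable order over a small AOI alphabet, initialised
  from the exact stationary distribution so finite-sample information
  estimates can be compared against the analytic values computed by
  :func:`analytic_ais` (exact enumeration of the stationary joint).
* Continuous gaze traces with planted fixation clusters for testing the
  dispersion-based fixation detector end to end.
* Full two-condition studies emulating a visual-comparison experiment with a
  relaxed, time-unconstrained condition (TUC) and a stressed, time-constrained
  condition (TC): the TC generator has lower stationary fixation entropy
  (gaze concentrates on fewer regions) and lower normalized predictability
  (more context-independent switching), and TC trials are shorter.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import GazeRecording, Scanpath

__all__ = [
    "MarkovModel",
    "StudyDesign",
    "AnalyticInfo",
    "generate_chain",
    "analytic_ais",
    "generate_gaze_trace",
    "generate_study",
    "default_condition_models",
    "default_study_design",
]

_JOINT_STATE_GUARD = 10**6


@dataclass(frozen=True)
class MarkovModel:
    """Finite-alphabet Markov chain of order ``k >= 0``.

    ``transitions`` has shape ``(K,) * order + (K,)``: the trailing axis is
    the distribution over the next symbol given the length-``order`` context
    (oldest context symbol first).  Order 0 is an i.i.d. model with
    ``transitions`` of shape ``(K,)``.
    """

    order: int
    alphabet_size: int
    transitions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "transitions", np.asarray(self.transitions, dtype=float)
        )
        k = self.alphabet_size
        expected = (k,) * self.order + (k,)
        if self.transitions.shape != expected:
            raise ValueError(
                f"transitions shape {self.transitions.shape} != {expected}"
            )
        if np.any(self.transitions < 0):
            raise ValueError("transition probabilities must be non-negative")
        rows = self.transitions.reshape(-1, k)
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every context row must sum to 1")

    # -- exact distributions -------------------------------------------------

    def stationary_context_distribution(self) -> np.ndarray:
        """Stationary distribution over length-``order`` contexts.

        Solved as the unit-eigenvalue left eigenvector of the context chain
        (contexts shift by one symbol per step).  Order 0 returns a scalar
        array ``[1.0]`` placeholder shaped ``()``-free for uniform handling.
        """
        k = self.alphabet_size
        if self.order == 0:
            return np.ones(1)
        m = k**self.order
        p = np.zeros((m, m))
        for idx, ctx in enumerate(itertools.product(range(k), repeat=self.order)):
            row = self.transitions[ctx]
            for nxt in range(k):
                new_ctx = ctx[1:] + (nxt,)
                j = int(np.ravel_multi_index(new_ctx, (k,) * self.order))
                p[idx, j] += row[nxt]
        # solve pi P = pi, sum pi = 1
        a = np.vstack([p.T - np.eye(m), np.ones(m)])
        b = np.zeros(m + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def window_distribution(self, window: int) -> np.ndarray:
        """Exact stationary joint over ``window`` consecutive symbols.

        Returned as a tensor of shape ``(K,) * window`` with axes ordered
        oldest to newest.  Guarded against enumeration blow-up.
        """
        k = self.alphabet_size
        if k**window > _JOINT_STATE_GUARD:
            raise ValueError("joint enumeration exceeds the size guard")
        if window < 1:
            raise ValueError("window must be >= 1")
        if self.order == 0:
            out = np.ones((k,) * window)
            for axis in range(window):
                shape = [1] * window
                shape[axis] = k
                out = out * self.transitions.reshape(shape)
            return out
        base = max(window, self.order)
        pi_ctx = self.stationary_context_distribution().reshape((k,) * self.order)
        joint = pi_ctx
        # extend one symbol at a time; joint always holds the newest `m` axes
        m = self.order
        while m < base:
            ctx = joint.reshape((k,) * m)
            # condition on the most recent `order` symbols
            next_probs = self.transitions  # shape (K,)*order + (K,)
            expanded = ctx[..., None] * next_probs.reshape(
                (1,) * (m - self.order) + (k,) * self.order + (k,)
            )
            joint = expanded
            m += 1
        joint = joint.reshape((k,) * base)
        # marginalise oldest axes if the requested window is shorter
        while joint.ndim > window:
            joint = joint.sum(axis=0)
        return joint


def _entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float).ravel()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class AnalyticInfo:
    """Exact information quantities of a stationary Markov model."""

    ais: float
    h_next: float
    gte: float

    @property
    def ais_normalized(self) -> float:
        return self.ais / self.h_next if self.h_next > 0 else 0.0


def analytic_ais(model: MarkovModel, lags: tuple[int, ...] | list[int]) -> AnalyticInfo:
    """Exact AIS for a given lag set, plus exact H(X_t) and transition entropy.

    AIS is the mutual information between the next symbol and the selected
    past variables, evaluated on the exact stationary joint over a window of
    ``max(lags) + 1`` symbols by direct enumeration.  The transition entropy
    (GTE) is H(X_t | X_{t-1}) on the exact pair distribution.
    """
    lags = tuple(sorted(set(int(l) for l in lags)))
    if lags and lags[0] < 1:
        raise ValueError("lags must be positive")
    max_lag = lags[-1] if lags else 1
    window = max_lag + 1
    joint = model.window_distribution(window)  # axes: t-max_lag ... t
    h_next = _entropy_bits(joint.sum(axis=tuple(range(window - 1))))

    pair = model.window_distribution(2)
    gte = _entropy_bits(pair) - _entropy_bits(pair.sum(axis=1))

    if not lags:
        return AnalyticInfo(ais=0.0, h_next=h_next, gte=gte)

    keep = {window - 1} | {window - 1 - l for l in lags}  # axis of X_{t-l}
    drop = tuple(ax for ax in range(window) if ax not in keep)
    sub = joint.sum(axis=drop) if drop else joint
    # in `sub`, the last axis is X_t, the rest are the past variables
    h_joint = _entropy_bits(sub)
    h_past = _entropy_bits(sub.sum(axis=-1))
    ais = h_past + h_next - h_joint
    return AnalyticInfo(ais=max(ais, 0.0), h_next=h_next, gte=gte)


# ---------------------------------------------------------------------------
# chain generation


def generate_chain(
    model: MarkovModel,
    length: int,
    seed: int | np.random.Generator,
    participant_id: str = "",
    trial_id: str = "",
    condition: str = "",
    burn_in: int = 0,
) -> Scanpath:
    """Sample a scanpath of ``length`` symbols from a Markov model.

    The initial context is drawn from the exact stationary context
    distribution (so the realized process is stationary from the first
    symbol); a ``burn_in`` is available but unnecessary with stationary
    initialisation.
    """
    if length <= model.order:
        raise ValueError("length must exceed the model order")
    rng = np.random.default_rng(seed)
    k = model.alphabet_size
    total = length + burn_in

    if model.order == 0:
        cum = np.cumsum(model.transitions)
        u = rng.random(total)
        symbols = np.searchsorted(cum, u, side="right")
        return Scanpath(symbols[burn_in:], k, participant_id, trial_id, condition)

    pi_ctx = model.stationary_context_distribution()
    ctx_idx = rng.choice(pi_ctx.size, p=pi_ctx)
    context = list(np.unravel_index(ctx_idx, (k,) * model.order))
    cum_rows = np.cumsum(model.transitions.reshape(-1, k), axis=1)
    shape = (k,) * model.order
    symbols = np.empty(total + model.order, dtype=np.int64)
    symbols[: model.order] = context
    u = rng.random(total)
    for t in range(total):
        row = int(np.ravel_multi_index(tuple(context), shape))
        nxt = int(np.searchsorted(cum_rows[row], u[t], side="right"))
        symbols[model.order + t] = nxt
        context = context[1:] + [nxt]
    # the first `order` symbols come from the stationary context itself, so
    # keep them: the emitted sequence is stationary end to end
    out = symbols[: length + burn_in][burn_in:] if burn_in else symbols[:length]
    return Scanpath(out, k, participant_id, trial_id, condition)


# ---------------------------------------------------------------------------
# gaze traces


def generate_gaze_trace(
    fixation_plan: list[tuple[float, float, float]],
    noise_sd: float = 3.0,
    rate: float = 120.0,
    saccade_ms: float = 40.0,
    seed: int | np.random.Generator = 0,
    low_conf_fraction: float = 0.0,
    participant_id: str = "",
    trial_id: str = "",
    condition: str = "",
) -> GazeRecording:
    """Continuous gaze trace with planted fixation clusters.

    ``fixation_plan`` lists (x [px], y [px], duration [ms]) targets; samples
    are drawn at ``rate`` Hz around each target with isotropic Gaussian noise
    and consecutive targets are joined by short linear saccade segments.
    Confidence is drawn in [0.92, 1.0] except for an optional planted
    fraction of low-confidence samples (drawn in [0, 0.9)).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if any(d <= 0 for _, _, d in fixation_plan):
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate
    xs: list[float] = []
    ys: list[float] = []
    for i, (fx, fy, dur_ms) in enumerate(fixation_plan):
        n_fix = max(int(round(dur_ms / 1000.0 * rate)) + 1, 2)
        xs.extend(fx + rng.normal(0.0, noise_sd, n_fix))
        ys.extend(fy + rng.normal(0.0, noise_sd, n_fix))
        if i + 1 < len(fixation_plan):
            nx, ny, _ = fixation_plan[i + 1]
            n_sac = max(int(round(saccade_ms / 1000.0 * rate)), 1)
            frac = np.arange(1, n_sac + 1) / (n_sac + 1)
            xs.extend(fx + frac * (nx - fx))
            ys.extend(fy + frac * (ny - fy))
    n = len(xs)
    t = np.arange(n) * dt
    conf = rng.uniform(0.92, 1.0, n)
    if low_conf_fraction > 0:
        n_low = int(round(low_conf_fraction * n))
        low_idx = rng.choice(n, size=n_low, replace=False)
        conf[low_idx] = rng.uniform(0.0, 0.9 - 1e-9, n_low)
    return GazeRecording(
        participant_id=participant_id,
        trial_id=trial_id,
        condition=condition,
        t=t,
        x=np.asarray(xs),
        y=np.asarray(ys),
        confidence=conf,
    )


# ---------------------------------------------------------------------------
# study designs


def default_condition_models(alphabet_size: int = 4) -> tuple[MarkovModel, MarkovModel]:
    """Default (TUC, TC) generator pair over the 4-AOI alphabet.

    TUC: an order-1 chain with a strong cyclic scanning structure
    (probability 0.7 of advancing to the "next" AOI, remainder spread
    uniformly) — near-uniform stationary distribution, high entropy,
    substantial predictability.

    TC: each transition row is pulled toward a fixed context-independent
    preference for one AOI (gaze concentrating on fewer regions under time
    pressure) mixed with a weakened copy of the cyclic structure — lower
    stationary entropy and lower normalized predictability.
    """
    k = alphabet_size

    def cyclic(step: float) -> np.ndarray:
        rows = np.full((k, k), (1.0 - step) / (k - 1))
        for i in range(k):
            rows[i, (i + 1) % k] = step
        return rows

    # TUC: H(X_t) = 2 bits, lag-1 AIS ~= 0.79 bits (normalized ~= 0.40)
    tuc = MarkovModel(order=1, alphabet_size=k, transitions=cyclic(0.75))
    # TC: 40% context-independent pull toward one AOI over a weaker cycle;
    # H(X_t) ~= 1.87 bits, lag-1 AIS ~= 0.27 bits (normalized ~= 0.14)
    pref = np.full(k, 0.2 / (k - 1))
    pref[0] = 0.8
    tc_rows = 0.40 * pref[None, :] + 0.60 * cyclic(0.70)
    tc = MarkovModel(order=1, alphabet_size=k, transitions=tc_rows)
    return tuc, tc


def mixture_lag_model(
    weights: tuple[float, ...],
    advance: float = 0.85,
    alphabet_size: int = 4,
) -> MarkovModel:
    """Order-k chain mixing one sharp transition rule per lag.

    The next-symbol distribution is a convex mixture over lags l = 1..k with
    the given weights; the lag-l component places probability ``advance`` on
    (x_{t-l} + l) mod K and spreads the rest uniformly.  Every lag is
    individually and conditionally informative (no pure-synergy structure),
    which makes the model a suitable ground truth for greedy forward
    selection of the embedding: the true minimal lag set is exactly {1..k}.
    """
    k = len(weights)
    if k < 1 or not np.isclose(sum(weights), 1.0):
        raise ValueError("weights must be a non-empty tuple summing to 1")
    K = alphabet_size
    rest = (1.0 - advance) / (K - 1)
    transitions = np.zeros((K,) * k + (K,))
    for ctx in itertools.product(range(K), repeat=k):
        row = np.zeros(K)
        for lag, w in enumerate(weights, start=1):
            comp = np.full(K, rest)
            comp[(ctx[k - lag] + lag) % K] = advance
            row += w * comp
        transitions[ctx] = row
    return MarkovModel(order=k, alphabet_size=K, transitions=transitions)


@dataclass(frozen=True)
class StudyDesign:
    """Two-condition study layout with planted observer-state effect.

    Defaults mirror a small within-subject visual-comparison experiment:
    10 participants, 22 trials per condition, 4 AOIs.  TC trials are shorter
    (time-limited search) than TUC trials.  ``participant_concentration``
    controls inter-individual variability: each participant's transition rows
    are Dirichlet perturbations of the condition model with this
    concentration scale (larger = less variability).
    """

    n_participants: int = 10
    trials_per_condition: int = 22
    model_tuc: MarkovModel = field(default_factory=lambda: default_condition_models()[0])
    model_tc: MarkovModel = field(default_factory=lambda: default_condition_models()[1])
    length_range_tuc: tuple[int, int] = (50, 90)
    length_range_tc: tuple[int, int] = (25, 45)
    participant_concentration: float = 150.0

    def __post_init__(self) -> None:
        if self.model_tuc.alphabet_size != self.model_tc.alphabet_size:
            raise ValueError("condition models must share an alphabet")


def default_study_design(**overrides) -> StudyDesign:
    return StudyDesign(**overrides)


def _perturb_model(model: MarkovModel, concentration: float, rng: np.random.Generator) -> MarkovModel:
    k = model.alphabet_size
    rows = model.transitions.reshape(-1, k)
    new_rows = np.empty_like(rows)
    for i, row in enumerate(rows):
        alpha = np.clip(row * concentration, 1e-3, None)
        new_rows[i] = rng.dirichlet(alpha)
    return MarkovModel(
        order=model.order,
        alphabet_size=k,
        transitions=new_rows.reshape(model.transitions.shape),
    )


@dataclass(frozen=True)
class StudyData:
    """Generated study: scanpaths plus per-participant analytic targets."""

    scanpaths: tuple[Scanpath, ...]
    analytic_targets: pd.DataFrame
    design: StudyDesign


def generate_study(design: StudyDesign, seed: int | np.random.Generator = 0) -> StudyData:
    """Generate all trials of a two-condition study.

    Each participant gets its own Dirichlet-perturbed copy of both condition
    models; trial lengths are drawn uniformly from the per-condition range.
    The returned table of analytic targets holds the exact lag-1 AIS, H(X_t),
    normalized AIS and transition entropy of every participant-condition
    generator, for recovery tests.
    """
    rng = np.random.default_rng(seed)
    scanpaths: list[Scanpath] = []
    targets: list[dict] = []
    for p in range(design.n_participants):
        pid = f"P{p:02d}"
        for cond, model, length_range in (
            ("TUC", design.model_tuc, design.length_range_tuc),
            ("TC", design.model_tc, design.length_range_tc),
        ):
            pmodel = _perturb_model(model, design.participant_concentration, rng)
            info = analytic_ais(pmodel, lags=(1,))
            targets.append(
                {
                    "participant": pid,
                    "condition": cond,
                    "ais": info.ais,
                    "h_next": info.h_next,
                    "ais_norm": info.ais_normalized,
                    "gte": info.gte,
                }
            )
            lo, hi = length_range
            for trial in range(design.trials_per_condition):
                length = int(rng.integers(lo, hi + 1))
                scanpaths.append(
                    generate_chain(
                        pmodel,
                        length,
                        rng,
                        participant_id=pid,
                        trial_id=f"{cond}{trial:02d}",
                        condition=cond,
                    )
                )
    return StudyData(
        scanpaths=tuple(scanpaths),
        analytic_targets=pd.DataFrame(targets),
        design=design,
    )
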
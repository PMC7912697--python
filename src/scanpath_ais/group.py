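"""Between-condition comparisons with estimation bias held constant.

Plug-in information estimates are biased as a function of the sample count
and the dimension of the variables entering the estimator.  To compare two
conditions within a participant without a bias confound, all of that
participant's trials are re-embedded with one *uniform* past state — the
union of the per-trial selected lag sets — and truncated from the beginning
so every trial contributes the same number of embedded samples.  Condition
differences are then assessed with independent-samples permutation tests on
the per-trial values of AIS, H(X_t) and AIS/H(X_t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .embedding import (
    MIN_EMBEDDED_SAMPLES,
    AISResult,
    InsufficientSamplesError,
    PastStateSpec,
    estimate_ais,
    optimize_past_state,
)
from .preprocessing import Scanpath

__all__ = [
    "PermTestOutcome",
    "GroupAnalysisReport",
    "union_past_state",
    "equalize_samples",
    "permutation_test_conditions",
    "run_group_analysis",
    "results_to_table",
]

logger = logging.getLogger(__name__)

MEASURES = ("ais", "h_next", "ais_norm")


def union_past_state(specs: Iterable[PastStateSpec]) -> PastStateSpec:
    """Union of selected lags over trials; k_max = maximum over inputs.

    The union contains all relevant past variables for the participant, at
    the cost of including lags irrelevant for some trials.  All-empty input
    yields an empty union (the participant cannot be compared).
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one spec")
    lags: set[int] = set()
    for s in specs:
        lags.update(s.lags)
    return PastStateSpec(lags=tuple(sorted(lags)), k_max=max(s.k_max for s in specs))


def equalize_samples(
    scanpaths: Sequence[Scanpath],
    union_spec: PastStateSpec,
    min_samples: int = MIN_EMBEDDED_SAMPLES,
) -> pd.DataFrame:
    """Re-estimate one participant's trials under a uniform past state.

    Every usable trial is embedded with ``union_spec`` and truncated from the
    beginning to the common sample count N* = minimum embedded length over
    usable trials, so the estimation bias (a function of n and the past-state
    dimension) is constant across all values entering a comparison.  AIS is
    left uncorrected here: with constant bias the comparisons are unaffected
    and the surrogate-based significance handles the offset.

    Returns a tidy per-trial table (participant, condition, trial, n_samples,
    ais, h_next, ais_norm, gte).
    """
    if not union_spec:
        raise ValueError("cannot equalize with an empty union spec")
    offset = union_spec.max_lag
    usable = [sp for sp in scanpaths if len(sp) - offset >= min_samples]
    dropped = len(scanpaths) - len(usable)
    if dropped:
        logger.warning(
            "dropping %d trial(s) below %d embedded samples", dropped, min_samples
        )
    if not usable:
        raise InsufficientSamplesError("no usable trials after equalization")
    n_star = min(len(sp) - offset for sp in usable)
    rows = []
    for sp in usable:
        res = estimate_ais(
            sp,
            union_spec,
            correct_bias=False,
            n_perm=0,
            max_samples=n_star,
        )
        rows.append(_result_row(res))
    return pd.DataFrame(rows)


def _result_row(res: AISResult) -> dict:
    return {
        "participant": res.participant_id,
        "condition": res.condition,
        "trial": res.trial_id,
        "selected_lags": ";".join(str(l) for l in res.spec.lags),
        "ais": res.ais,
        "ais_norm": res.ais_normalized,
        "h_next": res.h_next,
        "gte": res.gte,
        "p_value": res.p_value,
        "n_samples": res.n_samples,
    }


def results_to_table(results: Iterable[AISResult]) -> pd.DataFrame:
    """Serialize per-trial results into the long-format study table."""
    return pd.DataFrame([_result_row(r) for r in results])


@dataclass(frozen=True)
class PermTestOutcome:
    """Independent-samples permutation test on a difference of means."""

    statistic: float
    p_value: float
    n_perm: int
    direction: str
    n_a: int
    n_b: int
    tails: str


def permutation_test_conditions(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
    tails: str = "two",
    labels: tuple[str, str] = ("a", "b"),
) -> PermTestOutcome:
    """Permutation test of mean(a) - mean(b) by random label reassignment.

    ``tails`` is ``"two"`` (default), ``"greater"`` (a > b) or ``"less"``.
    p-values use the add-one convention and are therefore never exactly 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if min(a.size, b.size) < 2:
        logger.warning("a group has fewer than 2 values; test runs on means anyway")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = float(a.mean() - b.mean())
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = perm[:n_a].mean() - perm[n_a:].mean()
    tol = 1e-12
    if tails == "two":
        exceed = int((np.abs(null) >= abs(observed) - tol).sum())
    elif tails == "greater":
        exceed = int((null >= observed - tol).sum())
    elif tails == "less":
        exceed = int((null <= observed + tol).sum())
    else:
        raise ValueError(f"unknown tails: {tails!r}")
    p = (1 + exceed) / (1 + n_perm)
    la, lb = labels
    direction = f"{la}<{lb}" if observed < 0 else (f"{la}>{lb}" if observed > 0 else "=")
    return PermTestOutcome(
        statistic=observed,
        p_value=float(p),
        n_perm=n_perm,
        direction=direction,
        n_a=int(n_a),
        n_b=int(b.size),
        tails=tails,
    )


@dataclass(frozen=True)
class GroupAnalysisReport:
    """Output of the full group workflow.

    ``tests`` has one row per (participant, measure) with the permutation
    statistic, p-value and direction; ``trial_table`` is the equalized
    per-trial table (the export hook for external mixed-model fitting);
    ``union_specs`` maps participant -> uniform past state; ``excluded``
    lists participants without any significant past state.
    """

    tests: pd.DataFrame
    trial_table: pd.DataFrame
    union_specs: dict[str, PastStateSpec]
    excluded: tuple[str, ...]

    def significant_counts(self, alpha: float = 0.05) -> pd.DataFrame:
        """Participants significant per measure and direction."""
        t = self.tests
        sig = t[t["p_value"] < alpha]
        return (
            sig.groupby(["measure", "direction"])["participant"]
            .nunique()
            .rename("n_participants")
            .reset_index()
        )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def run_group_analysis(
    scanpaths: Sequence[Scanpath],
    k_max: int = 5,
    selection_n_perm: int = 200,
    selection_alpha: float = 0.05,
    n_perm: int = 5000,
    tails: str = "two",
    seed: int | np.random.Generator | None = None,
    specs: Mapping[tuple[str, str], PastStateSpec] | None = None,
    holm: bool = False,
) -> GroupAnalysisReport:
    """Per-participant condition comparisons on AIS, H(X_t), and AIS/H(X_t).

    For each participant: optimize a past state per trial (unless ``specs``
    provides pre-computed ones keyed by (participant, trial)), form the
    union, re-embed and equalize sample counts, then run an
    independent-samples permutation test per measure between the two
    condition labels (sorted order defines the sign of the statistic).

    Per-participant tests are reported unadjusted by default; ``holm=True``
    adds a ``p_holm`` column with a step-down adjustment across participants
    within each measure.
    """
    rng = np.random.default_rng(seed)
    by_participant: dict[str, list[Scanpath]] = {}
    for sp in scanpaths:
        by_participant.setdefault(sp.participant_id, []).append(sp)

    conditions = sorted({sp.condition for sp in scanpaths})
    if len(conditions) != 2:
        raise ValueError(f"expected exactly 2 condition labels, got {conditions}")
    cond_a, cond_b = conditions

    test_rows = []
    trial_tables = []
    union_specs: dict[str, PastStateSpec] = {}
    excluded: list[str] = []
    for pid in sorted(by_participant):
        trials = by_participant[pid]
        per_trial_specs = []
        for sp in trials:
            if specs is not None and (pid, sp.trial_id) in specs:
                per_trial_specs.append(specs[(pid, sp.trial_id)])
                continue
            try:
                per_trial_specs.append(
                    optimize_past_state(
                        sp,
                        k_max=k_max,
                        n_perm=selection_n_perm,
                        alpha=selection_alpha,
                        seed=rng,
                    )
                )
            except InsufficientSamplesError:
                logger.warning("skipping short trial %s/%s", pid, sp.trial_id)
        if not per_trial_specs:
            excluded.append(pid)
            continue
        union = union_past_state(per_trial_specs)
        if not union:
            logger.warning("participant %s: no significant past state; excluded", pid)
            excluded.append(pid)
            continue
        union_specs[pid] = union
        table = equalize_samples(trials, union)
        trial_tables.append(table)
        for measure in MEASURES:
            va = table.loc[table["condition"] == cond_a, measure].to_numpy()
            vb = table.loc[table["condition"] == cond_b, measure].to_numpy()
            if va.size == 0 or vb.size == 0:
                logger.warning("participant %s lacks condition data; skipped", pid)
                continue
            outcome = permutation_test_conditions(
                va, vb, n_perm=n_perm, seed=rng, tails=tails, labels=(cond_a, cond_b)
            )
            test_rows.append(
                {
                    "participant": pid,
                    "measure": measure,
                    "statistic": outcome.statistic,
                    "p_value": outcome.p_value,
                    "direction": outcome.direction,
                    "n_a": outcome.n_a,
                    "n_b": outcome.n_b,
                }
            )
    tests_df = pd.DataFrame(test_rows)
    if holm and len(tests_df):
        tests_df["p_holm"] = np.nan
        for measure, g in tests_df.groupby("measure"):
            tests_df.loc[g.index, "p_holm"] = holm_adjust(g["p_value"].to_numpy())
    return GroupAnalysisReport(
        tests=tests_df,
        trial_table=pd.concat(trial_tables, ignore_index=True)
        if trial_tables
        else pd.DataFrame(),
        union_specs=union_specs,
        excluded=tuple(excluded),
    )
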
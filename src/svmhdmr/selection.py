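"""Two-stage bottom-up feature elimination.

Stage 1 repeatedly refits the classifier, ranks features by the main-effect
index of the scores, and removes the low-index tail in batches, guarded by
the cross-validated misclassification rate.  Stage 2 switches to the
structural index of the additive score expansion and removes one feature at a
time until the guard blocks further removal.  The inverse removal order plus
the final subset (ordered by structural index) yields a full prioritization of
all starting features at a cost of tens of model fits, versus the combinatorial
cost of a wrapper search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .datasets import FeatureTable
from .errors import ConfigurationError
from .hdmr import build_kernel_bank, compute_scsa, fit_svr_hdmr
from .main_effect import compute_main_effects
from .scoring import cross_validated_mce, fit_svm

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "propose_tail_batch",
    "prune_stage1",
    "prune_stage2",
    "two_stage_select",
    "wrapper_combination_count",
]


@dataclass
class SelectionStep:
    """One guarded removal attempt."""

    stage: int
    candidates_removed: list[str]
    guard_mce_before: float
    guard_mce_after: float
    accepted: bool
    indices_snapshot: dict[str, float]
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "candidates_removed": self.candidates_removed,
            "guard_mce_before": self.guard_mce_before,
            "guard_mce_after": self.guard_mce_after,
            "accepted": self.accepted,
            "indices_snapshot": self.indices_snapshot,
            "note": self.note,
        }


@dataclass
class SelectionTrace:
    """Ordered record of a two-stage run: steps, final subset, prioritization,
    settings and total model-fit counts."""

    steps: list[SelectionStep] = field(default_factory=list)
    final_subset: list[str] = field(default_factory=list)
    prioritization: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)
    removed_order: list[str] = field(default_factory=list)
    n_svm_fits: int = 0
    n_hdmr_fits: int = 0
    final_indices: dict | None = None
    final_mce: float | None = None

    @property
    def n_model_fits(self) -> int:
        return self.n_svm_fits + self.n_hdmr_fits

    def to_dict(self) -> dict:
        return {
            "steps": [s.to_dict() for s in self.steps],
            "final_subset": self.final_subset,
            "prioritization": self.prioritization,
            "settings": self.settings,
            "removed_order": self.removed_order,
            "n_svm_fits": self.n_svm_fits,
            "n_hdmr_fits": self.n_hdmr_fits,
            "n_model_fits": self.n_model_fits,
            "final_indices": self.final_indices,
            "final_mce": self.final_mce,
        }


def wrapper_combination_count(n: int, k_max: int) -> int:
    """Number of feature subsets of size 1..k_max out of n, exact integer."""
    if not 1 <= k_max <= n:
        raise ConfigurationError("need 1 <= k_max <= n")
    return sum(math.comb(n, i) for i in range(1, k_max + 1))


def wrapper_combination_count_bruteforce(n: int, k_max: int) -> int:
    """Independent enumeration check (small n only)."""
    return sum(1 for k in range(1, k_max + 1) for _ in combinations(range(n), k))


def propose_tail_batch(
    indices: dict[str, float],
    cap: int | None = None,
    min_gap_ratio: float = 1.5,
) -> list[str] | None:
    """Pick the low-index tail below the largest relative gap.

    Features are sorted by decreasing index; among splits leaving a tail of at
    most ``cap`` features (default ``ceil(n/4)``), the split with the largest
    ratio of neighboring index values is chosen.  Returns ``None`` if no gap
    reaches ``min_gap_ratio``.
    """
    names = sorted(indices, key=lambda k: (-indices[k], k))
    vals = np.array([indices[k] for k in names])
    n = len(names)
    if n < 3:
        return None
    if cap is None:
        cap = math.ceil(n / 4)
    cap = min(cap, n - 2)
    eps = 1e-300
    best_ratio, best_tail = 0.0, None
    for tail in range(1, cap + 1):
        ratio = (vals[n - tail - 1] + eps) / (vals[n - tail] + eps)
        if ratio > best_ratio:
            best_ratio, best_tail = ratio, tail
    if best_tail is None or best_ratio < min_gap_ratio:
        return None
    return names[n - best_tail:]


def _guarded_attempt(
    table: FeatureTable,
    current: list[str],
    batch: list[str],
    mce_before: float,
    guard_delta: float,
    folds: int,
    cost: float,
    seed: int,
    trace: SelectionTrace,
    stage: int,
    indices: dict[str, float],
    note: str = "",
) -> bool:
    remaining = [f for f in current if f not in batch]
    mce_after = cross_validated_mce(
        table, remaining, k_folds=folds, cost=cost, seed=seed
    ).mce
    trace.n_svm_fits += 1
    accepted = (mce_after - mce_before) <= guard_delta
    trace.steps.append(
        SelectionStep(
            stage=stage,
            candidates_removed=list(batch),
            guard_mce_before=mce_before,
            guard_mce_after=mce_after,
            accepted=accepted,
            indices_snapshot={k: float(v) for k, v in indices.items()},
            note=note,
        )
    )
    return accepted


def prune_stage1(
    table: FeatureTable,
    current_features: list[str] | None = None,
    guard_delta: float = 0.015,
    seed: int = 0,
    folds: int = 10,
    cost: float = 1.0,
    degree: int = 3,
    floor: int = 15,
    max_skip: int = 3,
    batch_cap: int | None = None,
    trace: SelectionTrace | None = None,
) -> tuple[list[str], SelectionTrace]:
    """Pre-selection by the main-effect index with a CV-MCE guard.

    Each round refits the classifier on the current features, ranks them by
    main effect, and proposes the tail batch below the largest index gap
    (capped).  A rejected batch falls back to single removals, skipping upward
    past at most ``max_skip`` guard-protected features (a small index caused by
    negative correlation is kept if removing it costs accuracy).  The stage
    ends at the feature floor or when no removal passes the guard.
    """
    current = list(current_features) if current_features else list(table.feature_names)
    if len(current) < 3:
        raise ConfigurationError("stage 1 needs at least 3 features")
    trace = trace or SelectionTrace()
    mce_current: float | None = None
    while len(current) > max(floor, 3):
        _, score_set = fit_svm(table, current, cost=cost, seed=seed)
        trace.n_svm_fits += 1
        me = compute_main_effects(table.subset(current), score_set, degree=degree)
        if mce_current is None:
            mce_current = cross_validated_mce(
                table, current, k_folds=folds, cost=cost, seed=seed
            ).mce
            trace.n_svm_fits += 1
        mce_before = mce_current
        ascending = sorted(current, key=lambda k: (me.s_hat[k], k))

        cap = batch_cap if batch_cap is not None else math.ceil(len(current) / 4)
        cap = min(cap, len(current) - max(floor, 3))
        accepted_any = False
        batch = propose_tail_batch(me.s_hat, cap=cap)
        if batch is not None and len(batch) > 1:
            if _guarded_attempt(
                table, current, batch, mce_before, guard_delta, folds, cost,
                seed, trace, stage=1, indices=me.s_hat, note="gap-rule batch",
            ):
                current = [f for f in current if f not in batch]
                trace.removed_order.extend(batch)
                mce_current = trace.steps[-1].guard_mce_after
                accepted_any = True
        if not accepted_any:
            for k in range(min(max_skip, len(ascending))):
                cand = [ascending[k]]
                note = "singleton" if k == 0 else f"singleton (skip-up {k})"
                if _guarded_attempt(
                    table, current, cand, mce_before, guard_delta, folds, cost,
                    seed, trace, stage=1, indices=me.s_hat, note=note,
                ):
                    current = [f for f in current if f not in cand]
                    trace.removed_order.extend(cand)
                    mce_current = trace.steps[-1].guard_mce_after
                    accepted_any = True
                    break
        if not accepted_any:
            break
    return current, trace


def prune_stage2(
    table: FeatureTable,
    current_features: list[str],
    guard_delta: float = 0.015,
    seed: int = 0,
    folds: int = 10,
    cost: float = 1.0,
    kernel_family: str = "rbf",
    bandwidth="median",
    kernel_c: float = 1.0,
    svr_cost: float = 10.0,
    epsilon: float | None = None,
    min_features: int = 2,
    max_skip: int = 1,
    trace: SelectionTrace | None = None,
) -> tuple[list[str], SelectionTrace]:
    """Refined one-at-a-time elimination driven by the structural index.

    Each round fits the classifier, builds the additive expansion of its
    scores, and proposes removing the feature with the smallest structural
    index; the guard accepts only removals that do not degrade the CV MCE by
    more than ``guard_delta``.  On termination the surviving features are
    ordered by decreasing structural index.
    """
    current = list(current_features)
    if len(current) < 2:
        raise ConfigurationError("stage 2 needs at least 2 features")
    trace = trace or SelectionTrace()
    mce_current: float | None = None
    scsa = None
    while True:
        # refit the score model and its additive expansion for the current set
        _, score_set = fit_svm(table, current, cost=cost, seed=seed)
        trace.n_svm_fits += 1
        bank = build_kernel_bank(
            table, current, family=kernel_family, bandwidth=bandwidth, c=kernel_c
        )
        model = fit_svr_hdmr(bank, score_set, epsilon=epsilon, cost=svr_cost)
        trace.n_hdmr_fits += 1
        scsa = compute_scsa(model, score_set)
        sa = dict(zip(scsa.feature_names, scsa.sa))
        if len(current) <= min_features:
            break
        if mce_current is None:
            mce_current = cross_validated_mce(
                table, current, k_folds=folds, cost=cost, seed=seed
            ).mce
            trace.n_svm_fits += 1
        mce_before = mce_current
        ascending = sorted(current, key=lambda k: (sa[k], k))
        accepted_any = False
        for k in range(min(max_skip, len(ascending))):
            cand = [ascending[k]]
            note = "smallest structural index" if k == 0 else f"skip-up {k}"
            if _guarded_attempt(
                table, current, cand, mce_before, guard_delta, folds, cost,
                seed, trace, stage=2, indices=sa, note=note,
            ):
                current = [f for f in current if f not in cand]
                trace.removed_order.extend(cand)
                mce_current = trace.steps[-1].guard_mce_after
                accepted_any = True
                break
        if not accepted_any:
            break

    if mce_current is None:
        mce_current = cross_validated_mce(
            table, current, k_folds=folds, cost=cost, seed=seed
        ).mce
        trace.n_svm_fits += 1
    trace.final_subset = sorted(current, key=lambda k: (-sa[k], k))
    trace.final_indices = scsa.to_dict()
    trace.final_mce = mce_current
    trace.prioritization = trace.final_subset + list(reversed(trace.removed_order))
    return current, trace


def two_stage_select(
    table: FeatureTable,
    guard_delta: float = 0.015,
    seed: int = 0,
    folds: int = 10,
    cost: float = 1.0,
    degree: int = 3,
    stage1_floor: int = 15,
    kernel_family: str = "rbf",
    bandwidth="median",
    kernel_c: float = 1.0,
    svr_cost: float = 10.0,
    epsilon: float | None = None,
    min_features: int = 2,
) -> SelectionTrace:
    """Run stage 1 (main-effect pre-selection) then stage 2 (structural-index
    refinement) over all features of a normalized table."""
    trace = SelectionTrace(
        settings={
            "guard_delta": guard_delta,
            "seed": seed,
            "folds": folds,
            "svm_cost": cost,
            "main_effect_degree": degree,
            "stage1_floor": stage1_floor,
            "kernel_family": kernel_family,
            "bandwidth": str(bandwidth),
            "kernel_c": kernel_c,
            "svr_cost": svr_cost,
            "epsilon": epsilon,
            "min_features": min_features,
        }
    )
    current, trace = prune_stage1(
        table,
        guard_delta=guard_delta,
        seed=seed,
        folds=folds,
        cost=cost,
        degree=degree,
        floor=stage1_floor,
        trace=trace,
    )
    _, trace = prune_stage2(
        table,
        current,
        guard_delta=guard_delta,
        seed=seed,
        folds=folds,
        cost=cost,
        kernel_family=kernel_family,
        bandwidth=bandwidth,
        kernel_c=kernel_c,
        svr_cost=svr_cost,
        epsilon=epsilon,
        min_features=min_features,
        trace=trace,
    )
    return trace
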
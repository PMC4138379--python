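"""Branch-and-bound search for the cheapest screening combination.

The search enumerates assay combinations over a coverage-greedy ordering
(assays contributing the most new events first) as a depth-first prefix
tree, keeping the best strategy found so far and reporting every
improvement as it happens (anytime behaviour).  Two pruning rules keep it
tractable:

1. a branch is abandoned when the screening-run cost ``g(k)`` of its
   combinations already exceeds the best total expected cost — the
   event-specific part is non-negative, so no descendant can win;
2. each candidate's expected cost is accumulated against the incumbent
   as a bound and abandoned as soon as the partial sum exceeds it.

On natural completion the returned strategy is the proven optimum; the
search can also be stopped by a wall-clock budget or a cooperative
interrupt, in which case the best-so-far is returned with
``completed=False``.  ``exhaustive_search`` provides the independent
brute-force reference for small pools.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

from .cost import (
    COST_ATOL,
    CapacityError,
    CostModel,
    Pruned,
    TestingStrategy,
    coverage,
    evaluate_strategy,
    expected_es_lower_bound,
    expected_total_cost,
    run_cost,
)
from .matrix import GMOMatrix, Presence, ScreeningAssay

__all__ = [
    "SearchConfig",
    "TraceRecord",
    "SearchTrace",
    "rank_assays",
    "find_best_strategy",
    "exhaustive_search",
    "count_candidate_combinations",
]


@dataclass
class SearchConfig:
    """Knobs for :func:`find_best_strategy`.

    By default there is no size cap and no coverage constraint: the
    optimum is whatever combination minimizes total expected cost.
    ``interrupt`` is polled between candidate evaluations, so a GUI/CLI
    can stop a long search and keep the best-so-far.
    """

    max_combo_size: int | None = None
    time_budget: float | None = None  # seconds
    interrupt: Callable[[], bool] | None = None
    report_sink: Callable[[str], None] | None = None

    def __post_init__(self) -> None:
        if self.max_combo_size is not None and self.max_combo_size < 1:
            raise ValueError("max_combo_size must be >= 1 when set")


@dataclass(frozen=True)
class TraceRecord:
    elapsed_ms: float
    total_expected_cost: float
    baseline_cost: float
    savings: float
    assay_names: tuple[str, ...]
    coverage_pct: float
    covered_events: int
    total_events: int

    def format_line(self) -> str:
        names = ",".join(self.assay_names) if self.assay_names else "-"
        return (
            f"{self.elapsed_ms:.0f}\t{self.total_expected_cost:.2f}\t"
            f"({self.baseline_cost:.2f}, {self.savings:.2f})\t{names}\t"
            f"({self.coverage_pct:.0f}%, {self.covered_events}/{self.total_events})"
        )


@dataclass
class SearchTrace:
    """Anytime record of the strictly improving best-so-far sequence."""

    records: list[TraceRecord] = field(default_factory=list)
    completed: bool = True


def rank_assays(m: GMOMatrix) -> list[ScreeningAssay]:
    """Coverage-greedy assay ordering.

    The first assay detects the most events; each next one maximizes
    newly covered events given the events already covered.  Ties go to
    the larger summed prior of the newly covered events, then to the
    alphabetically smaller name.
    """
    remaining = list(m.assays)
    covered: set[str] = set()
    ranked: list[ScreeningAssay] = []
    detected = {
        a.name: {ev.name for ev in m.detected_events(a)} for a in m.assays
    }
    priors = {ev.name: ev.prior for ev in m.events}
    while remaining:
        def key(a: ScreeningAssay):
            new = detected[a.name] - covered
            return (-len(new), -sum(priors[e] for e in new), a.name)

        best = min(remaining, key=key)
        remaining.remove(best)
        ranked.append(best)
        covered |= detected[best.name]
    return ranked


def _candidate_key(
    cost: float, names: frozenset[str], coverage_pct: float
) -> tuple:
    """Tie-break ordering: fewer assays, higher coverage, lexicographic."""
    return (len(names), -coverage_pct, tuple(sorted(names)))


def _is_better(
    cost: float,
    names: frozenset[str],
    cov_pct: float,
    best: TestingStrategy,
) -> bool:
    if cost < best.total_expected_cost - COST_ATOL:
        return True
    if cost > best.total_expected_cost + COST_ATOL:
        return False
    return _candidate_key(cost, names, cov_pct) < _candidate_key(
        best.total_expected_cost, best.assay_names, best.coverage_pct
    )


def find_best_strategy(
    m: GMOMatrix,
    cm: CostModel | None = None,
    cfg: SearchConfig | None = None,
) -> tuple[TestingStrategy, SearchTrace]:
    """Minimum total-expected-cost screening combination.

    The empty combination (all-event-specific baseline) is evaluated
    first so a pruning bound exists immediately.  On natural completion
    the result is the global optimum; an exhausted time budget or an
    interrupt yields the best-so-far with ``trace.completed=False``.
    """
    cm = cm or CostModel()
    cfg = cfg or SearchConfig()
    if not m.assays:
        raise ValueError("matrix has no screening assays to search over")

    # Assays detecting nothing only add screening cost; never candidates.
    order = [a for a in rank_assays(m) if m.detected_events(a)]
    t0 = time.perf_counter()
    trace = SearchTrace()

    best = evaluate_strategy(m, (), cm)
    _append_trace(trace, best, t0, cfg, replace_last=False)

    # Rule-1 size cutoff: no strategy can beat g(k) + es_floor, where
    # es_floor is the strategy-independent lower bound on the expected
    # event-specific cost (present events can never be screened away), so
    # branches whose screening run alone is too expensive are abandoned.
    es_floor = expected_es_lower_bound(m, cm)

    def size_limit(best_total: float) -> int:
        kmax = math.floor(
            (best_total + COST_ATOL - es_floor - cm.intercept) / cm.slope
        )
        kmax = max(kmax, 0)
        if cfg.max_combo_size is not None:
            kmax = min(kmax, cfg.max_combo_size)
        return min(kmax, len(order))

    state = {"best": best, "stopped": False}

    def stop_requested() -> bool:
        if cfg.interrupt is not None and cfg.interrupt():
            return True
        if (
            cfg.time_budget is not None
            and time.perf_counter() - t0 > cfg.time_budget
        ):
            return True
        return False

    def dfs(prefix: list[ScreeningAssay], start: int) -> None:
        if state["stopped"]:
            return
        k = len(prefix) + 1
        for i in range(start, len(order)):
            if stop_requested():
                state["stopped"] = True
                return
            best_total = state["best"].total_expected_cost
            if k > size_limit(best_total):
                return  # rule 1: every remaining candidate here is >= size k
            cand = prefix + [order[i]]
            cost = expected_total_cost(m, cand, cm, bound=best_total + COST_ATOL)
            if not isinstance(cost, Pruned):
                names = frozenset(a.name for a in cand)
                cov_pct, _, _ = coverage(m, cand)
                if _is_better(cost, names, cov_pct, state["best"]):
                    tie = (
                        abs(cost - state["best"].total_expected_cost) <= COST_ATOL
                    )
                    state["best"] = evaluate_strategy(m, cand, cm)
                    _append_trace(trace, state["best"], t0, cfg, replace_last=tie)
            dfs(cand, i + 1)
            if state["stopped"]:
                return

    dfs([], 0)
    trace.completed = not state["stopped"]
    return state["best"], trace


def _append_trace(
    trace: SearchTrace,
    s: TestingStrategy,
    t0: float,
    cfg: SearchConfig,
    replace_last: bool,
) -> None:
    rec = TraceRecord(
        elapsed_ms=(time.perf_counter() - t0) * 1000.0,
        total_expected_cost=s.total_expected_cost,
        baseline_cost=s.baseline_cost,
        savings=s.savings,
        assay_names=s.sorted_assays(),
        coverage_pct=s.coverage_pct,
        covered_events=s.covered_events,
        total_events=s.total_events,
    )
    if replace_last and trace.records:
        trace.records[-1] = rec
    else:
        trace.records.append(rec)
    if cfg.report_sink is not None:
        cfg.report_sink(rec.format_line())


def exhaustive_search(
    m: GMOMatrix,
    cm: CostModel | None = None,
    max_size: int | None = None,
    capacity: int = 10**6,
) -> TestingStrategy:
    """Evaluate every combination up to ``max_size`` and return the best.

    The reference behaviour of the earlier exhaustive tool, kept here as
    the independent oracle for the branch-and-bound search.  The empty
    combination (baseline) is always among the candidates.
    """
    cm = cm or CostModel()
    n = len(m.assays)
    if max_size is None:
        max_size = n
    if count_candidate_combinations(n, max_size) > capacity:
        raise CapacityError(
            f"exhaustive search over {n} assays up to size {max_size} "
            f"exceeds the {capacity} combination cap"
        )
    best = evaluate_strategy(m, (), cm)
    for size in range(1, max_size + 1):
        for combo in combinations(m.assays, size):
            cost = expected_total_cost(m, combo, cm)
            assert not isinstance(cost, Pruned)
            names = frozenset(a.name for a in combo)
            cov_pct, _, _ = coverage(m, combo)
            if _is_better(cost, names, cov_pct, best):
                best = evaluate_strategy(m, combo, cm)
    return best


def count_candidate_combinations(n_assays: int, max_size: int) -> int:
    """Number of non-empty assay combinations of size <= max_size."""
    if n_assays < 0 or max_size < 0:
        raise ValueError("counts must be non-negative")
    if max_size > n_assays:
        raise ValueError("max_size cannot exceed the number of assays")
    return sum(math.comb(n_assays, k) for k in range(1, max_size + 1))
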
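"""Expected-cost model for two-phase (screening + event-specific) testing.

A testing strategy runs one screening PCR run with the chosen assay set S,
then one event-specific run confirming every event the screening could not
exclude.  The cost of a run of n assays is linear, ``g(n) = slope*n +
intercept`` (default 21.18 and 91.82 cost units, a fit to real laboratory
labor + reagent costs); a run of zero assays is simply not performed and
costs nothing.

Event presences are modelled as independent Bernoulli variables with the
priors stored in the matrix, and assays as perfectly sensitive/specific:
an assay is positive iff some present event carries its target element.
The total expected cost of S is then

    E[cost] = g(|S|) + sum over outcome patterns o of P(o) * g(N(o))

where the sum ranges over the 2^|S| positive/negative patterns and N(o)
is the number of distinct event-specific assays still required under o:
an event stays a candidate if it is uncovered (no assay in S detects it)
or if every assay detecting it came back positive.

``expected_total_cost`` computes this exactly via a signed superset
(Mobius) transform over the pattern lattice; ``brute_force_expected_cost``
is an independent oracle that enumerates all 2^E presence worlds and must
agree to 1e-9.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .matrix import GMEvent, GMOMatrix, Outcome, Presence, ScreeningAssay

__all__ = [
    "CostModel",
    "OutcomePattern",
    "TestingStrategy",
    "PRUNED",
    "Pruned",
    "CapacityError",
    "run_cost",
    "standalone_negative_prob",
    "candidate_count",
    "enumerate_patterns",
    "expected_total_cost",
    "expected_es_lower_bound",
    "brute_force_expected_cost",
    "coverage",
    "evaluate_strategy",
]

#: Absolute tolerance for cost comparisons throughout the package.
COST_ATOL = 1e-9

#: Refuse to enumerate outcome patterns above this combination size.
DEFAULT_PATTERN_CAP = 25


class CapacityError(ValueError):
    """Problem size exceeds an enumeration cap."""


class Pruned:
    """Sentinel: cost computation abandoned because it exceeded the bound."""

    _instance: "Pruned | None" = None

    def __new__(cls) -> "Pruned":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "PRUNED"


PRUNED = Pruned()


@dataclass(frozen=True)
class CostModel:
    """Linear per-run cost: ``g(n) = slope * n + intercept`` for n > 0."""

    slope: float = 21.18
    intercept: float = 91.82
    zero_assay_run_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("cost slope must be positive")
        if self.intercept < 0:
            raise ValueError("cost intercept must be non-negative")


@dataclass
class OutcomePattern:
    """One joint screening outcome with its probability and consequence."""

    outcomes: dict[str, Outcome]
    probability: float
    candidate_count: int


@dataclass(frozen=True)
class TestingStrategy:
    """A screening-assay combination with its derived cost metrics."""

    assay_names: frozenset[str]
    screening_cost: float
    expected_es_cost: float
    total_expected_cost: float
    coverage_pct: float
    covered_events: int
    total_events: int
    baseline_cost: float
    savings: float

    def sorted_assays(self) -> tuple[str, ...]:
        return tuple(sorted(self.assay_names))


def run_cost(n: int, cm: CostModel | None = None) -> float:
    """Cost of one PCR run containing ``n`` assays; a 0-assay run costs 0."""
    cm = cm or CostModel()
    if n < 0:
        raise ValueError(f"number of assays must be non-negative, got {n}")
    if n == 0:
        return cm.zero_assay_run_cost
    return cm.slope * n + cm.intercept


def standalone_negative_prob(m: GMOMatrix, assay: ScreeningAssay | str) -> float:
    """P(assay negative) if used alone: no detected event is present."""
    prob = 1.0
    for ev in m.detected_events(assay):
        prob *= 1.0 - ev.prior
    return prob


def _resolve(m: GMOMatrix, assays) -> list[ScreeningAssay]:
    amap = m.assay_map()
    out = []
    for a in assays:
        name = a.name if isinstance(a, ScreeningAssay) else a
        if name not in amap:
            raise ValueError(f"assay {name!r} not in matrix pool")
        out.append(amap[name])
    return out


def candidate_count(
    m: GMOMatrix,
    assays,
    outcomes: dict[str, Outcome],
) -> int:
    """Distinct event-specific assays still needed under a screening pattern.

    An event remains a candidate if no assay in the combination detects it
    (uncovered events are always confirmed event-specifically) or if every
    assay detecting it is POSITIVE.  UNKNOWN cells do not count as
    detections here: an assay is not credited with excluding an event it
    may not detect.
    """
    pool = _resolve(m, assays)
    missing = [a.name for a in pool if a.name not in outcomes]
    if missing:
        raise ValueError(f"pattern missing outcomes for assays {missing}")
    needed: set[str] = set()
    for ev in m.events:
        detecting = [
            a for a in pool if ev.presence(a.target_element) is Presence.PRESENT
        ]
        if not detecting or all(
            outcomes[a.name] is Outcome.POSITIVE for a in detecting
        ):
            needed.add(ev.es_assay_id)
    return len(needed)


# ---------------------------------------------------------------------------
# Exact pattern-lattice computation
# ---------------------------------------------------------------------------


def _pattern_tables(
    m: GMOMatrix, pool: list[ScreeningAssay]
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and candidate counts for all 2^k outcome patterns.

    Patterns are indexed by the bitmask N of NEGATIVE assays (bit i set =
    pool[i] negative).  ``prob[N]`` is the exact probability that the
    negative set is exactly N; ``counts[N]`` the distinct event-specific
    assays still required.

    prob is obtained from f(B) = P(all assays in B negative) = product over
    events detected by B of (1 - p), via the signed superset transform
    prob[N] = sum_{B >= N} (-1)^{|B \\ N|} f(B).
    """
    k = len(pool)
    size = 1 << k
    n = len(m.events)
    masks_idx = np.arange(size, dtype=np.int64)

    # Detection bitmask per event over the pool.
    ev_masks = np.zeros(n, dtype=np.int64)
    priors = np.empty(n, dtype=np.float64)
    es_ids: list[str] = []
    for j, ev in enumerate(m.events):
        d = 0
        for i, a in enumerate(pool):
            if ev.presence(a.target_element) is Presence.PRESENT:
                d |= 1 << i
        ev_masks[j] = d
        priors[j] = ev.prior
        es_ids.append(ev.es_assay_id)

    if size * n <= 2 * 10**7:
        # Batched path: hit[N, j] = event j detected by some negative assay.
        hit = (masks_idx[:, None] & ev_masks[None, :]) != 0
        f = np.where(hit, (1.0 - priors)[None, :], 1.0).prod(axis=1)
        # Event j is a candidate under N iff no negative assay detects it
        # (covers the uncovered mask 0 too).
        candidate = ~hit
    else:
        # Memory-light path for large combinations: aggregate events by
        # detection signature before touching the 2^k lattice.
        sig_q: dict[int, float] = {}
        for d, p in zip(ev_masks.tolist(), priors):
            if d:
                sig_q[d] = sig_q.get(d, 1.0) * (1.0 - p)
        f = np.ones(size, dtype=np.float64)
        for d, q in sig_q.items():
            f[(masks_idx & d) != 0] *= q
        candidate = None

    # Signed superset Mobius transform, one bit at a time:
    # prob[N] = sum_{B >= N} (-1)^{|B \ N|} f(B).
    prob = f  # f is not needed afterwards; transform in place
    for i in range(k):
        bit = 1 << i
        lo = np.nonzero((masks_idx & bit) == 0)[0]
        prob[lo] -= prob[lo | bit]
    np.clip(prob, 0.0, None, out=prob)  # scrub float-noise negatives

    # Distinct event-specific assays needed per pattern.
    if candidate is not None and len(set(es_ids)) == n:
        counts = candidate.sum(axis=1)
    else:
        groups: dict[str, list[int]] = {}
        for j, es in enumerate(es_ids):
            groups.setdefault(es, []).append(j)
        counts = np.zeros(size, dtype=np.int64)
        for idx in groups.values():
            if candidate is not None:
                counts += candidate[:, idx].any(axis=1)
            else:
                need = np.zeros(size, dtype=bool)
                for j in idx:
                    need |= (masks_idx & int(ev_masks[j])) == 0
                counts += need
    return prob, counts


def enumerate_patterns(m: GMOMatrix, assays) -> list[OutcomePattern]:
    """All 2^k outcome patterns with exact probabilities (small k only)."""
    pool = _resolve(m, assays)
    if len(pool) > 20:
        raise CapacityError("pattern enumeration limited to 20 assays")
    prob, counts = _pattern_tables(m, pool)
    patterns = []
    for neg_mask in range(1 << len(pool)):
        outcomes = {
            a.name: (Outcome.NEGATIVE if neg_mask & (1 << i) else Outcome.POSITIVE)
            for i, a in enumerate(pool)
        }
        patterns.append(
            OutcomePattern(
                outcomes=outcomes,
                probability=float(prob[neg_mask]),
                candidate_count=int(counts[neg_mask]),
            )
        )
    return patterns


def expected_total_cost(
    m: GMOMatrix,
    assays,
    cm: CostModel | None = None,
    bound: float | None = None,
    pattern_cap: int = DEFAULT_PATTERN_CAP,
) -> float | Pruned:
    """Exact total expected cost of screening with the given combination.

    Terms are accumulated in descending pattern probability; since every
    term is non-negative, the partial sum is a lower bound on the total,
    so once it exceeds ``bound`` the true cost cannot beat the incumbent
    and PRUNED is returned.
    """
    cm = cm or CostModel()
    pool = _resolve(m, assays)
    k = len(pool)
    if k > pattern_cap:
        raise CapacityError(
            f"combination of {k} assays exceeds the pattern enumeration "
            f"cap of {pattern_cap}"
        )
    total = run_cost(k, cm)
    if bound is not None and total > bound:
        return PRUNED
    if k == 0:
        value = total + run_cost(m.distinct_es_assays(), cm)
        if bound is not None and value > bound:
            return PRUNED
        return value

    prob, counts = _pattern_tables(m, pool)
    g_counts = np.where(
        counts > 0, cm.slope * counts + cm.intercept, cm.zero_assay_run_cost
    )
    if bound is None:
        return float(total + np.dot(prob, g_counts))
    order = np.argsort(prob)[::-1]
    for idx in order:
        total += prob[idx] * g_counts[idx]
        if total > bound:
            return PRUNED
    return float(total)


def brute_force_expected_cost(
    m: GMOMatrix,
    assays,
    cm: CostModel | None = None,
    max_events: int = 20,
) -> float:
    """Oracle: enumerate all 2^E presence worlds and average the cost.

    A world is a subset W of events assumed present; its weight is the
    product of priors/complements.  Each world induces a screening
    pattern (assay positive iff it detects a present event), whose
    candidate count prices the event-specific run.  Must agree with
    :func:`expected_total_cost` to 1e-9.
    """
    cm = cm or CostModel()
    pool = _resolve(m, assays)
    events = m.events
    if len(events) > max_events:
        raise CapacityError(
            f"{len(events)} events exceeds the {max_events}-event world "
            "enumeration cap"
        )
    total = run_cost(len(pool), cm)
    for world in itertools.product([False, True], repeat=len(events)):
        weight = 1.0
        for present, ev in zip(world, events):
            weight *= ev.prior if present else 1.0 - ev.prior
        if weight == 0.0:
            continue
        outcomes = {}
        for a in pool:
            positive = any(
                present and ev.presence(a.target_element) is Presence.PRESENT
                for present, ev in zip(world, events)
            )
            outcomes[a.name] = Outcome.POSITIVE if positive else Outcome.NEGATIVE
        n = candidate_count(m, pool, outcomes)
        total += weight * run_cost(n, cm)
    return total


def expected_es_lower_bound(m: GMOMatrix, cm: CostModel | None = None) -> float:
    """Lower bound on the expected event-specific cost of ANY strategy.

    In every presence world each present event keeps all its detecting
    assays positive, so it can never be screened away: the event-specific
    run always covers at least the event-specific assays of the present
    events.  With independent priors the group-presence indicators give
    the closed form

        E[es cost] >= slope * sum_g (1 - q_g) + intercept * (1 - prod_g q_g)

    where q_g is the probability that no event of event-specific group g
    is present.  Used to tighten the search's screening-size cutoff; it
    never affects which strategy is optimal.
    """
    cm = cm or CostModel()
    group_q: dict[str, float] = {}
    for ev in m.events:
        group_q[ev.es_assay_id] = group_q.get(ev.es_assay_id, 1.0) * (
            1.0 - ev.prior
        )
    expected_groups = sum(1.0 - q for q in group_q.values())
    p_any = 1.0 - math.prod(group_q.values())
    return cm.slope * expected_groups + cm.intercept * p_any


def coverage(m: GMOMatrix, assays) -> tuple[float, int, int]:
    """(% events detected by >= 1 assay in the set, covered, total)."""
    pool = _resolve(m, assays)
    covered = sum(
        1
        for ev in m.events
        if any(ev.presence(a.target_element) is Presence.PRESENT for a in pool)
    )
    total = len(m.events)
    return 100.0 * covered / total, covered, total


def evaluate_strategy(
    m: GMOMatrix,
    assays,
    cm: CostModel | None = None,
) -> TestingStrategy:
    """Full metric set for one screening combination.

    The baseline (reference for savings) is the all-event-specific
    strategy: no screening run, one confirmation assay per distinct
    event-specific id.
    """
    cm = cm or CostModel()
    pool = _resolve(m, assays)
    total = expected_total_cost(m, pool, cm)
    assert not isinstance(total, Pruned)
    screening = run_cost(len(pool), cm)
    baseline = run_cost(m.distinct_es_assays(), cm) + cm.zero_assay_run_cost
    pct, covered, n_events = coverage(m, pool)
    return TestingStrategy(
        assay_names=frozenset(a.name for a in pool),
        screening_cost=screening,
        expected_es_cost=total - screening,
        total_expected_cost=total,
        coverage_pct=pct,
        covered_events=covered,
        total_events=n_events,
        baseline_cost=baseline,
        savings=baseline - total,
    )
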
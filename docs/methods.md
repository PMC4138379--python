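# Methods

## The testing problem

A GMO testing laboratory receiving a food, feed or seed sample must decide,
for every GM event on its watch list, whether the event is present. Two
kinds of real-time PCR assay exist: *screening* assays that detect a genetic
element (P35S, T-nos, epsps, ...) shared by many events, and *event-specific*
assays that confirm exactly one event via its unique insertion signature.
The "matrix approach" runs a combination of screening assays first, compares
the outcomes against a tabulated event × element presence matrix, discards
every event contradicted by a negative screening result, and confirms only
the surviving candidates event-specifically.

gmopanel chooses the screening combination that minimizes the *total
expected cost* of this two-phase procedure, interprets the wet-lab results,
and prices candidate new screening assays under market scenarios.

## Probability and cost model

* **Run cost.** One PCR run of `n` assays costs `g(n) = slope·n + intercept`
  with defaults `slope = 21.18` and `intercept = 91.82` (arbitrary cost
  units; a linear fit to real laboratory labor + reagent costs). A run of
  zero assays is not performed and costs 0 (`CostModel.zero_assay_run_cost`,
  overridable). Exactly two runs are budgeted per sample: one screening run
  and one event-specific run.
* **Priors.** Each event `e` is present independently with probability
  `p_e`, its prior estimated from testing history (see frequency rules
  below). Independence is an approximation: co-occurrence of events (mixed
  lots, stacked varieties) is not modelled.
* **Assays.** Perfect sensitivity and specificity: a screening assay is
  positive iff some present event carries its target element. Analytical
  performance (LOD, cross-reactivity, per-assay prices) is out of scope.
* **Detection semantics.** Matrix cells are PRESENT / ABSENT / UNKNOWN.
  UNKNOWN counts as ABSENT in all probability and cost computations (an
  assay is never credited with a detection it may not make) but blocks
  exclusion in decision support and counts as a possible explanation for a
  positive signal (conservative on both axes).

For a screening set `S`, with `N(o)` the number of distinct event-specific
assays still needed under joint outcome `o` (an event stays a candidate iff
it is uncovered by `S` or all assays detecting it are positive):

```
E[cost](S) = g(|S|) + Σ_o P(o) · g(N(o))        (o over all 2^|S| patterns)
```

Event-specific run sizes count **distinct event-specific assay ids**, not
events, so events sharing a confirmation assay are priced once. The
all-event-specific baseline is therefore exactly `g(#distinct ids)`.

### Exact pattern computation

`expected_total_cost` computes the 2^k pattern distribution exactly.
Indexing patterns by the bitmask `N` of negative assays:

1. `f(B) = P(all assays in B negative) = Π_{e detected by B} (1 − p_e)`,
   evaluated for all `B` in one vectorized pass;
2. `P(neg set exactly N) = Σ_{B ⊇ N} (−1)^{|B\N|} f(B)`, computed with the
   standard in-place superset Möbius transform (k passes over the lattice);
3. `N(o)` per pattern from the per-event detection bitmasks, collapsing
   events by event-specific id.

Float noise can make transform outputs negative at the 1e-16 level; they
are clipped to 0. Pattern probabilities sum to 1 within 1e-9 (tested).
Combinations above 25 assays (configurable) are refused with a capacity
error. For very large lattices (`2^k · #events > 2·10^7` cells) a
memory-light per-signature path replaces the batched one.

An **independent oracle**, `brute_force_expected_cost`, enumerates all 2^E
presence worlds in pure Python and must agree within 1e-9; the test suite
checks this on hundreds of seeded random matrices (≤ 12 events).

### Early termination

When an incumbent bound is supplied, pattern terms are accumulated in
descending probability; every term is non-negative, so the partial sum is a
lower bound and the computation returns a PRUNED signal the moment it
exceeds the bound. Ordering affects only speed, never the result.

## Search

`find_best_strategy` runs depth-first over the subset tree of the
coverage-greedy assay ranking (largest marginal coverage first; ties by
summed prior of newly covered events, then name). The empty combination is
evaluated first so a bound exists immediately. Pruning:

* **Size cutoff.** No strategy of size `k` can cost less than
  `g(k) + es_floor`, where `es_floor` is a strategy-independent lower bound
  on the expected event-specific cost: a present event keeps all its
  detecting assays positive and can never be screened away, giving the
  closed form `es_floor = slope·Σ_g (1−q_g) + intercept·(1−Π_g q_g)` over
  event-specific groups `g` with group-absence probability `q_g`. Branches
  with `g(k) + es_floor` above the incumbent are abandoned; since `g` is
  increasing this caps the tree depth.
* **Bounded evaluation.** Each candidate's expected cost is computed with
  the incumbent as bound (early termination above).
* Assays detecting no event strictly increase cost and are dropped from
  the extension order.

Both rules are conservative, so natural completion proves global
optimality; the suite verifies equality with `exhaustive_search` (every
combination evaluated) on 240 seeded pools of ≤ 10 assays. Cost ties within
1e-9 are broken toward fewer assays, then higher coverage, then the
lexicographically smallest name set — the matrix gives no reason to prefer
otherwise, and determinism matters for testing.

Every improvement is appended to an anytime trace (elapsed ms, cost,
baseline, savings, assays, coverage) and optionally streamed to a sink; a
cooperative interrupt or wall-clock budget stops the search between
evaluations and returns the best-so-far flagged `completed=False`.

## Decision support

After screening, events partition into EXCLUDED (some tested detecting
assay negative), CANDIDATE (detected, not excluded) and UNCOVERED (no
tested assay detects them); the required event-specific list is exactly the
non-excluded events. Untested assays are neutral. After identification,
`check_consistency` reports: confirmed events contradicted by a negative
detecting assay; positive screening assays explained by no confirmed event
(UNKNOWN cells count as explanations — no false alarms from incomplete
curation); and a stacked-event warning whenever ≥ 2 events of one species
are confirmed, since a single stacked variety would produce exactly that
signature. The verdict is CONSISTENT iff there are no contradictions and no
unexplained positives. Event-specific results entered for excluded events
are accepted with a note, as laboratories sometimes test anyway.

## Frequency rules and scenarios

Template priors from testing history: never-observed unauthorized GMOs
0.001; unauthorized GMOs already reported in the EU 1%; authorized /
pipeline / tolerated events a 1% floor; anything observed above 1% keeps
its observed frequency (the dominant Roundup Ready soybean, RRS, carries
0.46 in the template data).

Scenario presets rewrite priors only (presence cells, species and event
lists are never touched):

* `equal_frequencies(f)` — every event at `f`; the robustness sweep uses
  0.01 / 0.02 / 0.05 / 0.10 by default.
* `near_future_1(f)` — authorized/pipeline events rise to `f`; EU-reported
  unauthorized and tolerated events drop to 0.001; RRS keeps its prior.
  (Never-observed unauthorized events already sit at 0.001 and are left
  unmatched.)
* `near_future_2(f)` — events first applied for authorization in 2003 or
  earlier stagnate; later events rise to `f`; RRS falls to 0.25.
* `near_future_3(f)` — old events fall to 0.005, RRS to 0.05, later events
  rise to `f`. High-penetration variants (single events at 80%) are
  expressed with explicit-name override rules rather than a dedicated
  preset.

Year-based selectors require the year metadata column and fail with a clear
error naming the event otherwise. RRS is matched by configurable event
name. `profitability` reports, per scenario, the optimal cost with the
existing assay pool, with the pool extended by the candidates, and the
difference — non-negative by construction, and the natural price signal for
developing a new screening assay.

## Synthetic panels

The generator emulates the silhouette of real panels (20–250 events,
24–220 elements, priors 0.001–0.46, several species): i.i.d. sparse
presence cells at a configurable density, optional *planted* columns shared
by an exact number of events (the P35S-like promoters that make screening
worthwhile), round-robin species, unique event-specific ids, priors drawn
uniformly or from a discrete panel-like distribution such as
{0.001, 0.01, 0.46}. It does **not** emulate the phylogenetic correlation
of real construct reuse, frequency clustering by species, or curation
errors; green tests therefore demonstrate correctness of the optimization
and interpretation logic, not field performance on any specific registry.

## Problem sizes and numerics

Property tests run the world-enumeration oracle on matrices of ≤ 12 events
and the exhaustive search oracle on pools of ≤ 10 assays (200+ seeded
trials each); the whole suite completes in well under a minute. All cost
comparisons use absolute tolerance 1e-9. Historical-panel reproductions
(the published EU 2005/2008 optima) activate automatically when the
original `.tab` datasets are placed under `data/supplementary/`; they are
not redistributed here.

## Known limitations

* Independent Bernoulli priors ignore event co-occurrence and stacking at
  the *cost* stage (stacking is handled at interpretation time only).
* Exactly two runs per sample; iterative re-screening and multiplex
  chemistry pricing are not modelled.
* One screening assay per element column; grouped targets must be encoded
  as derived OR columns.
* Pattern enumeration is exponential in the combination size (capped at
  25); the search depth cutoff keeps practical instances small, but a
  pathological matrix with hundreds of near-free assays would be slow.
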
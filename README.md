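# gmopanel

Cost-optimal two-phase GMO testing strategies over event × element
matrices, with wet-lab result interpretation and market-scenario
simulation.

GMO testing laboratories use the *matrix approach*: a sample is first
tested with screening PCR assays targeting genetic elements (P35S, T-nos,
...) shared by many GM events, the outcomes are compared against a
tabulated event × element presence matrix to exclude events, and only the
surviving candidates are confirmed with event-specific assays. Choosing
*which* screening assays to run is a cost/coverage trade-off that depends
on how likely each event is to appear in the sample.

gmopanel models one PCR run of `n` assays as costing
`g(n) = 21.18·n + 91.82` (configurable) and event presences as independent
Bernoulli variables with priors estimated from testing history. The total
expected cost of screening with assay set `S` is

```
E[cost](S) = g(|S|) + Σ_o P(o) · g(N(o))
```

summed over all 2^|S| screening outcome patterns `o`, where `N(o)` is the
number of distinct event-specific assays still required. A branch-and-bound
search over the assay pool finds the combination minimizing this quantity —
streaming every improvement as it is found and proving optimality on
completion — and is validated against brute-force world enumeration and
exhaustive search oracles. See `docs/methods.md` for the model and its
assumptions.

## Worked example

```python
from gmopanel import (GeneratorConfig, SearchConfig, generate_matrix,
                      find_best_strategy)

# a 20-event x 24-element panel: most events share P35S / T-nos promoters,
# priors drawn from the panel-like distribution {0.001, 0.01, 0.46}
m = generate_matrix(GeneratorConfig(
    n_events=20, n_elements=24, presence_density=0.08,
    planted_elements=(("P35S", 14), ("T-nos", 9)),
    prior_choices=((0.001, 0.01, 0.46), (6.0, 13.0, 1.0)),
    n_species=4, seed=7))

best, trace = find_best_strategy(m, cfg=SearchConfig(report_sink=print))
```

prints the anytime trace — one line per improving strategy:
`elapsed ms, expected cost, (baseline, savings), assays, (coverage)` —

```
0	515.42	(515.42, 0.00)	-	(0%, 0/20)
1	361.32	(515.42, 154.10)	P35S	(70%, 14/20)
1	337.78	(515.42, 177.64)	GE003,P35S	(80%, 16/20)
1	329.21	(515.42, 186.21)	GE003,GE007,GE017,GE018,GE021,P35S	(100%, 20/20)
8	326.09	(515.42, 189.33)	GE003,GE017,GE018,GE021,P35S,T-nos	(100%, 20/20)
```

Confirming all 20 events event-specifically would cost 515.42 units;
screening with P35S alone already cuts the expectation to 361.32 at 70%
coverage, and the proven optimum is a 6-assay combination costing 326.09
(savings 189.33) while covering every event. `best.total_expected_cost`,
`best.savings` and `best.coverage_pct` carry the same numbers.

The same workflow is available from the shell:

```sh
gmopanel generate --out panel.tab --n-events 20 --n-elements 24 --seed 7
gmopanel search --matrix panel.tab --species species1,species2
gmopanel count --n 24 --max-size 5        # exhaustive search-space size: 55454
gmopanel interpret --matrix panel.tab --screening screen.tsv --events ids.tsv
gmopanel scenario --matrix panel.tab --preset near-future-2 --levels 0.02,0.05
```

`interpret` classifies each event (EXCLUDED / CANDIDATE / UNCOVERED), lists
the event-specific assays still required, and cross-checks both phases —
flagging contradictions, unexplained positive screening signals and
potential stacked events (≥ 2 confirmed events of one species).
`scenario` and `profit` re-optimize under what-if market frequencies and
price candidate new screening assays by the drop in optimal expected cost.

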
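"""Market-frequency scenarios and new-assay profitability estimates.

Prior presence frequencies are what drive the optimizer, so strategy
robustness is probed by rewriting them under what-if scenarios while
leaving the presence matrix untouched:

* ``equal_frequencies(f)`` — every event at the same level (swept over
  0.1%, 1%, 2%, 5%, 10% in the original study);
* ``near_future_1/2/3(f)`` — progressively stronger market-shift stories
  built on regulatory status, first-application year and the historically
  dominant Roundup Ready soybean event (RRS, GTS 40-3-2, prior 0.46 in
  the template data).

``assign_baseline_frequencies`` encodes the rules that produced the
template priors from testing history: never-observed unauthorized GMOs
get 0.001, EU-reported ones 1%, authorized/tolerated events a 1% floor,
and anything observed above 1% its observed frequency.

``profitability`` prices a candidate new screening assay: the drop in the
optimal total expected cost when the assay joins the pool, per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import yaml

from .cost import CostModel
from .matrix import GMEvent, GMOMatrix, MatrixError, ScreeningAssay, Status
from .search import SearchConfig, find_best_strategy

__all__ = [
    "KEEP",
    "Selector",
    "ScenarioSpec",
    "MissingMetadataError",
    "assign_baseline_frequencies",
    "apply_scenario",
    "equal_frequencies",
    "near_future_1",
    "near_future_2",
    "near_future_3",
    "load_scenario",
    "profitability",
    "DEFAULT_SWEEP_LEVELS",
    "DEFAULT_RRS_NAME",
]

#: Frequency levels swept in the robustness study (2%, 5%, 10% plus 1%).
DEFAULT_SWEEP_LEVELS = (0.01, 0.02, 0.05, 0.10)

DEFAULT_RRS_NAME = "GTS 40-3-2"


class MissingMetadataError(MatrixError):
    """A scenario selector needs metadata the matrix does not carry."""


class _Keep:
    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "KEEP"


#: Rule value meaning "leave the event's prior unchanged" (explicit no-op,
#: used by the 'frequency stays the same' clauses of the presets).
KEEP = _Keep()


@dataclass(frozen=True)
class Selector:
    """Predicate over events; unset fields match everything.

    ``max_year``/``min_year`` are inclusive bounds on the first
    application year; selecting on year against an event without year
    metadata raises :class:`MissingMetadataError`.
    """

    statuses: frozenset[Status] | None = None
    species: frozenset[str] | None = None
    names: frozenset[str] | None = None
    max_year: int | None = None
    min_year: int | None = None

    def matches(self, ev: GMEvent) -> bool:
        if self.names is not None and ev.name not in self.names:
            return False
        if self.species is not None and ev.species not in self.species:
            return False
        if self.statuses is not None and ev.status not in self.statuses:
            return False
        if self.max_year is not None or self.min_year is not None:
            if ev.first_application_year is None:
                raise MissingMetadataError(
                    f"event {ev.name!r} has no first-application year but a "
                    "scenario rule selects on year"
                )
            if self.max_year is not None and ev.first_application_year > self.max_year:
                return False
            if self.min_year is not None and ev.first_application_year < self.min_year:
                return False
        return True


@dataclass
class ScenarioSpec:
    """Named, ordered rewrite rules; later rules override earlier ones."""

    name: str
    rules: list[tuple[Selector, float | _Keep]] = field(default_factory=list)
    level: float | None = None

    def __post_init__(self) -> None:
        for sel, prior in self.rules:
            if prior is not KEEP and not (0.0 <= prior <= 1.0):
                raise ValueError(
                    f"scenario {self.name!r}: rule prior {prior} outside [0, 1]"
                )


def assign_baseline_frequencies(
    raw: dict[str, tuple[Status, float | None]]
) -> dict[str, float]:
    """Template priors from (status, observed frequency) testing history.

    Never-observed unauthorized GMOs get 0.001; EU-reported ones 1%;
    authorized / pipeline / tolerated events a 1% floor; observed
    frequencies above 1% are kept as-is.
    """
    out: dict[str, float] = {}
    for name, (status, observed) in raw.items():
        if status is Status.UNKNOWN:
            raise MatrixError(
                f"event {name!r}: regulatory status required to assign a "
                "baseline frequency"
            )
        if status is Status.UGM_NEVER_REPORTED:
            out[name] = 0.001
        elif status is Status.UGM_EU_REPORTED:
            out[name] = 0.01
        else:  # authorized, pipeline, tolerated: 1% floor
            if observed is not None and observed > 0.01:
                out[name] = observed
            else:
                out[name] = 0.01
    return out


def apply_scenario(m: GMOMatrix, spec: ScenarioSpec) -> GMOMatrix:
    """Rewrite priors per the scenario; presence cells never change."""
    new_events = []
    for ev in m.events:
        prior = ev.prior
        for sel, value in spec.rules:
            if sel.matches(ev):
                prior = ev.prior if value is KEEP else value
        new_events.append(replace(ev, prior=prior))
    return GMOMatrix(
        events=new_events, elements=list(m.elements), assays=list(m.assays)
    )


def equal_frequencies(level: float, name: str | None = None) -> ScenarioSpec:
    """Every event at the same presence frequency."""
    return ScenarioSpec(
        name=name or f"equal-{level:g}",
        rules=[(Selector(), level)],
        level=level,
    )


_AUTH = frozenset({Status.EU_AUTHORIZED, Status.PIPELINE})


def near_future_1(
    level: float, rrs_name: str = DEFAULT_RRS_NAME, name: str | None = None
) -> ScenarioSpec:
    """Authorized/pipeline events rise to ``level``; UGMs seen in the EU
    and tolerated events drop to 0.1%; the dominant RRS event keeps its
    template frequency."""
    return ScenarioSpec(
        name=name or f"near-future-1-{level:g}",
        rules=[
            (Selector(statuses=_AUTH), level),
            (Selector(statuses=frozenset({Status.UGM_EU_REPORTED})), 0.001),
            (Selector(statuses=frozenset({Status.TOLERATED})), 0.001),
            (Selector(names=frozenset({rrs_name})), KEEP),
        ],
        level=level,
    )


def near_future_2(
    level: float, rrs_name: str = DEFAULT_RRS_NAME, name: str | None = None
) -> ScenarioSpec:
    """Old events (first application <= 2003) stagnate, newer ones rise to
    ``level``; RRS falls to 25%."""
    return ScenarioSpec(
        name=name or f"near-future-2-{level:g}",
        rules=[
            (Selector(statuses=_AUTH, max_year=2003), KEEP),
            (Selector(statuses=_AUTH, min_year=2004), level),
            (Selector(names=frozenset({rrs_name})), 0.25),
        ],
        level=level,
    )


def near_future_3(
    level: float, rrs_name: str = DEFAULT_RRS_NAME, name: str | None = None
) -> ScenarioSpec:
    """Like near-future 2 but old events fall to 0.5% and RRS to 5%."""
    return ScenarioSpec(
        name=name or f"near-future-3-{level:g}",
        rules=[
            (Selector(statuses=_AUTH, max_year=2003), 0.005),
            (Selector(statuses=_AUTH, min_year=2004), level),
            (Selector(names=frozenset({rrs_name})), 0.05),
        ],
        level=level,
    )


_PRESETS = {
    "equal": equal_frequencies,
    "near-future-1": near_future_1,
    "near-future-2": near_future_2,
    "near-future-3": near_future_3,
}


def preset_scenario(
    preset: str, level: float, rrs_name: str = DEFAULT_RRS_NAME
) -> ScenarioSpec:
    try:
        factory = _PRESETS[preset]
    except KeyError as exc:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(_PRESETS)}"
        ) from exc
    if preset == "equal":
        return factory(level)
    return factory(level, rrs_name=rrs_name)


def load_scenario(source: str | dict) -> ScenarioSpec:
    """Build a ScenarioSpec from a small YAML/dict config.

    Shape::

        name: my-scenario          # optional for presets
        preset: near-future-2      # or 'equal', 'near-future-1/3'
        level: 0.05
        rrs: "GTS 40-3-2"          # optional override
        overrides:                 # optional explicit-name rules, applied last
          SomeEvent: 0.8
    """
    data = yaml.safe_load(source) if isinstance(source, str) else dict(source)
    if not isinstance(data, dict):
        raise ValueError("scenario config must be a mapping")
    if "preset" in data:
        spec = preset_scenario(
            data["preset"],
            float(data.get("level", 0.01)),
            rrs_name=data.get("rrs", DEFAULT_RRS_NAME),
        )
        if "name" in data:
            spec.name = data["name"]
    else:
        spec = ScenarioSpec(name=data.get("name", "custom"), rules=[])
    for ev_name, prior in (data.get("overrides") or {}).items():
        spec.rules.append((Selector(names=frozenset({ev_name})), float(prior)))
    return spec


def profitability(
    m_existing: GMOMatrix,
    candidate_assays: Sequence[ScreeningAssay],
    specs: Iterable[ScenarioSpec],
    cm: CostModel | None = None,
    cfg: SearchConfig | None = None,
) -> list[dict]:
    """Per-scenario value of adding candidate screening assays to the pool.

    For each scenario: the optimal total expected cost with the existing
    pool, with the extended pool, and their difference (>= 0; a superset
    pool can only match or improve the optimum).  New elements must have
    been added to the matrix columns beforehand.
    """
    cm = cm or CostModel()
    element_names = m_existing.element_names()
    existing_names = {a.name for a in m_existing.assays}
    extra = []
    for a in candidate_assays:
        if a.target_element not in element_names:
            raise MatrixError(
                f"candidate assay {a.name!r} targets element "
                f"{a.target_element!r} absent from the matrix columns"
            )
        if a.name not in existing_names:
            extra.append(a)
    m_extended = m_existing.with_assays(list(m_existing.assays) + extra)

    rows = []
    for spec in specs:
        m_s = apply_scenario(m_existing, spec)
        m_s_ext = apply_scenario(m_extended, spec)
        best_existing, _ = find_best_strategy(m_s, cm, cfg)
        best_extended, _ = find_best_strategy(m_s_ext, cm, cfg)
        rows.append(
            {
                "scenario": spec.name,
                "cost_existing": best_existing.total_expected_cost,
                "cost_extended": best_extended.total_expected_cost,
                "delta": best_existing.total_expected_cost
                - best_extended.total_expected_cost,
                "coverage_existing": best_existing.coverage_pct,
                "coverage_extended": best_extended.coverage_pct,
            }
        )
    return rows
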
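"""Decision support: turn wet-lab results into conclusions.

After the screening run, each event is classified from the entered
positive/negative outcomes: a tested negative assay that (per the matrix)
detects an event excludes it; events detected only by positive assays are
candidates; events no tested assay detects remain uncovered and must be
confirmed event-specifically regardless.  UNKNOWN matrix cells never
exclude (a negative assay cannot rule out an event it may not detect) but
do count as possible explanations for positive signals.

After the identification run, ``check_consistency`` compares both phases:
confirmed events must not contradict negative screening assays, every
positive screening signal must be explained by some confirmed event, and
two or more confirmed events of one species raise a stacked-event warning
(the sample may contain a gene-stacked variety rather than a mixture).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

from .matrix import GMOMatrix, Outcome, Presence

__all__ = [
    "ScreenClass",
    "IdentClass",
    "ScreeningResultSet",
    "IdentificationResultSet",
    "ConsistencyReport",
    "classify_events",
    "required_event_specific",
    "check_consistency",
]


class ScreenClass(enum.Enum):
    """Event status after the screening phase."""

    EXCLUDED = "EXCLUDED"
    CANDIDATE = "CANDIDATE"
    UNCOVERED = "UNCOVERED"


class IdentClass(enum.Enum):
    """Event status after the identification phase."""

    CONFIRMED = "CONFIRMED"
    NOT_DETECTED = "NOT_DETECTED"
    UNTESTED = "UNTESTED"


@dataclass
class ScreeningResultSet:
    """Outcomes of the tested screening assays; untested assays absent."""

    tested: dict[str, Outcome] = field(default_factory=dict)

    def validate(self, m: GMOMatrix) -> None:
        known = {a.name for a in m.assays}
        unknown = set(self.tested) - known
        if unknown:
            raise ValueError(
                f"screening results name unknown assays: {sorted(unknown)}"
            )


@dataclass
class IdentificationResultSet:
    """Outcomes of the performed event-specific assays, keyed by event."""

    tested: dict[str, Outcome] = field(default_factory=dict)

    def validate(self, m: GMOMatrix) -> None:
        known = {ev.name for ev in m.events}
        unknown = set(self.tested) - known
        if unknown:
            raise ValueError(
                f"identification results name unknown events: {sorted(unknown)}"
            )


@dataclass
class ConsistencyReport:
    confirmed: list[str]
    contradictions: list[tuple[str, str]]  # (event, negative screening assay)
    unexplained_positives: list[str]
    stacked_warnings: list[tuple[str, tuple[str, ...]]]  # (species, events)
    warnings: list[str]
    verdict: str  # CONSISTENT | INCONSISTENT

    def to_dict(self) -> dict:
        return {
            "confirmed": self.confirmed,
            "contradictions": [list(c) for c in self.contradictions],
            "unexplained_positives": self.unexplained_positives,
            "stacked_warnings": [
                {"species": sp, "events": list(evs)}
                for sp, evs in self.stacked_warnings
            ],
            "warnings": self.warnings,
            "verdict": self.verdict,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = [f"Verdict: {self.verdict}"]
        lines.append(
            "Confirmed events: "
            + (", ".join(self.confirmed) if self.confirmed else "none")
        )
        for ev, assay in self.contradictions:
            lines.append(
                f"Contradiction: event {ev} confirmed but detecting assay "
                f"{assay} was negative"
            )
        for assay in self.unexplained_positives:
            lines.append(
                f"Unexplained positive: assay {assay} is positive but no "
                "confirmed event carries its target"
            )
        for sp, evs in self.stacked_warnings:
            lines.append(
                f"Stacked-event warning ({sp}): {', '.join(evs)} — the sample "
                "may contain a stacked variety"
            )
        lines.extend(f"Note: {w}" for w in self.warnings)
        return "\n".join(lines)


def classify_events(
    m: GMOMatrix, sr: ScreeningResultSet
) -> dict[str, ScreenClass]:
    """Classify every event from the screening outcomes.

    EXCLUDED: some tested assay that detects the event (PRESENT cell) was
    negative.  CANDIDATE: not excluded, and at least one tested assay
    detects it.  UNCOVERED: no tested assay detects it.  The three labels
    partition the event set.
    """
    sr.validate(m)
    amap = m.assay_map()
    result: dict[str, ScreenClass] = {}
    for ev in m.events:
        detecting = [
            name
            for name in sr.tested
            if ev.presence(amap[name].target_element) is Presence.PRESENT
        ]
        if any(sr.tested[name] is Outcome.NEGATIVE for name in detecting):
            result[ev.name] = ScreenClass.EXCLUDED
        elif detecting:
            result[ev.name] = ScreenClass.CANDIDATE
        else:
            result[ev.name] = ScreenClass.UNCOVERED
    return result


def required_event_specific(
    m: GMOMatrix, sr: ScreeningResultSet
) -> list[str]:
    """Events needing event-specific confirmation, by species then name.

    Exactly the non-EXCLUDED events: candidates implicated by positive
    screening plus events the tested assays cannot see at all (including
    UNKNOWN-cell relations, which never exclude).
    """
    classes = classify_events(m, sr)
    needed = [
        ev for ev in m.events if classes[ev.name] is not ScreenClass.EXCLUDED
    ]
    needed.sort(key=lambda ev: (ev.species, ev.name))
    return [ev.name for ev in needed]


def check_consistency(
    m: GMOMatrix,
    sr: ScreeningResultSet,
    ir: IdentificationResultSet,
) -> ConsistencyReport:
    """Cross-check screening and identification phases.

    Positive event-specific tests prove presence; the report flags
    (a) confirmed events contradicted by a negative detecting assay,
    (b) positive screening assays with no confirmed event carrying the
    target element (PRESENT or UNKNOWN cells both count as explanations),
    and (c) species with >= 2 confirmed events (possible gene stacking).
    The verdict is CONSISTENT iff (a) and (b) are both empty.
    """
    sr.validate(m)
    ir.validate(m)
    amap = m.assay_map()
    classes = classify_events(m, sr)

    confirmed = [
        ev.name
        for ev in m.events
        if ir.tested.get(ev.name) is Outcome.POSITIVE
    ]
    warnings = [
        f"event-specific result entered for {name}, which screening had "
        "already excluded"
        for name in ir.tested
        if classes[name] is ScreenClass.EXCLUDED
    ]

    contradictions: list[tuple[str, str]] = []
    for name in confirmed:
        ev = m.event(name)
        for aname, outcome in sr.tested.items():
            if (
                outcome is Outcome.NEGATIVE
                and ev.presence(amap[aname].target_element) is Presence.PRESENT
            ):
                contradictions.append((name, aname))

    unexplained: list[str] = []
    for aname, outcome in sr.tested.items():
        if outcome is not Outcome.POSITIVE:
            continue
        target = amap[aname].target_element
        explained = any(
            m.event(name).presence(target)
            in (Presence.PRESENT, Presence.UNKNOWN)
            for name in confirmed
        )
        if not explained:
            unexplained.append(aname)

    by_species: dict[str, list[str]] = {}
    for name in confirmed:
        by_species.setdefault(m.event(name).species, []).append(name)
    stacked = [
        (sp, tuple(sorted(evs)))
        for sp, evs in sorted(by_species.items())
        if len(evs) >= 2
    ]

    verdict = (
        "CONSISTENT" if not contradictions and not unexplained else "INCONSISTENT"
    )
    return ConsistencyReport(
        confirmed=sorted(confirmed),
        contradictions=sorted(contradictions),
        unexplained_positives=sorted(unexplained),
        stacked_warnings=stacked,
        warnings=warnings,
        verdict=verdict,
    )
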
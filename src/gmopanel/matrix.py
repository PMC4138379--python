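"""Event/element presence matrix for the GMO "matrix approach".

The central object is :class:`GMOMatrix`: rows are GM events (a specific
transformation event such as MON810), columns are genetic elements (P35S,
T-nos, ...) that screening PCR assays can target.  Each event carries the
prior probability that it is present in the sample at hand, estimated from
laboratory testing history, plus optional regulatory metadata used by the
scenario presets.

Matrices are serialized as a small tab-separated dialect::

    # comment lines start with '#'
    event<TAB>species<TAB>frequency[<TAB>status][<TAB>year]<TAB>es_assay<TAB><elem1><TAB><elem2>...
    MON810<TAB>maize<TAB>0.01<TAB>EU_AUTHORIZED<TAB>1998<TAB>es-MON810<TAB>1<TAB>0...

Cell vocabulary: ``1`` = element present, ``0`` or empty = absent, ``?`` =
unknown.  Unknown cells are treated as absent in every probability and cost
computation (an assay is never credited with a detection it may not make)
but as "cannot exclude" by the decision-support logic.  Frequencies are
decimals in [0, 1]; a trailing ``%`` is accepted and divided by 100.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Presence",
    "Status",
    "Outcome",
    "GeneticElement",
    "GMEvent",
    "ScreeningAssay",
    "GMOMatrix",
    "MatrixError",
    "MatrixParseError",
    "parse_matrix",
    "write_matrix",
    "filter_species",
]


class MatrixError(ValueError):
    """Invalid matrix content or structure."""


class MatrixParseError(MatrixError):
    """Malformed TSV input; the message names the offending row/column."""


class Presence(enum.Enum):
    PRESENT = "1"
    ABSENT = "0"
    UNKNOWN = "?"


class Status(enum.Enum):
    """Regulatory status of a GM event in the jurisdiction of interest."""

    EU_AUTHORIZED = "EU_AUTHORIZED"
    PIPELINE = "PIPELINE"
    TOLERATED = "TOLERATED"
    UGM_EU_REPORTED = "UGM_EU_REPORTED"
    UGM_NEVER_REPORTED = "UGM_NEVER_REPORTED"
    UNKNOWN = "UNKNOWN"


class Outcome(enum.Enum):
    """Wet-lab result of a single assay."""

    POSITIVE = "pos"
    NEGATIVE = "neg"


@dataclass(frozen=True)
class GeneticElement:
    """A screening target sequence (promoter, terminator, gene...)."""

    name: str

    def __post_init__(self) -> None:
        if not self.name or "\t" in self.name:
            raise MatrixError(f"invalid element name: {self.name!r}")


@dataclass(frozen=True)
class ScreeningAssay:
    """A screening PCR assay targeting one genetic-element column."""

    name: str
    target_element: str


@dataclass
class GMEvent:
    """One matrix row: a GM event with its prior presence probability.

    ``elements`` maps element name -> Presence; names absent from the
    mapping are treated as ABSENT.  ``es_assay_id`` identifies the
    event-specific assay that confirms this event; distinct events may
    share one (e.g. an event pair indistinguishable at the insertion
    locus), which is why event-specific run sizes count distinct ids.
    """

    name: str
    species: str
    prior: float
    elements: dict[str, Presence] = field(default_factory=dict)
    es_assay_id: str = ""
    status: Status = Status.UNKNOWN
    first_application_year: int | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise MatrixError("event name must be non-empty")
        if not (0.0 <= self.prior <= 1.0):
            raise MatrixError(
                f"event {self.name!r}: prior {self.prior} outside [0, 1]"
            )
        if not self.es_assay_id:
            self.es_assay_id = f"es-{self.name}"

    def presence(self, element: str) -> Presence:
        return self.elements.get(element, Presence.ABSENT)


@dataclass
class GMOMatrix:
    """Events x elements presence table plus the screening-assay pool.

    By default there is one screening assay per element column, named
    after the element.  Grouped screening targets (an assay hitting any
    of several elements) are modelled by adding a derived column whose
    cells are the OR of the member columns.
    """

    events: list[GMEvent]
    elements: list[GeneticElement]
    assays: list[ScreeningAssay] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assays:
            self.assays = [
                ScreeningAssay(name=el.name, target_element=el.name)
                for el in self.elements
            ]
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if not self.events:
            raise MatrixError("matrix must contain at least one event")
        if not self.elements:
            raise MatrixError("matrix must contain at least one element")
        _check_unique([e.name for e in self.events], "event")
        _check_unique([el.name for el in self.elements], "element")
        _check_unique([a.name for a in self.assays], "assay")
        element_names = self.element_names()
        for ev in self.events:
            for el in ev.elements:
                if el not in element_names:
                    raise MatrixError(
                        f"event {ev.name!r} references unknown element {el!r}"
                    )
        for a in self.assays:
            if a.target_element not in element_names:
                raise MatrixError(
                    f"assay {a.name!r} targets unknown element "
                    f"{a.target_element!r}"
                )

    # -- lookups ---------------------------------------------------------

    def element_names(self) -> set[str]:
        return {el.name for el in self.elements}

    def species(self) -> list[str]:
        """Distinct species labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.species, None)
        return list(seen)

    def event(self, name: str) -> GMEvent:
        for ev in self.events:
            if ev.name == name:
                return ev
        raise MatrixError(f"no event named {name!r}")

    def assay(self, name: str) -> ScreeningAssay:
        for a in self.assays:
            if a.name == name:
                return a
        raise MatrixError(f"no assay named {name!r}")

    def assay_map(self) -> dict[str, ScreeningAssay]:
        return {a.name: a for a in self.assays}

    def detected_events(self, assay: ScreeningAssay | str) -> list[GMEvent]:
        """Events whose cell for the assay's target element is PRESENT."""
        if isinstance(assay, str):
            assay = self.assay(assay)
        return [
            ev
            for ev in self.events
            if ev.presence(assay.target_element) is Presence.PRESENT
        ]

    def distinct_es_assays(self, events: Iterable[GMEvent] | None = None) -> int:
        evs = self.events if events is None else events
        return len({ev.es_assay_id for ev in evs})

    def with_assays(self, assays: Sequence[ScreeningAssay]) -> "GMOMatrix":
        """Copy of this matrix with a different screening-assay pool."""
        return GMOMatrix(
            events=[replace(ev) for ev in self.events],
            elements=list(self.elements),
            assays=list(assays),
        )


def _check_unique(names: list[str], kind: str) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise MatrixError(f"duplicate {kind} name: {n!r}")
        seen.add(n)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ("event", "species", "frequency", "status", "year", "es_assay")


def parse_matrix(text: str | io.TextIOBase) -> GMOMatrix:
    """Parse the tab-separated matrix dialect into a :class:`GMOMatrix`.

    Raises :class:`MatrixParseError` naming the offending row/column for
    duplicate names, out-of-vocabulary cells, or priors outside [0, 1].
    """
    if hasattr(text, "read"):
        text = text.read()  # type: ignore[union-attr]
    lines = [
        ln
        for ln in str(text).replace("\r\n", "\n").split("\n")
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise MatrixParseError("empty matrix file")

    header = lines[0].split("\t")
    lowered = [h.strip().lower() for h in header]
    if lowered[:3] != ["event", "species", "frequency"]:
        raise MatrixParseError(
            "header must start with 'event<TAB>species<TAB>frequency', got "
            f"{header[:3]!r}"
        )
    has_status = "status" in lowered
    has_year = "year" in lowered
    expect = ["event", "species", "frequency"]
    if has_status:
        expect.append("status")
    if has_year:
        expect.append("year")
    expect.append("es_assay")
    if lowered[: len(expect)] != expect:
        raise MatrixParseError(
            f"header columns must be ordered {expect}, got {lowered[:len(expect)]}"
        )
    element_names = [h.strip() for h in header[len(expect):]]
    if not element_names:
        raise MatrixParseError("matrix has no element columns")
    _parse_check_unique(element_names, "element")

    elements = [GeneticElement(n) for n in element_names]
    events: list[GMEvent] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(expect) + len(element_names):
            raise MatrixParseError(
                f"line {lineno}: expected {len(expect) + len(element_names)} "
                f"fields, got {len(fields)}"
            )
        it = iter(range(len(expect)))
        name = fields[next(it)].strip()
        species = fields[next(it)].strip()
        freq_tok = fields[next(it)].strip()
        status = Status.UNKNOWN
        year: int | None = None
        if has_status:
            tok = fields[next(it)].strip()
            if tok:
                try:
                    status = Status(tok.upper())
                except ValueError as exc:
                    raise MatrixParseError(
                        f"line {lineno} (event {name!r}): unknown status {tok!r}"
                    ) from exc
        if has_year:
            tok = fields[next(it)].strip()
            if tok:
                try:
                    year = int(tok)
                except ValueError as exc:
                    raise MatrixParseError(
                        f"line {lineno} (event {name!r}): bad year {tok!r}"
                    ) from exc
        es_assay = fields[next(it)].strip()

        prior = _parse_frequency(freq_tok, name)
        cells: dict[str, Presence] = {}
        for el_name, tok in zip(element_names, fields[len(expect):]):
            tok = tok.strip()
            if tok in ("", "0"):
                continue
            if tok == "1":
                cells[el_name] = Presence.PRESENT
            elif tok == "?":
                cells[el_name] = Presence.UNKNOWN
            else:
                raise MatrixParseError(
                    f"invalid cell value {tok!r} at event {name!r}, "
                    f"element {el_name!r} (allowed: 1, 0, ?, empty)"
                )
        events.append(
            GMEvent(
                name=name,
                species=species,
                prior=prior,
                elements=cells,
                es_assay_id=es_assay,
                status=status,
                first_application_year=year,
            )
        )
    _parse_check_unique([e.name for e in events], "event")
    try:
        return GMOMatrix(events=events, elements=elements)
    except MatrixError as exc:
        raise MatrixParseError(str(exc)) from exc


def _parse_check_unique(names: list[str], kind: str) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise MatrixParseError(f"duplicate {kind} name: {n!r}")
        seen.add(n)


def _parse_frequency(token: str, event: str) -> float:
    if not token:
        raise MatrixParseError(f"event {event!r}: missing frequency")
    tok = token.rstrip()
    scale = 1.0
    if tok.endswith("%"):
        tok = tok[:-1].strip()
        scale = 0.01
    try:
        value = float(tok) * scale
    except ValueError as exc:
        raise MatrixParseError(
            f"event {event!r}: cannot parse frequency {token!r}"
        ) from exc
    if not (0.0 <= value <= 1.0):
        raise MatrixParseError(
            f"event {event!r}: frequency {value} outside [0, 1]"
        )
    return value


def write_matrix(m: GMOMatrix) -> str:
    """Serialize to the TSV dialect; ``parse_matrix`` round-trips exactly.

    Status and year columns are always emitted so no metadata is lost.
    Priors are written with repr precision (exact float round-trip).
    """
    cols = ["event", "species", "frequency", "status", "year", "es_assay"]
    cols += [el.name for el in m.elements]
    out = ["\t".join(cols)]
    for ev in m.events:
        row = [
            ev.name,
            ev.species,
            repr(ev.prior),
            ev.status.value,
            "" if ev.first_application_year is None else str(ev.first_application_year),
            ev.es_assay_id,
        ]
        for el in m.elements:
            p = ev.presence(el.name)
            row.append({Presence.PRESENT: "1", Presence.ABSENT: "0", Presence.UNKNOWN: "?"}[p])
        out.append("\t".join(row))
    return "\n".join(out) + "\n"


def filter_species(m: GMOMatrix, selected: Iterable[str]) -> GMOMatrix:
    """Restrict the matrix to events of the selected species.

    Used to tailor the search to the sample at hand (e.g. a pure-maize
    sample need not budget for soybean events).  Element and assay lists
    are unchanged; removed events contribute nothing downstream.
    """
    wanted = set(selected)
    if not wanted:
        raise MatrixError("selected species set must be non-empty")
    available = set(m.species())
    unknown = wanted - available
    if unknown:
        raise MatrixError(
            f"unknown species {sorted(unknown)}; available: {sorted(available)}"
        )
    kept = [replace(ev) for ev in m.events if ev.species in wanted]
    return GMOMatrix(events=kept, elements=list(m.elements), assays=list(m.assays))
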
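"""Synthetic event/element matrices shaped like real testing panels.

Real panels in this domain range from ~20 events x 24 elements (an EU
panel circa 2005) up to ~250 events x 220 elements (all events known
globally), with priors spanning 0.001 (never-observed unauthorized GMOs)
to 0.46 (the dominant Roundup Ready soybean event).  The generator
reproduces that silhouette: a sparse random presence structure, optional
"planted" high-sharing elements (the P35S-like promoters most events
carry, which is what makes screening worthwhile), several species, and
optional masking of known-present cells to UNKNOWN to mimic incomplete
matrix curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import GeneticElement, GMEvent, GMOMatrix, Presence

__all__ = ["GeneratorConfig", "generate_matrix", "toy_matrix"]


@dataclass
class GeneratorConfig:
    """Shape and randomness knobs for :func:`generate_matrix`.

    ``planted_elements`` lists (element name, number of carrying events)
    pairs: those columns are PRESENT in exactly that many events, giving
    the generator the heavy-sharing columns real panels have.
    ``prior_choices`` switches to a "panel-like" discrete prior draw
    (e.g. values (0.001, 0.01, 0.46) with weights) instead of the
    uniform draw over ``prior_range``.
    """

    n_events: int = 20
    n_elements: int = 24
    presence_density: float = 0.15
    prior_range: tuple[float, float] = (0.001, 0.46)
    n_species: int = 3
    planted_elements: tuple[tuple[str, int], ...] = ()
    unknown_rate: float = 0.0
    seed: int = 0
    prior_choices: tuple[tuple[float, ...], tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.n_events < 1 or self.n_elements < 1:
            raise ValueError("need at least one event and one element")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        for p in (self.presence_density, self.unknown_rate, *self.prior_range):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for name, count in self.planted_elements:
            if count > self.n_events:
                raise ValueError(
                    f"planted element {name!r} asks for {count} carriers but "
                    f"only {self.n_events} events exist"
                )


def generate_matrix(cfg: GeneratorConfig) -> GMOMatrix:
    """Deterministic (seeded) random matrix with the configured shape."""
    rng = np.random.default_rng(cfg.seed)
    planted_names = [name for name, _ in cfg.planted_elements]
    n_random = cfg.n_elements - len(planted_names)
    if n_random < 0:
        raise ValueError("more planted elements than element columns")
    random_names = [f"GE{i + 1:03d}" for i in range(n_random)]
    element_names = planted_names + random_names

    species = [f"species{i + 1}" for i in range(cfg.n_species)]
    if cfg.prior_choices is not None:
        values, weights = cfg.prior_choices
        w = np.asarray(weights, dtype=float)
        priors = rng.choice(np.asarray(values), size=cfg.n_events, p=w / w.sum())
    else:
        lo, hi = cfg.prior_range
        priors = rng.uniform(lo, hi, size=cfg.n_events)

    # Random sparse structure; planted columns overwritten below.
    cells = rng.random((cfg.n_events, cfg.n_elements)) < cfg.presence_density
    unknown = np.zeros_like(cells)
    if cfg.unknown_rate > 0:
        unknown = cells & (rng.random(cells.shape) < cfg.unknown_rate)
    for j, (name, count) in enumerate(cfg.planted_elements):
        col = np.zeros(cfg.n_events, dtype=bool)
        col[rng.choice(cfg.n_events, size=count, replace=False)] = True
        cells[:, j] = col
        unknown[:, j] = False  # planted structure is exact, never masked

    events = []
    for i in range(cfg.n_events):
        row: dict[str, Presence] = {}
        for j, el in enumerate(element_names):
            if cells[i, j]:
                row[el] = Presence.UNKNOWN if unknown[i, j] else Presence.PRESENT
        events.append(
            GMEvent(
                name=f"EV{i + 1:03d}",
                species=species[i % cfg.n_species],
                prior=float(priors[i]),
                elements=row,
                es_assay_id=f"es-EV{i + 1:03d}",
            )
        )
    return GMOMatrix(
        events=events, elements=[GeneticElement(n) for n in element_names]
    )


def toy_matrix() -> GMOMatrix:
    """The canonical 3-event worked example used throughout the tests.

    Events E1, E2 (maize, prior 0.5 each) and E3 (soybean, prior 0.1);
    assay P35S detects {E1, E2}, assay T-nos detects {E2}; E3 carries no
    screenable element, so it is always confirmed event-specifically.
    """
    return GMOMatrix(
        events=[
            GMEvent(
                name="E1",
                species="maize",
                prior=0.5,
                elements={"P35S": Presence.PRESENT},
                es_assay_id="es-E1",
            ),
            GMEvent(
                name="E2",
                species="maize",
                prior=0.5,
                elements={"P35S": Presence.PRESENT, "T-nos": Presence.PRESENT},
                es_assay_id="es-E2",
            ),
            GMEvent(
                name="E3",
                species="soybean",
                prior=0.1,
                elements={},
                es_assay_id="es-E3",
            ),
        ],
        elements=[GeneticElement("P35S"), GeneticElement("T-nos")],
    )
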
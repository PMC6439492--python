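"""Demographic scenarios for the three-group kelp system and their priors.

The sampled units are three genetic groups: H (Japan: Hokkaido/Honshu
lineage), P (Primorye: west coast of the Japan Sea) and A (Sakhalin,
putatively admixed).  A scenario is a backward-in-time event schedule over
these demes: lineages sampled at time 0 coalesce within demes of constant
diploid effective size until, at event times t1 < t2 (generations), demes
merge or an admixed deme splits its lineages between two sources; after
the final event a single ancestral deme of size ``N_anc`` remains.

Seven presets mirror the competing hypotheses for the system:

1-4  hierarchical splits (all orders of pairwise merging),
5    isolation-with-admixture: A founded at t1 by admixture of H and P,
6    as 5, with H/P divergence constrained to pre-date the Last Glacial
     Maximum (t2 > t_LGM) and a small pre-expansion ancestral size,
7    as 5, with post-LGM divergence (t2 <= t_LGM).

The wording "X merged with Y at t" is interpreted backward in time:
lineages of X move into Y, and Y persists with its own effective size
until the next event.  The admixture rate ``r`` is the proportion of A's
lineages tracing to the first-listed source (H).
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Merge",
    "Admixture",
    "SizeChange",
    "PriorSpec",
    "ParameterDraw",
    "DemographicScenario",
    "builtin_scenarios",
    "get_scenario",
    "with_prior",
    "validate_scenario",
    "draw_parameters",
    "generations_to_years",
    "T_LGM_GENERATIONS",
    "DEFAULT_GENERATION_TIME",
]

#: older bound of the LGM (~21 kya) in generations at 2 years/generation
T_LGM_GENERATIONS: float = 10_500.0

#: years per generation implied by the study system's reported conversions
DEFAULT_GENERATION_TIME: float = 2.0

_OPS = {"<": operator.lt, "<=": operator.le, ">": operator.gt, ">=": operator.ge}


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Merge:
    """All lineages of ``source`` move into ``target`` at ``time_param``."""

    time_param: str
    source: str
    target: str


@dataclass(frozen=True)
class Admixture:
    """Each lineage of ``derived`` moves to ``source1`` with probability
    ``rate_param`` (else ``source2``) at ``time_param``."""

    time_param: str
    derived: str
    source1: str
    source2: str
    rate_param: str


@dataclass(frozen=True)
class SizeChange:
    """``population`` takes effective size ``size_param`` at ``time_param``
    (looking further back in time)."""

    time_param: str
    population: str
    size_param: str


Event = Merge | Admixture | SizeChange


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Independent-ish priors with optional cross-parameter constraints.

    ``params`` maps parameter name to ``(dist, low, high)`` where ``dist``
    is "uniform" or "loguniform" and either bound may be the name of an
    earlier parameter (draws follow insertion order, so e.g. t1 may be
    Uniform(100, t2)).  ``conditions`` are ``(lhs, op, rhs)`` triples with
    op in {<, <=, >, >=} and rhs a parameter name or a number; draws
    violating any condition are rejected and redrawn.
    """

    params: dict[str, tuple[str, float | str, float | str]]
    conditions: tuple[tuple[str, str, float | str], ...] = ()

    def __post_init__(self) -> None:
        for name, (dist, low, high) in self.params.items():
            if dist not in ("uniform", "loguniform"):
                raise ValueError(f"{name}: unknown distribution {dist!r}")
            if isinstance(low, str) and low not in self.params:
                raise ValueError(f"{name}: unknown bound reference {low!r}")
            if isinstance(high, str) and high not in self.params:
                raise ValueError(f"{name}: unknown bound reference {high!r}")
            if not isinstance(low, str) and not isinstance(high, str):
                if not (np.isfinite(low) and np.isfinite(high) and low < high):
                    raise ValueError(f"{name}: bounds must be finite with low < high")
        for lhs, op, rhs in self.conditions:
            if op not in _OPS:
                raise ValueError(f"unknown condition operator {op!r}")
            if lhs not in self.params:
                raise ValueError(f"condition references unknown parameter {lhs!r}")
            if isinstance(rhs, str) and rhs not in self.params:
                raise ValueError(f"condition references unknown parameter {rhs!r}")


@dataclass(frozen=True)
class ParameterDraw:
    """Concrete parameter values for one scenario."""

    scenario: str
    values: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def draw_parameters(
    prior: PriorSpec, rng: np.random.Generator, max_rejections: int = 100_000
) -> dict[str, float]:
    """One draw from ``prior``, redrawing until all conditions hold.

    Deterministic given the generator state.  Raises after
    ``max_rejections`` consecutive rejected draws (unsatisfiable system).
    """
    for _ in range(max_rejections):
        values: dict[str, float] = {}
        for name, (dist, low, high) in prior.params.items():
            lo = values[low] if isinstance(low, str) else float(low)
            hi = values[high] if isinstance(high, str) else float(high)
            if not lo < hi:
                break  # dependent bound collapsed; reject whole draw
            if dist == "uniform":
                values[name] = float(rng.uniform(lo, hi))
            else:
                values[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            ok = all(
                _OPS[op](
                    values[lhs],
                    values[rhs] if isinstance(rhs, str) else float(rhs),
                )
                for lhs, op, rhs in prior.conditions
            )
            if ok:
                return values
    raise RuntimeError(
        f"prior rejected {max_rejections} consecutive draws; "
        "conditions appear unsatisfiable"
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemographicScenario:
    """Populations, sizes, timed events and priors for one hypothesis."""

    name: str
    description: str
    sampled_populations: tuple[str, ...]
    size_params: dict[str, str]  # population -> size parameter name
    events: tuple[Event, ...]
    prior: PriorSpec
    generation_time_years: float = DEFAULT_GENERATION_TIME

    def draw(self, rng: np.random.Generator) -> ParameterDraw:
        return ParameterDraw(self.name, draw_parameters(self.prior, rng))

    @property
    def parameter_names(self) -> list[str]:
        return list(self.prior.params)


def _default_prior(
    admixture: bool, t2_condition: tuple[str, str, float] | None = None
) -> PriorSpec:
    params: dict[str, tuple[str, float | str, float | str]] = {
        "N_H": ("uniform", 100.0, 100_000.0),
        "N_P": ("uniform", 100.0, 100_000.0),
        "N_A": ("uniform", 100.0, 100_000.0),
        "N_anc": ("uniform", 100.0, 100_000.0),
        "t2": ("uniform", 1_000.0, 30_000.0),
        "t1": ("uniform", 100.0, "t2"),
    }
    if admixture:
        params["r"] = ("uniform", 0.001, 0.999)
    conditions: list[tuple[str, str, float | str]] = [("t1", "<", "t2")]
    if t2_condition is not None:
        conditions.append(t2_condition)
    return PriorSpec(params=params, conditions=tuple(conditions))


def _split_scenario(
    name: str, description: str, first: tuple[str, str], second: tuple[str, str]
) -> DemographicScenario:
    events: tuple[Event, ...] = (
        Merge("t1", *first),
        Merge("t2", *second),
        SizeChange("t2", second[1], "N_anc"),
    )
    return DemographicScenario(
        name=name,
        description=description,
        sampled_populations=("H", "P", "A"),
        size_params={"H": "N_H", "P": "N_P", "A": "N_A"},
        events=events,
        prior=_default_prior(admixture=False),
    )


def _admixture_scenario(
    name: str,
    description: str,
    t2_condition: tuple[str, str, float] | None = None,
) -> DemographicScenario:
    events: tuple[Event, ...] = (
        Admixture("t1", "A", "H", "P", "r"),
        Merge("t2", "H", "P"),
        SizeChange("t2", "P", "N_anc"),
    )
    return DemographicScenario(
        name=name,
        description=description,
        sampled_populations=("H", "P", "A"),
        size_params={"H": "N_H", "P": "N_P", "A": "N_A"},
        events=events,
        prior=_default_prior(admixture=True, t2_condition=t2_condition),
    )


def builtin_scenarios() -> list[DemographicScenario]:
    """The seven preset scenarios (see module docstring)."""
    return [
        _split_scenario(
            "scenario1",
            "hierarchical split: H merges with A at t1, then with P at t2",
            ("H", "A"),
            ("A", "P"),
        ),
        _split_scenario(
            "scenario2",
            "hierarchical split: P merges with A at t1, then with H at t2",
            ("P", "A"),
            ("A", "H"),
        ),
        _split_scenario(
            "scenario3",
            "hierarchical split: A merges with P at t1, then with H at t2",
            ("A", "P"),
            ("P", "H"),
        ),
        _split_scenario(
            "scenario4",
            "hierarchical split: H merges with P at t1, then with A at t2",
            ("H", "P"),
            ("P", "A"),
        ),
        _admixture_scenario(
            "scenario5",
            "isolation with admixture: A founded at t1 from H and P, "
            "H/P divergence at t2",
        ),
        _admixture_scenario(
            "scenario6",
            "admixture with pre-LGM H/P divergence (t2 > t_LGM) and "
            "pre-expansion bottleneck ancestral size",
            t2_condition=("t2", ">", T_LGM_GENERATIONS),
        ),
        _admixture_scenario(
            "scenario7",
            "admixture with post-LGM H/P divergence (t2 <= t_LGM)",
            t2_condition=("t2", "<=", T_LGM_GENERATIONS),
        ),
    ]


def get_scenario(name: str) -> DemographicScenario:
    """Look up a preset by name ("scenario1" ... "scenario7")."""
    for s in builtin_scenarios():
        if s.name == name:
            return s
    raise KeyError(f"unknown scenario {name!r}")


def with_prior(scenario: DemographicScenario, prior: PriorSpec) -> DemographicScenario:
    """Copy of ``scenario`` with a replacement prior."""
    return replace(scenario, prior=prior)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _event_time_order(scenario: DemographicScenario) -> list[str]:
    seen: dict[str, None] = {}
    for ev in scenario.events:
        seen.setdefault(ev.time_param, None)
    return list(seen)


def validate_scenario(
    scenario: DemographicScenario, draw: ParameterDraw | None = None
) -> list[str]:
    """Structural checks; returns a list of violations (empty = valid).

    Checks: every sampled population has a size parameter; all event
    parameters exist in the prior; applying the events in order leaves
    exactly one population (single-ancestor reachability); with a concrete
    ``draw``: strict time ordering where the event schedule requires it,
    admixture rate in (0,1), positive sizes.
    """
    violations: list[str] = []
    prior_params = set(scenario.prior.params)
    for pop in scenario.sampled_populations:
        if pop not in scenario.size_params:
            violations.append(f"population {pop!r} has no size parameter")
        elif scenario.size_params[pop] not in prior_params:
            violations.append(
                f"size parameter {scenario.size_params[pop]!r} not in prior"
            )
    for ev in scenario.events:
        if ev.time_param not in prior_params:
            violations.append(f"event time {ev.time_param!r} not in prior")
        if isinstance(ev, Admixture) and ev.rate_param not in prior_params:
            violations.append(f"admixture rate {ev.rate_param!r} not in prior")
        if isinstance(ev, SizeChange) and ev.size_param not in prior_params:
            violations.append(f"size parameter {ev.size_param!r} not in prior")

    # reachability: symbolic execution of the event schedule
    alive = set(scenario.sampled_populations)
    for ev in scenario.events:
        if isinstance(ev, Merge):
            if ev.source not in alive:
                violations.append(f"merge source {ev.source!r} not alive")
            if ev.target not in alive:
                violations.append(f"merge target {ev.target!r} not alive")
            alive.discard(ev.source)
        elif isinstance(ev, Admixture):
            for pop in (ev.derived, ev.source1, ev.source2):
                if pop not in alive:
                    violations.append(f"admixture population {pop!r} not alive")
            alive.discard(ev.derived)
    if len(alive) != 1:
        violations.append(
            f"{len(alive)} populations remain after all events "
            "(exactly one ancestor required)"
        )

    if draw is not None:
        times = [draw.values.get(t) for t in _event_time_order(scenario)]
        if any(t is None for t in times):
            violations.append("draw is missing event times")
        else:
            for earlier, later in zip(times, times[1:]):
                if not earlier < later:
                    violations.append(
                        f"event times not strictly increasing: {earlier} >= {later}"
                    )
        for ev in scenario.events:
            if isinstance(ev, Admixture):
                r = draw.values.get(ev.rate_param, float("nan"))
                if not 0.0 < r < 1.0:
                    violations.append(f"admixture rate {r} outside (0, 1)")
        for pop, sp in scenario.size_params.items():
            size = draw.values.get(sp, float("nan"))
            if not size > 0:
                violations.append(f"size {sp}={size} not positive")
    return violations


# ---------------------------------------------------------------------------
# time conversion
# ---------------------------------------------------------------------------


def generations_to_years(
    t: float, scenario: DemographicScenario | None = None
) -> float:
    """Convert a time in generations to years before present.

    Uses the scenario's ``generation_time_years`` (default 2 years per
    generation, the value implied by the study system's reported
    generation-to-year conversions).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    gt = scenario.generation_time_years if scenario is not None else DEFAULT_GENERATION_TIME
    return t * gt
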
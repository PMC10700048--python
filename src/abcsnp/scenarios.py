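"""Demographic scenarios, priors, and prior sampling.

A :class:`Scenario` is a backward-time event list over five sampled demes
(Pop1..Pop5) plus an ancestral deme. Two event kinds exist:

* ``merge`` — at time ``t`` all lineages of ``source`` move into ``dest``
  (forward in time: ``source`` diverged from ``dest`` at ``t``). The event may
  change the size of ``dest`` above ``t`` (used for the root event, where the
  surviving deme takes the ancestral size ``NA``).
* ``admixture`` — at time ``t`` each lineage of ``admixed`` moves independently
  to ``parent1`` with probability ``ra``, else to ``parent2`` (forward in
  time: ``admixed`` was founded as a mixture of the two parents).

Sizes are diploid individual counts, times are generations; both are sampled
as continuous values from uniform priors with the divergence times subject to
the ordering t1 < t2 < t3 < t4 (enforced by joint rejection, which is exactly
uniform on the order-constrained region).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "PriorSpec",
    "DemographicEvent",
    "Scenario",
    "ParameterDraw",
    "builtin_scenarios",
    "sample_prior",
    "validate",
    "scenarios_to_config",
    "scenarios_from_config",
]

#: canonical sampled demes, in pipeline order
DEMES = ("Pop1", "Pop2", "Pop3", "Pop4", "Pop5")
#: field-standard group names for the five demes, in the same order
GROUP_NAMES = ("SOUTHERN", "LOWER-CENTRAL", "UPPER-CENTRAL", "EASTERN", "NORTHERN")
SIZE_SYMBOLS = ("N1", "N2", "N3", "N4", "N5")
TIME_SYMBOLS = ("t1", "t2", "t3", "t4")


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds for sizes (N), times (t) and admixture rate (ra).

    ``ordering`` lists strict inequalities among time symbols as
    ``(smaller, larger)`` pairs; the default chain is t1 < t2 < t3 < t4.
    """

    n_bounds: tuple[float, float] = (10.0, 6e5)
    t_bounds: tuple[float, float] = (10.0, 1e3)
    ra_bounds: tuple[float, float] = (1e-3, 0.999)
    ordering: tuple[tuple[str, str], ...] = (
        ("t1", "t2"),
        ("t2", "t3"),
        ("t3", "t4"),
    )

    def __post_init__(self) -> None:
        for name in ("n_bounds", "t_bounds", "ra_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound, got ({lo}, {hi})")
        for lo_sym, hi_sym in self.ordering:
            for sym in (lo_sym, hi_sym):
                if sym not in TIME_SYMBOLS:
                    raise ValueError(f"ordering refers to undeclared time symbol {sym!r}")

    def bounds_for(self, symbol: str) -> tuple[float, float]:
        """Prior bounds for one parameter symbol (NA/N* -> n, t* -> t, ra)."""
        if symbol.startswith("N"):
            return self.n_bounds
        if symbol.startswith("t"):
            return self.t_bounds
        if symbol == "ra":
            return self.ra_bounds
        raise KeyError(symbol)


@dataclass(frozen=True)
class DemographicEvent:
    """One backward-time event keyed by a symbolic time."""

    time_symbol: str
    kind: str  # "merge" | "admixture"
    source: str | None = None       # merge: deme whose lineages move
    dest: str | None = None         # merge: receiving deme
    admixed: str | None = None      # admixture: deme that dissolves
    parent1: str | None = None
    parent2: str | None = None
    rate_symbol: str | None = None  # admixture: probability of parent1
    dest_size_symbol: str | None = None  # optional new size of dest/parent above the event

    def __post_init__(self) -> None:
        if self.kind == "merge":
            if self.source is None or self.dest is None:
                raise ValueError("merge event requires source and dest")
        elif self.kind == "admixture":
            if None in (self.admixed, self.parent1, self.parent2, self.rate_symbol):
                raise ValueError("admixture event requires admixed, parent1, parent2, rate_symbol")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class Scenario:
    """A demographic scenario: sampled demes, size symbols, ordered events."""

    id: int
    events: tuple[DemographicEvent, ...]
    demes: tuple[str, ...] = DEMES
    size_symbols: tuple[str, ...] = SIZE_SYMBOLS
    ancestral_symbol: str = "NA"
    description: str = ""

    @property
    def parameters(self) -> tuple[str, ...]:
        """Symbols this scenario draws from the prior, in canonical order."""
        syms: list[str] = list(self.size_symbols) + [self.ancestral_symbol]
        times = sorted({e.time_symbol for e in self.events})
        rates = sorted({e.rate_symbol for e in self.events if e.rate_symbol})
        return tuple(syms + times + rates)


@dataclass(frozen=True)
class ParameterDraw:
    """Concrete values for the parameter subset a scenario uses."""

    scenario_id: int
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, symbol: str) -> float:
        return self.values[symbol]


def validate(scenario: Scenario) -> list[str]:
    """Check scenario invariants; return a list of violations (empty = ok).

    Checks: every referenced deme exists and is alive at its event's position
    in the list, every size symbol is declared, and the event list reduces the
    deme set to a single common ancestor.
    """
    violations: list[str] = []
    declared = set(scenario.size_symbols) | {scenario.ancestral_symbol}
    alive = set(scenario.demes)
    if len(scenario.demes) != len(scenario.size_symbols):
        violations.append("size symbol count does not match deme count")
    for i, ev in enumerate(scenario.events):
        if ev.time_symbol not in TIME_SYMBOLS:
            violations.append(f"event {i}: undeclared time symbol {ev.time_symbol!r}")
        if ev.dest_size_symbol is not None and ev.dest_size_symbol not in declared:
            violations.append(f"event {i}: undeclared size symbol {ev.dest_size_symbol!r}")
        if ev.kind == "merge":
            refs = {"source": ev.source, "dest": ev.dest}
        else:
            refs = {"admixed": ev.admixed, "parent1": ev.parent1, "parent2": ev.parent2}
        for role, deme in refs.items():
            if deme not in scenario.demes:
                violations.append(f"event {i}: unknown deme {deme!r} ({role})")
            elif deme not in alive:
                violations.append(f"event {i}: deme {deme!r} ({role}) not alive at event time")
        if ev.kind == "merge" and ev.source == ev.dest:
            violations.append(f"event {i}: merge source equals dest")
        # apply the event to the alive set
        gone = ev.source if ev.kind == "merge" else ev.admixed
        if gone in alive:
            alive.discard(gone)
    if len(alive) != 1:
        violations.append(
            f"no common ancestor: {len(alive)} demes remain after the last event"
        )
    return violations


def sample_prior(
    scenario: Scenario,
    priors: PriorSpec,
    rng: np.random.Generator,
    _max_tries: int = 100_000,
) -> ParameterDraw:
    """Draw one parameter vector from the prior for ``scenario``.

    Sizes and rates are independent uniforms; the time symbols are drawn
    jointly and redrawn until every ordering constraint holds, which yields the
    uniform density restricted to the order polytope.
    """
    values: dict[str, float] = {}
    for sym in scenario.size_symbols:
        values[sym] = rng.uniform(*priors.n_bounds)
    values[scenario.ancestral_symbol] = rng.uniform(*priors.n_bounds)
    for ev in scenario.events:
        if ev.rate_symbol is not None and ev.rate_symbol not in values:
            values[ev.rate_symbol] = rng.uniform(*priors.ra_bounds)

    time_syms = sorted({e.time_symbol for e in scenario.events})
    constraints = [
        (lo, hi) for lo, hi in priors.ordering if lo in time_syms and hi in time_syms
    ]
    for _ in range(_max_tries):
        draw = {s: rng.uniform(*priors.t_bounds) for s in time_syms}
        if all(draw[lo] < draw[hi] for lo, hi in constraints):
            values.update(draw)
            return ParameterDraw(scenario_id=scenario.id, values=values)
    raise RuntimeError(
        "prior time-ordering constraints not satisfied after "
        f"{_max_tries} joint redraws; check ordering for satisfiability"
    )


def _divergence_events(trunk: str, split_order: tuple[str, ...],
                       admix: bool = False) -> tuple[DemographicEvent, ...]:
    """Build the 4-event list of a pure-divergence (or admixed) scenario.

    ``split_order`` gives the demes merging into ``trunk`` at t1..t3; the
    basal deme Pop1 merges at t4 and the trunk takes the ancestral size. When
    ``admix`` is set, the t1 event becomes an admixture origin of the t1 deme
    from (trunk, Pop1) with rate ra.
    """
    t1_deme, t2_deme, t3_deme = split_order
    if admix:
        first = DemographicEvent(
            time_symbol="t1", kind="admixture",
            admixed=t1_deme, parent1=trunk, parent2="Pop1", rate_symbol="ra",
        )
    else:
        first = DemographicEvent(time_symbol="t1", kind="merge", source=t1_deme, dest=trunk)
    return (
        first,
        DemographicEvent(time_symbol="t2", kind="merge", source=t2_deme, dest=trunk),
        DemographicEvent(time_symbol="t3", kind="merge", source=t3_deme, dest=trunk),
        DemographicEvent(
            time_symbol="t4", kind="merge", source="Pop1", dest=trunk,
            dest_size_symbol="NA",
        ),
    )


def builtin_scenarios() -> list[Scenario]:
    """The eight shipped demographic scenarios.

    Scenarios 1-4 use the UPPER-CENTRAL deme (Pop3) as the trunk of the
    central metapopulation lineage; 5-8 mirror them with LOWER-CENTRAL (Pop2)
    as the trunk. Scenario 1: LOWER-CENTRAL splits from the trunk at t1, the
    NORTHERN group at t2, the EASTERN group at t3, and the basal SOUTHERN
    group at t4 where the trunk takes the ancestral size NA. Scenario 2 swaps
    the t2/t3 order of the NORTHERN and EASTERN splits. Scenarios 3 and 4
    replace the t1 divergence with an admixture origin of the t1 deme from the
    trunk and the SOUTHERN deme (rate ra). Topologies other than scenarios 1
    and 2 are provisional defaults and can be overridden via config files.
    """
    specs = [
        (1, "Pop3", ("Pop2", "Pop5", "Pop4"), False,
         "UPPER-CENTRAL trunk; eastern split older than northern"),
        (2, "Pop3", ("Pop2", "Pop4", "Pop5"), False,
         "UPPER-CENTRAL trunk; northern split older than eastern"),
        (3, "Pop3", ("Pop2", "Pop5", "Pop4"), True,
         "as scenario 1 with admixture origin of LOWER-CENTRAL (provisional)"),
        (4, "Pop3", ("Pop2", "Pop4", "Pop5"), True,
         "as scenario 2 with admixture origin of LOWER-CENTRAL (provisional)"),
        (5, "Pop2", ("Pop3", "Pop5", "Pop4"), False,
         "LOWER-CENTRAL trunk mirror of scenario 1 (provisional)"),
        (6, "Pop2", ("Pop3", "Pop4", "Pop5"), False,
         "LOWER-CENTRAL trunk mirror of scenario 2 (provisional)"),
        (7, "Pop2", ("Pop3", "Pop5", "Pop4"), True,
         "LOWER-CENTRAL trunk mirror of scenario 3 (provisional)"),
        (8, "Pop2", ("Pop3", "Pop4", "Pop5"), True,
         "LOWER-CENTRAL trunk mirror of scenario 4 (provisional)"),
    ]
    out = []
    for sid, trunk, order, admix, desc in specs:
        scn = Scenario(id=sid, events=_divergence_events(trunk, order, admix),
                       description=desc)
        assert not validate(scn), f"builtin scenario {sid} invalid"
        out.append(scn)
    return out


def trunk_deme(scenario: Scenario) -> str:
    """The deme that survives the whole event list (the scenario's trunk)."""
    alive = set(scenario.demes)
    for ev in scenario.events:
        alive.discard(ev.source if ev.kind == "merge" else ev.admixed)
    (deme,) = alive
    return deme


# ---------------------------------------------------------------------------
# structured-config round trip

def scenarios_to_config(scenarios: list[Scenario], priors: PriorSpec | None = None) -> dict:
    cfg: dict = {"scenarios": []}
    if priors is not None:
        cfg["priors"] = {
            "n_bounds": list(priors.n_bounds),
            "t_bounds": list(priors.t_bounds),
            "ra_bounds": list(priors.ra_bounds),
            "ordering": [list(p) for p in priors.ordering],
        }
    for s in scenarios:
        cfg["scenarios"].append(
            {
                "id": s.id,
                "description": s.description,
                "demes": list(s.demes),
                "size_symbols": list(s.size_symbols),
                "ancestral_symbol": s.ancestral_symbol,
                "events": [
                    {k: v for k, v in asdict(e).items() if v is not None}
                    for e in s.events
                ],
            }
        )
    return cfg


def scenarios_from_config(cfg: dict) -> tuple[list[Scenario], PriorSpec]:
    priors = PriorSpec()
    if "priors" in cfg:
        p = cfg["priors"]
        priors = PriorSpec(
            n_bounds=tuple(p.get("n_bounds", priors.n_bounds)),
            t_bounds=tuple(p.get("t_bounds", priors.t_bounds)),
            ra_bounds=tuple(p.get("ra_bounds", priors.ra_bounds)),
            ordering=tuple(tuple(x) for x in p.get("ordering", priors.ordering)),
        )
    scenarios = []
    for s in cfg.get("scenarios", []):
        events = tuple(DemographicEvent(**e) for e in s["events"])
        scn = Scenario(
            id=s["id"],
            events=events,
            demes=tuple(s.get("demes", DEMES)),
            size_symbols=tuple(s.get("size_symbols", SIZE_SYMBOLS)),
            ancestral_symbol=s.get("ancestral_symbol", "NA"),
            description=s.get("description", ""),
        )
        bad = validate(scn)
        if bad:
            raise ValueError(f"scenario {scn.id} invalid: {bad}")
        scenarios.append(scn)
    return scenarios, priors


def write_config(path: str | Path, scenarios: list[Scenario],
                 priors: PriorSpec | None = None) -> None:
    path = Path(path)
    cfg = scenarios_to_config(scenarios, priors)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2))


def read_config(path: str | Path) -> tuple[list[Scenario], PriorSpec]:
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    return scenarios_from_config(cfg)
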
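"""Sensitivity scenarios: which actor groups enable or block uptake.

Four suites of runs force groups of actors into supportive or unsupportive
attitudes while everyone else stays neutral (i.e. keeps their baseline
attitude distribution):

* all actors supportive / unsupportive;
* external (E) vs local (L) actors;
* government (G) vs market (M) actors;
* informal (I) vs formal (F) actors.

Each run records the uptake marginals of the three measures, their percent
change versus the baseline, and a synergy/trade-off class: S+ when all three
indicators increase, S- when all decrease, T when some increase and some
decrease ("none" when nothing changes at all).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import tables
from .bbn import BayesNet, infer_marginal
from .simodel import ActorProfile, default_roster

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "make_scenario_suite",
    "scenario_evidence",
    "run_scenario",
    "run_suite",
    "classify_tradeoff",
    "spatial_impact",
]

_GROUPS = {"all", "local", "external", "market", "government", "formal", "informal"}


@dataclass
class ScenarioSpec:
    """A named assignment of attitudes to actor groups.

    Actors in no assigned group stay neutral (baseline prior).
    """

    name: str
    assignments: dict = field(default_factory=dict)  # group -> attitude

    def __post_init__(self):
        for group, attitude in self.assignments.items():
            if group not in _GROUPS:
                raise ValueError(f"unknown group {group!r}")
            if attitude not in ("supportive", "neutral", "unsupportive"):
                raise ValueError(f"unknown attitude {attitude!r}")

    def attitude_of(self, actor: ActorProfile) -> str | None:
        """The attitude assigned to this actor, or None (stay baseline)."""
        states = []
        for group, attitude in self.assignments.items():
            if group == "all" or group in actor.groups:
                if attitude != "neutral":
                    states.append(attitude)
        if len(set(states)) > 1:
            raise ValueError(
                f"scenario {self.name!r}: conflicting states for {actor.name!r}"
            )
        return states[0] if states else None


def make_scenario_suite() -> list[ScenarioSpec]:
    """The 14 scenario rows of the sensitivity analysis."""
    suite = []
    pairs = [
        ("E", "external", "L", "local"),
        ("G", "government", "M", "market"),
        ("I", "informal", "F", "formal"),
    ]
    for a_lab, a_grp, b_lab, b_grp in pairs:
        suite.append(ScenarioSpec(
            f"{a_lab} unsupportive, {b_lab} neutral",
            {a_grp: "unsupportive", b_grp: "neutral"},
        ))
        suite.append(ScenarioSpec(
            f"{a_lab} unsupportive, {b_lab} supportive",
            {a_grp: "unsupportive", b_grp: "supportive"},
        ))
        suite.append(ScenarioSpec(
            f"{a_lab} supportive, {b_lab} unsupportive",
            {a_grp: "supportive", b_grp: "unsupportive"},
        ))
        suite.append(ScenarioSpec(
            f"{a_lab} supportive, {b_lab} neutral",
            {a_grp: "supportive", b_grp: "neutral"},
        ))
    suite.append(ScenarioSpec("All actors unsupportive", {"all": "unsupportive"}))
    suite.append(ScenarioSpec("All actors supportive", {"all": "supportive"}))
    return suite


def scenario_evidence(
    spec: ScenarioSpec, roster: Sequence[ActorProfile]
) -> dict[str, tuple[float, ...]]:
    """Actor prior replacements implementing a scenario.

    Supportive/unsupportive become degenerate distributions on the matching
    state; actors without an assignment keep their baseline prior (no
    entry).  An actor lacking the assigned state (Labels has no
    unsupportive state) is put on its least supportive available state.
    """
    evidence = {}
    for actor in roster:
        attitude = spec.attitude_of(actor)
        if attitude is None:
            continue
        if attitude not in actor.states:
            attitude = actor.states[-1]  # least supportive available
        dist = tuple(1.0 if s == attitude else 0.0 for s in actor.states)
        evidence[actor.name] = dist
    return evidence


def classify_tradeoff(deltas: Sequence[float]) -> str:
    """S_plus / S_minus / T / none from the signs of the three changes."""
    d = [float(x) for x in deltas]
    if len(d) != 3 or not all(np.isfinite(d)):
        raise ValueError("expected three finite values")
    if all(x > 0 for x in d):
        return "S_plus"
    if all(x < 0 for x in d):
        return "S_minus"
    if all(x == 0 for x in d):
        return "none"
    return "T"


@dataclass
class ScenarioResult:
    name: str
    sector: str
    uptake: dict                 # measure -> P(uptake=yes) under the scenario
    percent_change: dict         # measure -> 100*(p - p0)/p0
    classification: str


def run_scenario(
    net: BayesNet,
    spec: ScenarioSpec,
    baseline: Mapping[str, float],
    roster: Sequence[ActorProfile],
    sector: str = "",
) -> ScenarioResult:
    """Uptake marginals, percent changes and class for one scenario."""
    evidence = scenario_evidence(spec, roster)
    uptake, change = {}, {}
    for m in tables.MEASURES:
        p = infer_marginal(net, f"uptake_{m}", evidence)["yes"]
        p0 = baseline[m]
        if p0 <= 0:
            raise ZeroDivisionError(
                f"baseline uptake for {m} is zero; percent change undefined"
            )
        uptake[m] = p
        change[m] = 100.0 * (p - p0) / p0
    return ScenarioResult(
        spec.name, sector, uptake, change,
        classify_tradeoff([change[m] for m in tables.MEASURES]),
    )


def run_suite(
    net: BayesNet,
    sector: str,
    roster: Sequence[ActorProfile] | None = None,
    baseline: str | Mapping[str, float] = "model",
) -> pd.DataFrame:
    """Run the 14-scenario suite.

    ``baseline`` selects the reference for percent changes: ``"model"`` (the
    network's own baseline uptake marginals), ``"observed"`` (the quoted
    observed adoption shares), or an explicit measure->probability map.
    """
    roster = list(roster) if roster is not None else default_roster(sector)
    if baseline == "model":
        base = {m: infer_marginal(net, f"uptake_{m}")["yes"] for m in tables.MEASURES}
    elif baseline == "observed":
        base = dict(tables.OBSERVED_ADOPTION[sector])
    else:
        base = dict(baseline)
    rows = []
    for spec in make_scenario_suite():
        res = run_scenario(net, spec, base, roster, sector)
        row = {"scenario": res.name, "sector": sector, "class": res.classification}
        for m in tables.MEASURES:
            row[f"uptake_{m}"] = res.uptake[m]
            row[f"pct_change_{m}"] = res.percent_change[m]
        rows.append(row)
    return pd.DataFrame(rows)


def spatial_impact(
    farms,
    net: BayesNet,
    measure: str,
    roster: Sequence[ActorProfile] | None = None,
    sector: str | None = None,
) -> pd.DataFrame:
    """Per-farm all-supportive minus all-unsupportive uptake difference.

    Each farm's characteristics (location, size, age, successor,
    innovativeness) are entered as hard evidence; the uptake marginal is
    computed under the two extreme scenarios and the difference (always
    >= 0 by the monotone construction of the model) is returned per farm.
    """
    if measure not in tables.MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    roster = list(roster) if roster is not None else default_roster(
        sector or (farms[0].sector if farms else "dairy")
    )
    sup = scenario_evidence(ScenarioSpec("sup", {"all": "supportive"}), roster)
    unsup = scenario_evidence(ScenarioSpec("unsup", {"all": "unsupportive"}), roster)

    cache: dict[tuple, tuple[float, float]] = {}
    rows = []
    for farm in farms:
        key = (
            farm.location_class, farm.size_class, farm.age_class,
            farm.successor, farm.innovative,
        )
        if key not in cache:
            char_ev = {
                "location": farm.location_class,
                "size": farm.size_class,
                "age": farm.age_class,
                "successor": "yes" if farm.successor else "no",
                "innovative": farm.innovative,
            }
            p_sup = infer_marginal(net, f"uptake_{measure}", {**char_ev, **sup})["yes"]
            p_unsup = infer_marginal(net, f"uptake_{measure}", {**char_ev, **unsup})["yes"]
            cache[key] = (p_sup, p_unsup)
        p_sup, p_unsup = cache[key]
        rows.append({
            "farm_id": farm.farm_id,
            "sector": farm.sector,
            "x": farm.x,
            "y": farm.y,
            "p_supportive": p_sup,
            "p_unsupportive": p_unsup,
            "difference": p_sup - p_unsup,
        })
    return pd.DataFrame(rows)
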
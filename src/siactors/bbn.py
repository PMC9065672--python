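"""Discrete Bayesian belief networks with exact inference.

The networks used in this package are small (a few dozen nodes, two or three
states each), so everything is done in linear probability space with dense
:class:`numpy.ndarray` factors.  Two query routes are provided:

* :func:`infer_marginal` — variable elimination with a min-degree ordering,
  the production path;
* :func:`enumerate_joint` — summation of the explicit full joint, a slow
  reference implementation used as an oracle on small networks.

Soft (virtual) evidence is supported on root nodes only, by replacing the
node's prior with the supplied distribution.  This is exactly what the
scenario machinery needs: attitudes of actor groups are distributions, not
observed states.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DiscreteNode",
    "BayesNet",
    "ValidationError",
    "CycleError",
    "InconsistentEvidenceError",
    "validate_network",
    "infer_marginal",
    "enumerate_joint",
    "net_to_json",
    "net_from_json",
]

_ATOL = 1e-9


class ValidationError(ValueError):
    """A structural or numerical defect in a network definition."""


class CycleError(ValidationError):
    """The directed graph of parent links contains a cycle."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        super().__init__("cycle among nodes: " + " -> ".join(self.cycle))


class InconsistentEvidenceError(ValueError):
    """Evidence with zero probability under the model."""


@dataclass
class DiscreteNode:
    """A discrete chance node.

    Parameters
    ----------
    name
        Unique node identifier.
    states
        Ordered state labels.
    parents
        Ordered parent node names; the CPT rows follow this order.
    cpt
        Array of shape ``parent_cards + (len(states),)``.  For a root node,
        shape ``(len(states),)`` — the prior.  Every row must sum to 1.
    """

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()
    cpt: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.parents = tuple(self.parents)
        self.cpt = np.asarray(self.cpt, dtype=float)
        if len(set(self.states)) != len(self.states):
            raise ValidationError(f"node {self.name!r}: duplicate state labels")

    @property
    def card(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"node {self.name!r} has no state {state!r}") from None


class BayesNet:
    """A set of :class:`DiscreteNode` forming a DAG."""

    def __init__(self, nodes: Iterable[DiscreteNode]):
        self.nodes: dict[str, DiscreteNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ValidationError(f"duplicate node {node.name!r}")
            self.nodes[node.name] = node

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __getitem__(self, name: str) -> DiscreteNode:
        return self.nodes[name]

    def node_names(self) -> list[str]:
        return list(self.nodes)

    def children(self, name: str) -> list[str]:
        return [n.name for n in self.nodes.values() if name in n.parents]

    def copy(self) -> "BayesNet":
        return BayesNet(
            DiscreteNode(n.name, n.states, n.parents, n.cpt.copy())
            for n in self.nodes.values()
        )

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; raises :class:`CycleError` naming a cycle."""
        indeg = {name: 0 for name in self.nodes}
        for node in self.nodes.values():
            for p in node.parents:
                if p not in self.nodes:
                    raise ValidationError(
                        f"node {node.name!r} references unknown parent {p!r}"
                    )
                indeg[node.name] += 1
        queue = [n for n, d in indeg.items() if d == 0]
        order: list[str] = []
        while queue:
            name = queue.pop()
            order.append(name)
            for c in self.children(name):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) < len(self.nodes):
            remaining = [n for n in self.nodes if n not in order]
            raise CycleError(_find_cycle(self, remaining))
        return order


def _find_cycle(net: BayesNet, candidates: Sequence[str]) -> list[str]:
    start = candidates[0]
    seen: list[str] = []
    cur = start
    while cur not in seen:
        seen.append(cur)
        cur = next(p for p in net[cur].parents if p in candidates)
    i = seen.index(cur)
    return seen[i:] + [cur]


def validate_network(net: BayesNet, strict: bool = True) -> list[str]:
    """Check acyclicity, parent resolution, CPT shapes and row normalization.

    Returns a list of human-readable problem descriptions (empty if valid).
    With ``strict=True`` raises on the first problem instead.
    """
    problems: list[str] = []
    try:
        net.topological_order()
    except ValidationError as exc:
        if strict:
            raise
        problems.append(str(exc))
        return problems

    for node in net.nodes.values():
        expected = tuple(net[p].card for p in node.parents) + (node.card,)
        if node.cpt.shape != expected:
            msg = (
                f"node {node.name!r}: CPT shape {node.cpt.shape} != "
                f"expected {expected}"
            )
            if strict:
                raise ValidationError(msg)
            problems.append(msg)
            continue
        rows = node.cpt.reshape(-1, node.card)
        sums = rows.sum(axis=-1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > _ATOL)
        if bad.size:
            flat = int(bad[0])
            row = tuple(int(i) for i in np.unravel_index(flat, node.cpt.shape[:-1]))
            msg = (
                f"node {node.name!r}: CPT row {row} sums to "
                f"{float(sums[flat]):.6g}, not 1"
            )
            if strict:
                raise ValidationError(msg)
            problems.append(msg)
        if (node.cpt < -_ATOL).any():
            msg = f"node {node.name!r}: negative probability in CPT"
            if strict:
                raise ValidationError(msg)
            problems.append(msg)
    return problems


# ---------------------------------------------------------------------------
# Factors


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, variables: tuple[str, ...], table: np.ndarray):
        self.vars = variables
        self.table = table

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._expand(out_vars)
        b = other._expand(out_vars)
        return _Factor(out_vars, a * b)

    def _expand(self, out_vars: tuple[str, ...]) -> np.ndarray:
        # Move own axes into out_vars order, adding singleton axes for absent vars.
        perm = [self.vars.index(v) for v in out_vars if v in self.vars]
        arr = np.transpose(self.table, perm)
        shape = []
        k = 0
        for v in out_vars:
            if v in self.vars:
                shape.append(arr.shape[k])
                k += 1
            else:
                shape.append(1)
        return arr.reshape(shape)

    def marginalize(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            self.vars[:axis] + self.vars[axis + 1 :],
            self.table.sum(axis=axis),
        )

    def reduce(self, var: str, index: int) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            self.vars[:axis] + self.vars[axis + 1 :],
            np.take(self.table, index, axis=axis),
        )


Evidence = Mapping[str, "str | Sequence[float]"]


def _prepare_factors(net: BayesNet, evidence: Evidence | None) -> list[_Factor]:
    evidence = dict(evidence or {})
    factors: list[_Factor] = []
    hard: dict[str, int] = {}
    for name, val in evidence.items():
        if name not in net:
            raise KeyError(f"evidence on unknown node {name!r}")
        if isinstance(val, str):
            hard[name] = net[name].state_index(val)
        else:
            dist = np.asarray(val, dtype=float)
            node = net[name]
            if node.parents:
                raise ValueError(
                    f"soft evidence only supported on root nodes, {name!r} has parents"
                )
            if dist.shape != (node.card,):
                raise ValueError(
                    f"soft evidence for {name!r} must have {node.card} entries"
                )
            if abs(dist.sum() - 1.0) > 1e-6:
                raise ValueError(f"soft evidence for {name!r} does not sum to 1")
    for node in net.nodes.values():
        variables = node.parents + (node.name,)
        table = node.cpt
        if node.name in evidence and not isinstance(evidence[node.name], str):
            table = np.asarray(evidence[node.name], dtype=float)
        f = _Factor(variables, np.asarray(table, dtype=float))
        for var, idx in hard.items():
            if var in f.vars:
                f = f.reduce(var, idx)
        factors.append(f)
    return factors


def infer_marginal(
    net: BayesNet, query: str, evidence: Evidence | None = None
) -> dict[str, float]:
    """Exact posterior marginal of ``query`` given evidence.

    Evidence values may be state labels (hard evidence) or distributions over
    a root node's states (soft evidence, implemented as prior replacement).
    Raises :class:`InconsistentEvidenceError` if the evidence has zero
    probability.
    """
    if query not in net:
        raise KeyError(f"unknown query node {query!r}")
    evidence = dict(evidence or {})
    if query in evidence and isinstance(evidence[query], str):
        # Degenerate posterior.
        out = {s: 0.0 for s in net[query].states}
        out[str(evidence[query])] = 1.0
        return out

    factors = _prepare_factors(net, evidence)
    to_eliminate = {
        v for f in factors for v in f.vars if v != query
    }
    while to_eliminate:
        var = _min_degree_var(factors, to_eliminate)
        related = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        prod = related[0]
        for f in related[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(var)]
        to_eliminate.discard(var)

    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    table = np.asarray(result.table, dtype=float).reshape(-1)
    if result.vars and result.vars != (query,):
        raise AssertionError("elimination left unexpected variables")
    total = table.sum() if result.vars else float(table)
    if not result.vars:
        # query itself was eliminated -> cannot happen, guarded above
        raise AssertionError("query eliminated")
    if total <= 0:
        raise InconsistentEvidenceError(
            f"evidence has zero probability (querying {query!r})"
        )
    probs = table / total
    return dict(zip(net[query].states, probs.tolist()))


def _min_degree_var(factors: list[_Factor], candidates: set[str]) -> str:
    # Degree = number of distinct co-occurring variables after elimination.
    best, best_deg = None, None
    for var in sorted(candidates):
        neighbors: set[str] = set()
        for f in factors:
            if var in f.vars:
                neighbors.update(f.vars)
        neighbors.discard(var)
        if best_deg is None or len(neighbors) < best_deg:
            best, best_deg = var, len(neighbors)
    assert best is not None
    return best


def enumerate_joint(
    net: BayesNet,
    query: str,
    evidence: Evidence | None = None,
    max_joint: int = 10**7,
) -> dict[str, float]:
    """Marginal by explicit summation of the full joint (reference oracle)."""
    if query not in net:
        raise KeyError(f"unknown query node {query!r}")
    names = net.topological_order()
    cards = [net[n].card for n in names]
    size = int(np.prod(cards)) if cards else 1
    if size > max_joint:
        raise ValueError(f"joint of size {size} exceeds limit {max_joint}")
    evidence = dict(evidence or {})

    soft: dict[str, np.ndarray] = {}
    hard: dict[str, int] = {}
    for name, val in evidence.items():
        if isinstance(val, str):
            hard[name] = net[name].state_index(val)
        else:
            if net[name].parents:
                raise ValueError("soft evidence only supported on root nodes")
            soft[name] = np.asarray(val, dtype=float)

    acc = np.zeros(net[query].card)
    for combo in itertools.product(*(range(c) for c in cards)):
        assignment = dict(zip(names, combo))
        if any(assignment[n] != i for n, i in hard.items()):
            continue
        p = 1.0
        for n, idx in assignment.items():
            node = net[n]
            if n in soft:
                p *= soft[n][idx]
            else:
                row = node.cpt[tuple(assignment[q] for q in node.parents)]
                p *= row[idx]
        acc[assignment[query]] += p
    total = acc.sum()
    if total <= 0:
        raise InconsistentEvidenceError("evidence has zero probability")
    return dict(zip(net[query].states, (acc / total).tolist()))


# ---------------------------------------------------------------------------
# JSON serialization


def net_to_json(net: BayesNet, path=None) -> str:
    """Serialize to a JSON document (CPT rows row-major in parent order)."""
    doc = {
        "format": "siactors-bbn",
        "version": 1,
        "row_order": "row-major over parents in listed order",
        "nodes": [
            {
                "name": n.name,
                "states": list(n.states),
                "parents": list(n.parents),
                "cpt": np.asarray(n.cpt).reshape(-1, n.card).tolist(),
            }
            for n in net.nodes.values()
        ],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def net_from_json(source: str) -> BayesNet:
    """Load a network from a JSON string or a path to a JSON file."""
    if "\n" not in source and source.endswith(".json"):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = json.loads(source)
    name_to_states = {n["name"]: n["states"] for n in doc["nodes"]}
    nodes = []
    for n in doc["nodes"]:
        cards = tuple(len(name_to_states[p]) for p in n["parents"])
        cpt = np.asarray(n["cpt"], dtype=float).reshape(cards + (len(n["states"]),))
        nodes.append(DiscreteNode(n["name"], tuple(n["states"]), tuple(n["parents"]), cpt))
    net = BayesNet(nodes)
    validate_network(net)
    return net
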
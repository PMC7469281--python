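"""Update semantics, exhaustive state-transition graphs and attractors.

States are total assignments of 0/1 to every node, represented as tuples of
bits in the network's declaration order (dict-based views are accepted by
the public functions).  Two update schemes are supported:

* **synchronous** — every node updates simultaneously; each state has
  exactly one successor.
* **asynchronous** — one node updates at a time; each state has one
  successor per node whose update changes it, and a self-loop if none does.
  This is the full (general) asynchronous graph containing every
  interleaving, so attractor analysis over it is update-order independent.

Attractors are terminal strongly-connected components of the state
transition graph: state sets the dynamics cannot leave.  Under the
self-loop convention a fixed point is a terminal SCC of size one.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx

from .network import BooleanNetwork

__all__ = [
    "Perturbation",
    "StateTransitionGraph",
    "Attractor",
    "CapacityError",
    "evaluate_node",
    "synchronous_step",
    "asynchronous_successors",
    "build_state_transition_graph",
    "find_attractors",
    "summarize_attractor",
    "attractors_to_json",
    "attractors_to_tsv",
    "stg_to_dot",
]

State = tuple[int, ...]
Scheme = Literal["synchronous", "asynchronous"]

#: Exhaustive-enumeration bound: 2^22 ~ 4M states is the desk-scale ceiling.
DEFAULT_MAX_NODES = 22


class CapacityError(ValueError):
    """Raised when a network exceeds the exhaustive-enumeration bound."""


@dataclass(frozen=True)
class Perturbation:
    """Clamps overriding node rules with constants (treatment/knockdown).

    A clamped node's effective rule is the constant, regardless of the rule
    stored in the network.
    """

    clamps: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "clamps", dict(self.clamps))
        for name, value in self.clamps.items():
            if value not in (0, 1):
                raise ValueError(f"clamp for {name!r} must be 0 or 1, got {value!r}")

    def validate_against(self, net: BooleanNetwork) -> None:
        unknown = set(self.clamps) - set(net.nodes)
        if unknown:
            raise KeyError(f"clamped node(s) not in network: {', '.join(sorted(unknown))}")

    def merged(self, extra: "Perturbation | None") -> "Perturbation":
        if extra is None:
            return self
        clamps = dict(self.clamps)
        clamps.update(extra.clamps)
        return Perturbation(clamps)


def _as_mapping(net: BooleanNetwork, state) -> dict[str, int]:
    if isinstance(state, Mapping):
        missing = set(net.nodes) - set(state)
        if missing:
            raise KeyError(f"state missing node(s): {', '.join(sorted(missing))}")
        return {n: int(state[n]) for n in net.nodes}
    if len(state) != len(net.nodes):
        raise ValueError(f"state has {len(state)} bits for {len(net.nodes)} nodes")
    return dict(zip(net.nodes, (int(b) for b in state)))


def evaluate_node(
    net: BooleanNetwork,
    node: str,
    state: Mapping[str, int] | Sequence[int],
    pert: Perturbation | None = None,
) -> int:
    """Next value of one node: the clamp if clamped, else its rule on *state*."""
    if node not in net.rules:
        raise KeyError(f"unknown node {node!r}")
    if pert is not None:
        pert.validate_against(net)
        if node in pert.clamps:
            return pert.clamps[node]
    return net.rules[node].evaluate(_as_mapping(net, state))


def synchronous_step(
    net: BooleanNetwork,
    state: Mapping[str, int] | Sequence[int],
    pert: Perturbation | None = None,
) -> dict[str, int]:
    """Joint update: every node evaluated simultaneously on *state*."""
    mapping = _as_mapping(net, state)
    clamps = pert.clamps if pert is not None else {}
    if pert is not None:
        pert.validate_against(net)
    return {
        n: clamps[n] if n in clamps else net.rules[n].evaluate(mapping)
        for n in net.nodes
    }


def asynchronous_successors(
    net: BooleanNetwork,
    state: Mapping[str, int] | Sequence[int],
    pert: Perturbation | None = None,
) -> set[State]:
    """Single-node-update successors of *state*.

    One successor per node whose update changes its value; a stable state
    yields ``{state}`` (the self-loop convention).
    """
    mapping = _as_mapping(net, state)
    current = tuple(mapping[n] for n in net.nodes)
    target = synchronous_step(net, mapping, pert)
    successors: set[State] = set()
    for i, name in enumerate(net.nodes):
        if target[name] != current[i]:
            successors.add(current[:i] + (target[name],) + current[i + 1 :])
    if not successors:
        successors.add(current)
    return successors


@dataclass
class StateTransitionGraph:
    """Exhaustive directed graph of states under one update scheme.

    Without a perturbation the state set is all ``2^n`` assignments.  Under
    clamps, only the clamp-consistent subspace is enumerated (``2^n_free``
    full states with the clamped bits fixed), which is closed under both
    update schemes.
    """

    graph: nx.DiGraph
    nodes: tuple[str, ...]
    scheme: Scheme
    perturbation: Perturbation

    @property
    def n_states(self) -> int:
        return self.graph.number_of_nodes()


def build_state_transition_graph(
    net: BooleanNetwork,
    pert: Perturbation | None = None,
    scheme: Scheme = "asynchronous",
    max_nodes: int = DEFAULT_MAX_NODES,
) -> StateTransitionGraph:
    """Enumerate every state and its transitions under *scheme*."""
    if scheme not in ("synchronous", "asynchronous"):
        raise ValueError(f"unknown update scheme {scheme!r}")
    pert = pert if pert is not None else Perturbation()
    pert.validate_against(net)
    free = [n for n in net.nodes if n not in pert.clamps]
    if len(free) > max_nodes:
        raise CapacityError(
            f"{len(free)} free nodes exceeds the exhaustive bound of {max_nodes}; "
            "use a smaller model or raise max_nodes"
        )
    graph = nx.DiGraph()
    fixed = {n: pert.clamps[n] for n in net.nodes if n in pert.clamps}
    for bits in itertools.product((0, 1), repeat=len(free)):
        assignment = dict(fixed)
        assignment.update(zip(free, bits))
        state: State = tuple(assignment[n] for n in net.nodes)
        graph.add_node(state)
        if scheme == "synchronous":
            nxt = synchronous_step(net, assignment, pert)
            graph.add_edge(state, tuple(nxt[n] for n in net.nodes))
        else:
            for succ in asynchronous_successors(net, assignment, pert):
                graph.add_edge(state, succ)
    return StateTransitionGraph(graph, net.nodes, scheme, pert)


@dataclass
class Attractor:
    """A terminal SCC of the state-transition graph.

    ``basin_size`` (synchronous: states reaching this and only this
    attractor) or ``weak_basin_size`` (asynchronous: states that *can* reach
    it; weak basins may overlap) count the attractor's own states too.
    """

    states: frozenset[State]
    kind: Literal["fixed_point", "cyclic", "complex"]
    nodes: tuple[str, ...]
    basin_size: int | None = None
    weak_basin_size: int | None = None

    @property
    def size(self) -> int:
        return len(self.states)

    def sorted_states(self) -> list[State]:
        return sorted(self.states)


def find_attractors(
    stg: StateTransitionGraph, compute_basins: bool = True
) -> list[Attractor]:
    """Every terminal SCC, classified and deterministically ordered.

    Ordering is by (size, lexicographically smallest contained state with
    nodes in declaration order).  Under the synchronous scheme basin sizes
    partition the state set and sum to its cardinality.
    """
    attractors: list[Attractor] = []
    for component in nx.attracting_components(stg.graph):
        states = frozenset(component)
        if len(states) == 1:
            kind = "fixed_point"
        elif stg.scheme == "synchronous":
            kind = "cyclic"
        else:
            kind = "complex"
        attractors.append(Attractor(states, kind, stg.nodes))
    attractors.sort(key=lambda a: (a.size, min(a.states)))
    if compute_basins:
        for att in attractors:
            reach = set(att.states)
            for s in att.states:
                reach |= nx.ancestors(stg.graph, s)
            if stg.scheme == "synchronous":
                att.basin_size = len(reach)
            else:
                att.weak_basin_size = len(reach)
    return attractors


def summarize_attractor(
    att: Attractor, nodes: Iterable[str] | None = None
) -> dict[str, int | str]:
    """Per-node readout: 1/0 if constant across all attractor states, else
    ``"oscillating"``."""
    requested = tuple(nodes) if nodes is not None else att.nodes
    index = {n: i for i, n in enumerate(att.nodes)}
    summary: dict[str, int | str] = {}
    for name in requested:
        if name not in index:
            raise KeyError(f"unknown node {name!r}")
        values = {state[index[name]] for state in att.states}
        summary[name] = values.pop() if len(values) == 1 else "oscillating"
    return summary


# --------------------------------------------------------------------------
# Reports


def attractors_to_json(attractors: Sequence[Attractor]) -> str:
    payload = []
    for att in attractors:
        entry = {
            "kind": att.kind,
            "size": att.size,
            "states": [dict(zip(att.nodes, s)) for s in att.sorted_states()],
            "summary": summarize_attractor(att),
        }
        if att.basin_size is not None:
            entry["basin_size"] = att.basin_size
        if att.weak_basin_size is not None:
            entry["weak_basin_size"] = att.weak_basin_size
        payload.append(entry)
    return json.dumps(payload, indent=2) + "\n"


def attractors_to_tsv(attractors: Sequence[Attractor]) -> str:
    """Flat table: one row per attractor x node."""
    lines = ["attractor\tkind\tsize\tnode\tvalue"]
    for i, att in enumerate(attractors, start=1):
        summary = summarize_attractor(att)
        for node in att.nodes:
            lines.append(f"{i}\t{att.kind}\t{att.size}\t{node}\t{summary[node]}")
    return "\n".join(lines) + "\n"


def stg_to_dot(stg: StateTransitionGraph, attractors: Sequence[Attractor] | None = None) -> str:
    """DOT rendering of the STG; attractor states are shaded."""
    marked: set[State] = set()
    if attractors:
        for att in attractors:
            marked |= att.states
    def label(state: State) -> str:
        return "".join(str(b) for b in state)
    lines = ["digraph stg {", "  node [shape=box, fontname=monospace];"]
    for state in sorted(stg.graph.nodes):
        attrs = ' style=filled fillcolor="lightblue"' if state in marked else ""
        lines.append(f'  "{label(state)}" [{attrs.strip()}];' if attrs else f'  "{label(state)}";')
    for src, dst in sorted(stg.graph.edges):
        lines.append(f'  "{label(src)}" -> "{label(dst)}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
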
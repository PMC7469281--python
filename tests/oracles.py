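"""Independent brute-force oracles used to cross-check the engine.

Everything here works from the serialized rule text and plain Python,
deliberately avoiding the package's expression AST, graph machinery and
attractor detector.
"""

from __future__ import annotations

import itertools
import re
from math import comb


def rules_from_text(text: str) -> dict[str, str]:
    """Rule expressions by node, straight from the serialized dialect."""
    lines = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
    assert lines[0].lower().replace(" ", "") == "targets,factors"
    rules = {}
    for line in lines[1:]:
        name, expr = line.split(",", 1)
        rules[name.strip()] = expr.strip()
    return rules


def eval_rule(expr: str, state: dict[str, int]) -> int:
    """Evaluate a rule via Python's own boolean operators."""
    py = re.sub(
        r"\b([A-Za-z_][A-Za-z0-9_]*)\b",
        lambda m: "True" if state[m.group(1)] else "False",
        expr,
    )
    py = re.sub(r"\b0\b", "False", py)
    py = re.sub(r"\b1\b", "True", py)
    py = py.replace("!", " not ").replace("&", " and ").replace("|", " or ")
    return int(eval(py))  # noqa: S307 - trusted test fixture text


def sync_successor(rules: dict[str, str], nodes: list[str], state: tuple[int, ...],
                   clamps: dict[str, int] | None = None) -> tuple[int, ...]:
    clamps = clamps or {}
    mapping = dict(zip(nodes, state))
    return tuple(
        clamps[n] if n in clamps else eval_rule(rules[n], mapping) for n in nodes
    )


def async_successors(rules: dict[str, str], nodes: list[str], state: tuple[int, ...],
                     clamps: dict[str, int] | None = None) -> set[tuple[int, ...]]:
    """Single-flip enumeration: flip each node toward its target value."""
    target = sync_successor(rules, nodes, state, clamps)
    succ = set()
    for i in range(len(nodes)):
        if target[i] != state[i]:
            succ.add(state[:i] + (target[i],) + state[i + 1:])
    return succ or {state}


def all_states(n: int):
    return itertools.product((0, 1), repeat=n)


def _reachable(succ: dict[tuple, set[tuple]], start: tuple) -> set[tuple]:
    seen = {start}
    frontier = [start]
    while frontier:
        s = frontier.pop()
        for t in succ[s]:
            if t not in seen:
                seen.add(t)
                frontier.append(t)
    return seen


def brute_force_attractors(rules: dict[str, str], nodes: list[str], scheme: str,
                           clamps: dict[str, int] | None = None) -> set[frozenset]:
    """States from which no escape is possible, grouped into attractors.

    A state belongs to an attractor iff every state reachable from it can
    reach it back; the attractor is then its reachable set.
    """
    clamps = clamps or {}
    free = [n for n in nodes if n not in clamps]
    states = []
    for bits in all_states(len(free)):
        a = dict(clamps)
        a.update(zip(free, bits))
        states.append(tuple(a[n] for n in nodes))
    if scheme == "synchronous":
        succ = {s: {sync_successor(rules, nodes, s, clamps)} for s in states}
    else:
        succ = {s: async_successors(rules, nodes, s, clamps) for s in states}
    reach = {s: _reachable(succ, s) for s in states}
    attractors: set[frozenset] = set()
    for s in states:
        if all(s in reach[t] for t in reach[s]):
            attractors.add(frozenset(reach[s]))
    return attractors


def brute_force_basins(rules, nodes, clamps=None) -> dict[frozenset, int]:
    """Synchronous basin sizes: each state follows its unique trajectory."""
    attractors = brute_force_attractors(rules, nodes, "synchronous", clamps)
    clamps = clamps or {}
    free = [n for n in nodes if n not in clamps]
    basins = {a: 0 for a in attractors}
    for bits in all_states(len(free)):
        a = dict(clamps)
        a.update(zip(free, bits))
        s = tuple(a[n] for n in nodes)
        seen = set()
        while s not in seen:
            seen.add(s)
            s = sync_successor(rules, nodes, s, clamps)
        for att in attractors:
            if s in att:
                basins[att] += 1
                break
    return basins


def hypergeom_upper_tail(overlap: int, query: int, term: int, universe: int) -> float:
    """P(X >= overlap) by explicit pmf summation."""
    total = comb(universe, query)
    acc = 0
    for k in range(overlap, min(query, term) + 1):
        acc += comb(term, k) * comb(universe - term, query - k)
    return acc / total
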
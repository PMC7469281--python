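"""Seeded generators for every input the pipeline consumes.

Three generators, all pure functions of their arguments plus an integer
seed (numpy's PCG64 generator; no global random state is touched):

* random Boolean networks — oracle fixtures for the logic engine;
* secretome tables — an antibody-array-style table where a minority of
  analytes carry high normalized intensity (above the 0.2 cutoff) and the
  rest are low-level noise strictly below it;
* GMT libraries with one planted enriched term among uniform decoys, for
  testing over-representation recovery.

Decoy genes use synthetic symbols (G000001...) so accidental matches with
real gene names are impossible.  Identical arguments and seed give
byte-identical serialized outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enrichment import GeneSetLibrary, SecretomeTable
from .network import And, BooleanNetwork, Const, Expr, Not, Or, Var

__all__ = [
    "GeneratorConfig",
    "make_random_network",
    "make_secretome",
    "make_library",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of generator settings; defaults match the study conditions
    (a ~150-analyte array with a high-intensity minority; a 100-term
    library over a 2,000-gene universe with one planted term)."""

    seed: int = 0
    network_nodes: int = 8
    network_max_inputs: int = 3
    secretome_analytes: int = 150
    secretome_signal: int = 25
    signal_intensity: float = 0.9
    noise_range: tuple[float, float] = (0.0, 0.15)
    library_terms: int = 100
    term_size_range: tuple[int, int] = (20, 40)
    universe: int = 2000
    planted_overlap: int = 15
    extra: dict = field(default_factory=dict, compare=False)


def _random_expr(rng: np.random.Generator, regulators: list[str]) -> Expr:
    """Random expression over the given regulators: each appears once as a
    possibly-negated literal, joined left-to-right by random AND/OR."""
    literals: list[Expr] = []
    for name in regulators:
        lit: Expr = Var(name)
        if rng.random() < 0.5:
            lit = Not(lit)
        literals.append(lit)
    expr = literals[0]
    for lit in literals[1:]:
        expr = And(expr, lit) if rng.random() < 0.5 else Or(expr, lit)
    return expr


def make_random_network(n_nodes: int, max_inputs: int, seed: int) -> BooleanNetwork:
    """Random Boolean network with <= *max_inputs* regulators per rule.

    With small probability a rule is a bare constant, so the generated
    family covers all four unary behaviors (identity, negation, 0, 1).
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if max_inputs < 1:
        raise ValueError("max_inputs must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:02d}" for i in range(n_nodes)]
    rules: dict[str, Expr] = {}
    for node in nodes:
        if rng.random() < 0.05:
            rules[node] = Const(int(rng.integers(0, 2)))
            continue
        k = int(rng.integers(1, max_inputs + 1))
        k = min(k, n_nodes)
        regs = [nodes[i] for i in rng.choice(n_nodes, size=k, replace=False)]
        rules[node] = _random_expr(rng, regs)
    return BooleanNetwork(nodes, rules)


def make_secretome(
    n_analytes: int,
    n_signal: int,
    signal_intensity: float = 0.9,
    noise_range: tuple[float, float] = (0.0, 0.15),
    threshold: float = 0.2,
    seed: int = 0,
) -> SecretomeTable:
    """Array-style table: *n_signal* analytes at *signal_intensity* (above
    the cutoff), the remainder uniform in *noise_range* (strictly below it).

    Analytes are named SYN0001... with the planted signal occupying the
    first *n_signal* names, so the planted set is seed-independent while
    the noise intensities vary with the seed.
    """
    if n_signal > n_analytes:
        raise ValueError("n_signal must not exceed n_analytes")
    lo, hi = noise_range
    if not (0 <= lo <= hi):
        raise ValueError("noise_range must satisfy 0 <= low <= high")
    if hi >= threshold:
        raise ValueError(
            f"noise_range upper bound {hi} must stay strictly below the threshold {threshold}"
        )
    if signal_intensity <= threshold:
        raise ValueError(
            f"signal_intensity {signal_intensity} must exceed the threshold {threshold}"
        )
    rng = np.random.default_rng(seed)
    entries: dict[str, float] = {}
    for i in range(n_analytes):
        name = f"SYN{i + 1:04d}"
        if i < n_signal:
            entries[name] = float(signal_intensity)
        else:
            entries[name] = float(rng.uniform(lo, hi))
    return SecretomeTable(entries)


def make_library(
    n_terms: int,
    term_size_range: tuple[int, int],
    universe: int,
    planted_overlap: int,
    planted_query: list[str],
    seed: int = 0,
) -> GeneSetLibrary:
    """GMT-style library with one planted enriched term among uniform decoys.

    The planted term (``PLANTED``) shares exactly *planted_overlap* genes
    with *planted_query*; its remaining members and all decoy terms
    (``DECOY_001``...) are drawn uniformly from a synthetic-symbol pool
    disjoint from the query.  The universe for the test is the query plus
    the synthetic pool, *universe* genes in total.
    """
    if not planted_query:
        raise ValueError("planted_query must be nonempty")
    lo, hi = term_size_range
    if not (1 <= lo <= hi):
        raise ValueError("term_size_range must satisfy 1 <= low <= high")
    query = [g.strip().upper() for g in planted_query]
    if planted_overlap > len(query) or planted_overlap > hi:
        raise ValueError(
            "planted_overlap must not exceed the query size or the maximum term size"
        )
    n_decoy_pool = universe - len(query)
    if n_decoy_pool < hi:
        raise ValueError("universe too small for the requested term sizes")
    rng = np.random.default_rng(seed)
    pool = [f"G{i + 1:06d}" for i in range(n_decoy_pool)]
    terms: dict[str, frozenset[str]] = {}

    planted_size = int(rng.integers(max(lo, planted_overlap), hi + 1))
    overlap_genes = [query[i] for i in rng.choice(len(query), size=planted_overlap, replace=False)]
    filler = [pool[i] for i in rng.choice(n_decoy_pool, size=planted_size - planted_overlap, replace=False)]
    terms["PLANTED"] = frozenset(overlap_genes + filler)

    for t in range(n_terms - 1):
        size = int(rng.integers(lo, hi + 1))
        genes = [pool[i] for i in rng.choice(n_decoy_pool, size=size, replace=False)]
        terms[f"DECOY_{t + 1:03d}"] = frozenset(genes)
    return GeneSetLibrary(terms, universe=universe)
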
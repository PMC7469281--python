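"""The packaged TNF-alpha/macrophage signaling model and scenario analyses.

The model captures, at Boolean resolution, how tumor-associated macrophage
secretome rescues breast-cancer cells from TNF-alpha blockade: macrophage
cytokines activate JAK-STAT and PI3K-AKT, both of which converge on IKK and
keep NFKB active even when the TNF receptor is silent.  NFKB drives the
Survival and Proliferation phenotype nodes and suppresses Apoptosis.

Two input nodes are clamped per scenario: ``Macrophage`` (macrophages
present/absent) and ``TNF`` (TNF-alpha available; clamping to 0 models
Etanercept, a soluble decoy receptor that neutralizes the ligand).  The
free subnetwork is acyclic, so every scenario has exactly one attractor,
a fixed point, and synchronous and asynchronous analyses agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .dynamics import (
    Attractor,
    Perturbation,
    Scheme,
    build_state_transition_graph,
    find_attractors,
    summarize_attractor,
)
from .network import BooleanNetwork, parse_rules

__all__ = [
    "PHENOTYPE_NODES",
    "INPUT_NODES",
    "ScenarioSpec",
    "ScenarioResult",
    "ModelContractError",
    "load_paper_model",
    "run_scenario",
    "perturbation_scan",
]

PHENOTYPE_NODES: tuple[str, ...] = ("Apoptosis", "Proliferation", "Survival")
INPUT_NODES: tuple[str, str] = ("Macrophage", "TNF")

_RULES_RESOURCE = "tnf_macrophage_rules.txt"


class ModelContractError(ValueError):
    """A network lacks a node the scenario machinery requires."""


def load_paper_model() -> BooleanNetwork:
    """Load the packaged TNF-alpha/macrophage rule file."""
    try:
        text = (
            resources.files("tnfboolnet.data").joinpath(_RULES_RESOURCE).read_text()
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:  # pragma: no cover
        raise RuntimeError(f"packaged rule file {_RULES_RESOURCE!r} unavailable") from exc
    return parse_rules(text)


@dataclass(frozen=True)
class ScenarioSpec:
    """Input clamps defining one simulated condition.

    ``tnf=0`` models Etanercept treatment (ligand neutralized);
    ``extra_clamps`` adds in-silico knockdowns (e.g. NFKB=0) and must not
    re-clamp the two inputs.
    """

    macrophage: int
    tnf: int
    extra_clamps: Perturbation = field(default_factory=Perturbation)

    def __post_init__(self):
        if self.macrophage not in (0, 1) or self.tnf not in (0, 1):
            raise ValueError("macrophage and tnf clamps must be 0 or 1")
        overlap = set(self.extra_clamps.clamps) & set(INPUT_NODES)
        if overlap:
            raise ValueError(
                "extra_clamps must not re-clamp input node(s): "
                + ", ".join(sorted(overlap))
            )

    def perturbation(self) -> Perturbation:
        clamps = {INPUT_NODES[0]: self.macrophage, INPUT_NODES[1]: self.tnf}
        clamps.update(self.extra_clamps.clamps)
        return Perturbation(clamps)


@dataclass
class ScenarioResult:
    attractors: list[Attractor]
    phenotype: dict[str, int | str]
    spec: ScenarioSpec
    n_states: int

    @property
    def is_unique_fixed_point(self) -> bool:
        return len(self.attractors) == 1 and self.attractors[0].kind == "fixed_point"


def _check_contract(net: BooleanNetwork, required: tuple[str, ...]) -> None:
    missing = [n for n in required if n not in net.rules]
    if missing:
        raise ModelContractError(
            "model lacks required node(s): " + ", ".join(missing)
        )


def run_scenario(
    net: BooleanNetwork,
    spec: ScenarioSpec,
    scheme: Scheme = "asynchronous",
    phenotype_nodes: tuple[str, ...] = PHENOTYPE_NODES,
) -> ScenarioResult:
    """Clamp the inputs, build the exhaustive STG over the free nodes, find
    terminal-SCC attractors and summarize the phenotype nodes."""
    _check_contract(net, INPUT_NODES + phenotype_nodes)
    pert = spec.perturbation()
    pert.validate_against(net)
    stg = build_state_transition_graph(net, pert, scheme=scheme)
    attractors = find_attractors(stg)
    if len(attractors) == 1:
        phenotype = summarize_attractor(attractors[0], phenotype_nodes)
    else:
        # Multiple attractors: a node reads out a value only when it agrees
        # across all of them, otherwise it is reported as oscillating.
        per_att = [summarize_attractor(a, phenotype_nodes) for a in attractors]
        phenotype = {
            n: per_att[0][n]
            if all(p[n] == per_att[0][n] for p in per_att)
            else "oscillating"
            for n in phenotype_nodes
        }
    return ScenarioResult(attractors, phenotype, spec, stg.n_states)


def perturbation_scan(
    net: BooleanNetwork,
    base: ScenarioSpec,
    candidates: list[str],
    scheme: Scheme = "asynchronous",
    phenotype_nodes: tuple[str, ...] = PHENOTYPE_NODES,
) -> list[dict]:
    """Single-node clamp scan around a base scenario.

    For every candidate node and each clamp value in {0, 1} the scenario is
    rerun with that one extra clamp.  Rows are sorted by (node, value).
    Input nodes are rejected: their levels are the scenario definition.
    """
    bad = [c for c in candidates if c in INPUT_NODES]
    if bad:
        raise ValueError(
            "candidates must not include input node(s) "
            + ", ".join(sorted(bad))
            + "; set them through the scenario instead"
        )
    _check_contract(net, tuple(candidates))
    rows: list[dict] = []
    for node in sorted(set(candidates)):
        for value in (0, 1):
            clamps = dict(base.extra_clamps.clamps)
            clamps[node] = value
            spec = ScenarioSpec(base.macrophage, base.tnf, Perturbation(clamps))
            result = run_scenario(net, spec, scheme=scheme, phenotype_nodes=phenotype_nodes)
            row = {"node": node, "clamp": value, "n_attractors": len(result.attractors)}
            row.update(result.phenotype)
            rows.append(row)
    return rows
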
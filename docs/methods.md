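# Methods

## Boolean network formalism

A network is a finite set of named nodes, each with a logical update rule
over node names built from NOT (`!`), AND (`&`), OR (`|`), parentheses and
the constants `0`/`1`, with precedence NOT > AND > OR. Rule files use the
`targets, factors` dialect (header line, then one `name, expression` line
per node); parsing and serialization round-trip exactly, and parse errors
name the offending line or symbol. Inputs are nodes whose rule is the
identity on themselves or a constant.

### Update schemes and the state-transition graph

Both classical schemes are implemented over the exhaustive state space:

- **synchronous** — every node updates jointly; each state has exactly one
  successor.
- **asynchronous (general)** — one edge per node whose single update
  changes the state; a stable state carries an explicit self-loop.

The self-loop convention makes every state's out-degree ≥ 1 and turns
fixed points into terminal SCCs of size 1, so a single SCC-based detector
covers both schemes. The general asynchronous graph contains every
possible interleaving of single-node updates; attractor analysis over it
is therefore independent of any particular update order, and random-order
trajectory sampling is deliberately not implemented (it can only explore a
subgraph of what the exhaustive analysis already covers).

### Attractors

Attractors are the terminal strongly-connected components of the STG
(`networkx.attracting_components`; independently cross-checked in the test
suite against a brute-force "every reachable state can reach back"
enumeration). Classification: size 1 → fixed point; size > 1 → cycle
(synchronous) or complex attractor (asynchronous). Output order is
deterministic: by (size, lexicographically smallest member state with
nodes in declaration order). Basin sizes are reported for the synchronous
scheme, where every state reaches exactly one attractor and basins
partition the state space (they must sum to 2^n). Asynchronous basins can
overlap, so the asynchronous report instead carries a **weak basin** —
the count of states that *can* reach the attractor.

### Clamping and capacity

A perturbation clamps nodes to constants, overriding their rules — this is
how treatment (TNF = 0 models ligand neutralization by Etanercept) and
knockdown (NFKB = 0) enter the model. Under clamps the STG is enumerated
over the clamp-consistent subspace (2^n_free full states with clamped bits
fixed), which is closed under both schemes; without clamps it is all 2^n
states. Exhaustive enumeration is capped at 22 free nodes (~4M states) —
comfortable headroom over the 13-node packaged model — and exceeding the
cap raises a capacity error rather than silently degrading.

## The packaged TNF-α/macrophage model

13 nodes; 2 inputs (`Macrophage`, `TNF`), 3 phenotype outputs
(`Apoptosis`, `Proliferation`, `Survival`):

```
MacrophageCytokines = Macrophage
TNFR  = TNF
JAK   = MacrophageCytokines        STAT3 = JAK
PI3K  = MacrophageCytokines | TNFR AKT   = PI3K
IKK   = TNFR | STAT3 | AKT
NFKB  = IKK
Proliferation = NFKB & (STAT3 | AKT | TNFR)
Survival      = NFKB
Apoptosis     = !NFKB
```

The wiring encodes the field's consensus crosstalk: macrophage-secreted
cytokines drive JAK-STAT3 and PI3K-AKT; persistently active STAT3 and AKT
each sustain IKK, so NFKB stays on without TNF receptor engagement. It is
the smallest literature-consistent rule set reproducing all four behavioral
requirements, verified by the test suite:

| Macrophage | TNF | extra clamp | Apoptosis | Proliferation | Survival |
|---|---|---|---|---|---|
| 0 | 0 | — | 1 | 0 | 0 |
| 1 | 0 | — | 0 | 1 | 1 |
| 1 | 0 | NFKB=0 | 1 | 0 | 0 |
| 0 | 1 | — | 0 | 1 | 1 (NFKB = 1) |

The free subnetwork (inputs clamped) is acyclic, so every scenario has a
unique fixed-point attractor and synchronous/asynchronous analyses agree —
both asserted in tests. JNK and p38, which TNF also engages, are omitted:
they have no phenotype consequence in this readout, and the rule file is
plain data a user can replace (`--model`). The model is behavior-faithful
at the phenotype level; no claim is made that intermediate nodes match any
particular published rule set line by line. The untested (Macrophage=1,
TNF=1) cell is computed like any other but carries no external claim.

## Secretome filtering and over-representation

Analytes with normalized intensity **strictly greater than 0.2** are kept
(the published cutoff wording is "greater than", so 0.2 itself is
excluded), sorted by descending intensity. The normalization producing the
0–1 array scale upstream of the cutoff is not specified by the source
data's description; the synthetic generator assumes a 0–1 scale, and real
tables must be normalized before use.

The enrichment statistic is the hypergeometric upper tail
P(X ≥ overlap) for X ~ Hypergeom(N, t, q) — identical to the one-sided
Fisher exact test (`scipy.stats.hypergeom.sf`, cross-checked in tests
against explicit pmf summation and `fisher_exact`). Multiplicity is
handled by Bonferroni over the m library terms, adjusted p = min(1, m·p),
significant at adjusted p < 0.05, with ties in ranking broken by raw p
then term name. Enrichr-style combined scores are intentionally not
implemented; the adjusted Fisher p is the reported statistic. GMT files
carry no universe, so universe size is an explicit parameter (default
20,000 ≈ the protein-coding genome; override per config) and is logged
with every run. Gene matching is case-insensitive exact string match
after trimming; no alias resolution.

## Synthetic data

All generators are pure functions of their arguments plus an integer seed
(numpy PCG64; no global state), giving byte-identical serialized outputs
across runs.

- **Random networks** (`make_random_network`): each node gets ≤ max_inputs
  uniformly chosen regulators combined as randomly negated literals joined
  by random AND/OR; with probability 0.05 the rule is a bare constant, so
  the family covers identity, negation and both constants. Used as oracle
  fixtures at n ≤ 8, where brute force over ≤ 256 states is exact.
- **Secretome tables** (`make_secretome`): defaults of 150 analytes with
  25 planted at intensity 0.9 and the rest uniform in [0, 0.15] emulate an
  antibody-array profile where a minority of cytokines is genuinely
  secreted; the planted set occupies fixed names (SYN0001…SYN0025) so the
  seed moves only the noise. A noise range reaching the cutoff is a config
  error — strict separation is the point of the fixture.
- **GMT libraries** (`make_library`): one planted term overlapping the
  query in exactly `planted_overlap` genes plus uniform decoy terms drawn
  from a synthetic-symbol pool (G000001…) disjoint from the query, so
  accidental real-gene matches are impossible. Defaults (100 terms, sizes
  20–40, universe 2,000, overlap 15 against a 20-gene query) put the
  planted term's raw p around 1e-25 — decisively recoverable, as the
  recovery test demonstrates across 200 seeds.

What the synthetic data does **not** emulate: correlated analyte noise,
batch effects, array saturation, overlapping decoy terms or gene-alias
ambiguity. Passing tests demonstrate the statistics and the machinery, not
robustness to those real-data complications.

## Pipeline and numerical choices

The pipeline config is strict-schema YAML (unknown keys are errors, so a
misspelled threshold cannot silently default). Stages are independently
skippable; every run writes a markdown summary naming each artifact, and
identical inputs give byte-identical outputs. Logs go to stderr, results
to files.

Tolerances: the attractor machinery is exact integer computation with no
tolerances. Hypergeometric p-values are validated against rational-number
pmf summation at relative error 1e-10 or better. Degenerate inputs are
errors, not silent defaults: empty queries, empty GMT terms, negative or
non-finite intensities, overlap outside [0, min(q, t)], re-clamping a
scenario input, candidates that are inputs in a perturbation scan.

Problem sizes in the test suite — random-network oracles at n ≤ 8 with
100–125 seeds, 1,000 hypergeometric configurations, 200 library
replicates — are chosen so brute-force verification stays exact while the
full suite runs in well under a minute on one core.

## Known limitations

- Exhaustive enumeration only; no symbolic (BDD/SAT) attractor detection,
  so networks beyond ~22 free nodes are out of reach by design.
- Boolean resolution cannot express dose dependence (the in-vitro
  1 vs 10 μg/ml distinction has no counterpart here).
- The macrophage is a single input node, not a modeled cell; feedback from
  tumor to macrophage is outside the model's scope.
- Enrichment term ranks are comparable to Enrichr's only qualitatively,
  since Enrichr ranks by a different combined score.
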
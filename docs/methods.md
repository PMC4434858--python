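# Methods

## Model and assumptions

A metabolic network is a directed graph over compound nodes with
substrate→product edges.  The representation is compound-level and
unweighted: reactions, stoichiometry, cofactors, and reversibility
annotations are all collapsed into plain directed adjacency.  The
central producibility assumption is reachability — a compound is
synthesizable from a set of available compounds iff it is reachable
from that set by directed paths.  This deliberately ignores the
conjunctive nature of real reactions (a reaction needs *all* of its
substrates); reachability gives an optimistic, purely topological
notion of producibility that is cheap, deterministic, and has proved
informative at genome scale.  Nothing environment-specific enters the
computation: scores measure *potential* for interaction, and whether
that potential is realized depends on nutrient availability in the
actual habitat.

## Seed detection

The seed set is computed from the SCC condensation.  Strongly
connected components are found with an iterative Tarjan traversal
(written in-package so that the graph-library implementation remains
an independent cross-check in the tests); the condensation contracts
each SCC to a node and drops within-component edges, yielding a DAG.
Source components — external in-degree zero — are exactly the parts
of the network no internal reaction can produce, so each one becomes a
seed group.  Consequences worth spelling out:

* a node whose only in-edge is a self-loop is a singleton source SCC
  and hence a seed (a self-loop cannot bootstrap its own production);
* isolated nodes (representable only in the adjacency dialect) are
  singleton seeds;
* every minimal set of exogenous compounds that renders the whole
  network producible consists of exactly one member per seed group,
  which is the sense in which all alternative seed-set solutions are
  accounted for.  The exhaustive oracle in `fixtures` verifies this
  transversal correspondence directly on small graphs.

Each group carries confidence `1/|group|`, the weight of any single
member being "the" seed.  `min_confidence` (default 0, range [0, 1])
filters groups below the cutoff.  Filtered groups are removed from the
seed compounds and from both the numerator and denominator of every
downstream score — a threshold redefines the species' nutritional
profile, not just the arithmetic — but stay in the `SeedSet` record
for reporting.  The default of 0 keeps all groups, which is what makes
the packaged toy example's arithmetic the out-of-box behaviour.
Confidence comparisons are exact (`Fraction` against the given
float), so a group of three passes a threshold of `1/3`.

## Cooperation metrics

Both metrics score a *consumer* (whose retained seed groups form the
denominator) against a *provider*.  A group is satisfied by a single
witness compound; no partial credit is given.  BSS admits any provider
node as a witness — including provider seeds, since the provider
demonstrably obtains those compounds from its environment.  MCI
restricts witnesses to provider non-seed nodes, i.e. compounds the
provider can synthesize and hence potentially share.  This asymmetry
is the one semantic trap in the pair: in the toy example the group
`F/G/H` is *supported* via `F` (BSS) but not *complemented* (MCI),
because `F` is a seed of both species.

Scores are exact rationals `n_satisfied / n_groups`; reports format
them to 4 decimal places, and the JSON export carries numerator and
denominator so nothing is lost to rounding.  A consumer whose
threshold filtered every group has no denominator; scoring it raises
`UndefinedScoreError` rather than returning NaN.  No significance
cutoff separating "cooperation" from "no cooperation" is imposed; the
scores are meant for comparison across pairs under the same settings.

## File dialects and determinism

Edge lists accept tab, comma, or whitespace delimiters (auto-detected
from the first data line in that order); `#`-comments and blank lines
are skipped; columns beyond the first two are ignored with a warning
so weighted exports still load.  Adjacency matrices are tab-delimited
with or without a corner label over the row-label column — both header
variants are accepted since files in the wild come both ways.
Compound matching is exact and case-sensitive (KEGG IDs are
case-sensitive by convention); `case_fold` uppercases everything for
sloppier sources.  The edge-list dialect cannot express isolated
compounds: writing an edge-free network raises, and isolated nodes
alongside edges are dropped from edge-list output with a warning.

All outputs are deterministic: components and groups are ordered by
their lexicographically smallest member, edges are written sorted, and
matrix rows/columns follow the input (CLI: sorted filename) order.
Running the same command twice produces byte-identical files.

## Synthetic data

`random_network(n, p, seed)` draws Erdős–Rényi-style directed graphs
without self-loops, labelled `C0001…`.  The suite uses small, dense
regimes (n between 3 and 12, p between 0.1 and 0.5) because they
produce rich SCC structure — cycles, multi-node source components,
isolated nodes — while staying inside the exhaustive oracle's 12-node
enumeration bound; the 50-network collection used for the all-vs-all
timing check uses n = 30, p = 0.08.  What the generator does *not*
emulate: the scale-free degree distributions, currency-metabolite
hubs, and thousands of nodes of genome-scale networks.  Passing tests
therefore demonstrate algorithmic correctness on arbitrary digraph
topology, not biological realism of the inputs; published large-scale
analyses (hundreds of species against model hosts, >150 gut species)
require externally reconstructed genome-scale networks and are out of
scope here.

## Verification strategy

Three independent oracles back the implementation: a transitive-
closure SCC oracle and the graph library's SCC routine against the
Tarjan traversal; an exhaustive minimal-feasible-subset enumeration
(bitmask reachability over all 2^n seed candidates, minimality by
inclusion since feasibility is monotone) against the condensation
seed finder; and a direct per-group rescan against the BSS/MCI
scoring path.  The toy example is additionally tested over five
alternative edge sets satisfying the same structural constraints, to
pin the scores to the constraints rather than to one drawing.

## Known limitations

* Reachability ignores reaction conjunction, so seed sets are lower
  bounds on true nutritional requirements and scores are optimistic.
* Node identity is string equality; networks built with different
  compound namespaces must be reconciled before scoring.
* The adjacency sniffing heuristic can misclassify an edge list whose
  node labels are all numeric; pass an explicit format in that case.
* No statistics are attached to scores (no null model, no p-values);
  downstream comparative analysis is the intended use.
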
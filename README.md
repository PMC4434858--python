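# netcooperate

Reverse-ecology scoring of cooperative potential between metabolic
networks.

Microbes and their hosts exchange metabolites, and the potential for
such exchange is visible in the *topology* of their metabolic networks
alone — no flux model, stoichiometry, or growth medium required.  This
package is for microbiologists and microbiome researchers who have
compound-level metabolic networks (e.g. built from KEGG annotations)
and want to ask: *can species B feed species A?*

## The method

Each network is a directed graph whose nodes are compounds and whose
edges run from substrate to product.  Three quantities are computed:

**Seed set.**  The seed set of a network is the minimal set of
compounds that must be acquired exogenously so that every other
compound is reachable (synthesizable).  Topologically these are the
source components of the strongly-connected-component (SCC)
condensation: contract every SCC to a node and keep the components
with no incoming edge.  Mutually reachable compounds are
interchangeable, so each source SCC forms a **seed group** — any one
member suffices as the exogenous seed — with confidence
`1 / |group|`.  Groups below an optional confidence threshold can be
filtered out.

**Biosynthetic Support Score (BSS).**  For a *consumer* network with
seed groups `G_1 … G_k` (after thresholding) and a *provider* network
with node set `V_p`,

    BSS = |{ i : G_i ∩ V_p ≠ ∅ }| / k

— the fraction of consumer seed groups with at least one member found
*anywhere* in the provider.  It quantifies a host's capacity to meet a
parasite's or commensal's nutritional requirements.  Note that a
provider *seed* still counts as support: the provider imports that
compound from the environment, and the consumer can tap the same pool.

**Metabolic Complementarity Index (MCI).**  With `S_p` the provider's
own seed compounds,

    MCI = |{ i : G_i ∩ (V_p \ S_p) ≠ ∅ }| / k

— the fraction of consumer seed groups with a member the provider can
actually *synthesize* (present in the provider but not among its
seeds).  It quantifies the potential for syntrophy between two
microbes.  Both scores lie in [0, 1] and MCI ≤ BSS always; neither
carries a built-in cooperation/no-cooperation cutoff — compare scores
across pairs in the same setting.

## Worked example

The packaged toy pair is a parasite ("blue") living off a host
("red").  Blue has edges `A→B, B→C, F→G, G→H, H→F, F→D`; red has
`W→A, A→Z, F→Y`.

```python
from netcooperate import (figure1_networks, find_seed_set,
                          pair_report, report_table)

pair = figure1_networks()
blue_seeds = find_seed_set(pair.consumer)
print([g.sorted_compounds for g in blue_seeds.groups])
# [('A',), ('F', 'G', 'H')]

print(report_table(pair_report(pair.consumer, pair.provider)).to_string(index=False))
# metric consumer provider  score  n_groups  n_satisfied
#    BSS     blue      red 1.0000         2            2
#    BSS      red     blue 0.5000         2            1
#    MCI     blue      red 0.5000         2            1
#    MCI      red     blue 0.0000         2            0
```

Blue needs two seed groups: compound `A`, and any one of the
interchangeable cycle `F/G/H`.  The red host contains `A` and `F`, so
it supports both groups — BSS of red on blue is `2/2 = 1.0`, with
witnesses `A` and `F`.  But `F` is a seed of red too (red cannot make
it), so only the group `{A}` is truly complemented — MCI of red on
blue is `1/2 = 0.5`, with witness `A`.

The same run from the shell, using the packaged files:

```sh
$ netcooperate pair src/netcooperate/data/figure1_blue.tsv \
                    src/netcooperate/data/figure1_red.tsv
metric  consumer        provider        score   n_groups        n_satisfied
BSS     figure1_blue    figure1_red     1.0000  2       2
BSS     figure1_red     figure1_blue    0.5000  2       1
MCI     figure1_blue    figure1_red     0.5000  2       1
MCI     figure1_red     figure1_blue    0.0000  2       0
```

`netcooperate seeds NET...` dumps per-network seed tables,
`netcooperate matrix DIR` scores a directory all-vs-all (rows are
consumers), and `--details`/`--json` emit witness tables and a JSON
report with exact numerators and denominators.  Input files may be
tab-, comma-, or space-delimited edge lists or tab-delimited adjacency
matrices; the format is sniffed automatically and can be forced with
`--format`.

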
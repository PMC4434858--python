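"""Seed-set detection from metabolic network topology.

The seed set of a metabolic network is the minimal collection of
compounds that must be acquired from the environment so that every
other compound in the network can be synthesized, i.e. is reachable by
directed paths.  Topologically these are the *source* components of the
strongly-connected-component (SCC) condensation: contract every SCC to
a single node, and the components with no incoming edge from outside
themselves are exactly the parts of the network that nothing internal
can produce.

Because mutually reachable compounds can stand in for one another,
every source component forms a *seed group*: any single member of the
group can serve as the exogenously acquired seed for the whole group,
so the minimal seed sets of the network are exactly the transversals
that pick one compound per group.  Each group carries a confidence
weight of ``1 / |group|`` reflecting this ambiguity, and groups can be
filtered with a minimum-confidence threshold.

The SCC routine is an iterative Tarjan traversal written here so that
the graph-library implementation can serve as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .network_io import MetabolicNetwork

__all__ = [
    "SeedGroup",
    "SeedSet",
    "strongly_connected_components",
    "condensation",
    "find_seed_set",
    "is_seed",
    "seed_table",
]


@dataclass(frozen=True)
class SeedGroup:
    """One source SCC: a set of interchangeable seed compounds.

    Any single member can serve as the exogenous seed for the group, so
    the confidence that a particular member is *the* seed is
    ``1 / |compounds|``.
    """

    compounds: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", frozenset(self.compounds))
        if not self.compounds:
            raise ValueError("a seed group cannot be empty")

    @property
    def confidence(self) -> Fraction:
        return Fraction(1, len(self.compounds))

    @property
    def sorted_compounds(self) -> tuple[str, ...]:
        return tuple(sorted(self.compounds))

    def __iter__(self):
        return iter(self.sorted_compounds)

    def __len__(self) -> int:
        return len(self.compounds)


@dataclass(frozen=True)
class SeedSet:
    """All seed groups of one network.

    ``groups`` holds the groups retained at ``threshold_applied``;
    ``filtered_groups`` records groups whose confidence fell below the
    threshold.  Filtered groups are excluded from ``seed_compounds``
    and from every downstream score — a threshold redefines the
    nutritional profile, not merely the bookkeeping.
    """

    network_name: str
    groups: tuple[SeedGroup, ...]
    filtered_groups: tuple[SeedGroup, ...] = ()
    threshold_applied: float = 0.0

    @property
    def seed_compounds(self) -> frozenset[str]:
        return frozenset(c for g in self.groups for c in g.compounds)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)


def _sorted_components(components: Iterable[frozenset[str]]) -> list[frozenset[str]]:
    return sorted(components, key=lambda c: min(c))


def strongly_connected_components(net: MetabolicNetwork) -> list[frozenset[str]]:
    """Partition the compound set into SCCs (iterative Tarjan).

    Two compounds share a component iff each is reachable from the
    other.  Components are returned sorted by their lexicographically
    smallest member, so output order is deterministic.
    """
    adj = net.successors()
    index: dict[str, int] = {}
    lowlink: dict[str, int] = {}
    on_stack: set[str] = set()
    stack: list[str] = []
    components: list[frozenset[str]] = []
    counter = 0

    for root in sorted(net.nodes):
        if root in index:
            continue
        # Explicit DFS stack of (node, iterator position) frames.
        work: list[tuple[str, int]] = [(root, 0)]
        while work:
            node, child_i = work[-1]
            if child_i == 0:
                index[node] = lowlink[node] = counter
                counter += 1
                stack.append(node)
                on_stack.add(node)
            advanced = False
            children = adj[node]
            while child_i < len(children):
                child = children[child_i]
                child_i += 1
                if child not in index:
                    work[-1] = (node, child_i)
                    work.append((child, 0))
                    advanced = True
                    break
                if child in on_stack:
                    lowlink[node] = min(lowlink[node], index[child])
            if advanced:
                continue
            work.pop()
            if lowlink[node] == index[node]:
                comp = []
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.append(w)
                    if w == node:
                        break
                components.append(frozenset(comp))
            if work:
                parent = work[-1][0]
                lowlink[parent] = min(lowlink[parent], lowlink[node])
    return _sorted_components(components)


def condensation(
    net: MetabolicNetwork,
    components: Sequence[frozenset[str]] | None = None,
) -> tuple[list[frozenset[str]], set[tuple[int, int]]]:
    """Contract each SCC to a node and return ``(components, dag_edges)``.

    Edges within a component (including node self-loops) are dropped;
    the result is acyclic.  Edge indices refer to the returned
    component list, which is sorted by smallest member.
    """
    if components is None:
        components = strongly_connected_components(net)
    else:
        components = _sorted_components(components)
    comp_of = {node: i for i, comp in enumerate(components) for node in comp}
    dag_edges = {
        (comp_of[u], comp_of[v]) for u, v in net.edges if comp_of[u] != comp_of[v]
    }
    return list(components), dag_edges


def find_seed_set(net: MetabolicNetwork, min_confidence: float = 0.0) -> SeedSet:
    """Detect the seed set of a network.

    One :class:`SeedGroup` is produced per source component of the SCC
    condensation (external in-degree zero).  Groups with confidence
    below ``min_confidence`` are moved to ``filtered_groups``.  At the
    default threshold of 0 every node of the network is reachable from
    the seed compounds, and remains reachable under any choice of one
    representative per group.
    """
    if not isinstance(net, MetabolicNetwork):
        raise TypeError("find_seed_set expects a MetabolicNetwork")
    if not (0.0 <= min_confidence <= 1.0):
        raise ValueError(f"min_confidence must be in [0, 1], got {min_confidence}")
    components, dag_edges = condensation(net)
    has_incoming = {j for _, j in dag_edges}
    sources = [comp for i, comp in enumerate(components) if i not in has_incoming]

    retained: list[SeedGroup] = []
    filtered: list[SeedGroup] = []
    for comp in sources:
        group = SeedGroup(compounds=comp)
        # Fraction/float comparison is exact, so 1/3 passes a threshold of
        # float(1/3) (which rounds just below the true ratio).
        if group.confidence >= min_confidence:
            retained.append(group)
        else:
            filtered.append(group)
    return SeedSet(
        network_name=net.name,
        groups=tuple(retained),
        filtered_groups=tuple(filtered),
        threshold_applied=float(min_confidence),
    )


def is_seed(seed_set: SeedSet, compound: str) -> bool:
    """True iff ``compound`` belongs to the retained seed compounds.

    Unknown labels simply return False.
    """
    return compound in seed_set.seed_compounds


def seed_table(seed_set: SeedSet, include_filtered: bool = False) -> pd.DataFrame:
    """One row per seed compound: (group index, compound, confidence).

    Group indices are 1-based in the deterministic group order;
    filtered groups, when included, are flagged in a ``retained``
    column.
    """
    rows = []
    for idx, group in enumerate(seed_set.groups, start=1):
        for compound in group.sorted_compounds:
            rows.append((idx, compound, float(group.confidence), True))
    offset = len(seed_set.groups)
    if include_filtered:
        for idx, group in enumerate(seed_set.filtered_groups, start=offset + 1):
            for compound in group.sorted_compounds:
                rows.append((idx, compound, float(group.confidence), False))
    df = pd.DataFrame(rows, columns=["group", "compound", "confidence", "retained"])
    if not include_filtered:
        df = df.drop(columns=["retained"])
    return df
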
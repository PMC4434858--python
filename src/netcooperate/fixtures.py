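"""Packaged toy networks, a seeded random-network generator, and the
exhaustive seed-set oracle used by the property tests.

The canonical toy pair models a parasite (the "blue" bacterium) living
off a host (the "red" eukaryote).  Blue has two seed groups — the lone
compound ``A`` and the interchangeable cycle ``F/G/H`` — and the red
network contains ``A`` as a synthesized product and ``F`` as one of its
own seeds, with ``G`` and ``H`` absent.  Under those constraints the
expected scores are fixed: the host supports both blue seed groups
(BSS = 1.0, witnesses ``A`` and ``F``) but can only complement ``A``,
because ``F`` is a seed in both species (MCI = 0.5, witness ``A``).
Any edge set satisfying the constraints yields the same numbers; the
edge sets below are the packaged canon, also shipped as edge-list and
adjacency-matrix files under ``netcooperate/data`` so that both parsers
are exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product
from pathlib import Path

import numpy as np

from .network_io import MetabolicNetwork
from .seed_finder import find_seed_set

__all__ = [
    "FixturePair",
    "figure1_networks",
    "fixture_file",
    "random_network",
    "brute_force_seed_oracle",
]

BLUE_EDGES = (("A", "B"), ("B", "C"), ("F", "G"), ("G", "H"), ("H", "F"), ("F", "D"))
RED_EDGES = (("W", "A"), ("A", "Z"), ("F", "Y"))


@dataclass(frozen=True)
class FixturePair:
    """The toy consumer/provider pair with its frozen expectations."""

    consumer: MetabolicNetwork  # blue: the supported parasite
    provider: MetabolicNetwork  # red: the supporting host
    expected: dict


def _make(name: str, edges) -> MetabolicNetwork:
    nodes = frozenset(u for e in edges for u in e)
    return MetabolicNetwork(name=name, nodes=nodes, edges=frozenset(edges))


def figure1_networks(validate: bool = True) -> FixturePair:
    """Build the canonical toy pair and (by default) re-verify its
    structural constraints with the seed finder.

    Returns a :class:`FixturePair` whose ``expected`` mapping freezes
    the seed-group structure and both forward scores.
    """
    blue = _make("blue", BLUE_EDGES)
    red = _make("red", RED_EDGES)
    expected = {
        "blue_seed_groups": frozenset({frozenset({"A"}), frozenset({"F", "G", "H"})}),
        "bss": 1.0,
        "mci": 0.5,
        "bss_witnesses": ("A", "F"),
        "mci_witnesses": ("A",),
    }
    if validate:
        blue_groups = frozenset(g.compounds for g in find_seed_set(blue).groups)
        if blue_groups != expected["blue_seed_groups"]:
            raise RuntimeError(f"fixture self-check failed: blue seed groups {blue_groups}")
        red_seeds = find_seed_set(red).seed_compounds
        ok = (
            "A" in red.nodes
            and "A" not in red_seeds
            and "F" in red.nodes
            and "F" in red_seeds
            and "G" not in red.nodes
            and "H" not in red.nodes
        )
        if not ok:
            raise RuntimeError("fixture self-check failed: red-network constraints violated")
    return FixturePair(consumer=blue, provider=red, expected=expected)


def fixture_file(filename: str) -> Path:
    """Path to a packaged fixture data file (e.g. ``figure1_blue.tsv``)."""
    path = resources.files("netcooperate").joinpath("data", filename)
    return Path(str(path))


def random_network(n_nodes: int, edge_prob: float, rng_seed: int) -> MetabolicNetwork:
    """Erdős–Rényi-style directed graph, no self-loops, deterministic.

    Node labels follow the ``C0001`` … convention.  A draw with zero
    edges is legal and yields a network of isolated compounds.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be ≥ 2")
    if not (0.0 < edge_prob < 1.0):
        raise ValueError("edge_prob must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    labels = [f"C{i:04d}" for i in range(1, n_nodes + 1)]
    draws = rng.random((n_nodes, n_nodes))
    edges = frozenset(
        (labels[i], labels[j])
        for i in range(n_nodes)
        for j in range(n_nodes)
        if i != j and draws[i, j] < edge_prob
    )
    return MetabolicNetwork(
        name=f"random_n{n_nodes}_s{rng_seed}", nodes=frozenset(labels), edges=edges
    )


def brute_force_seed_oracle(net: MetabolicNetwork) -> frozenset[frozenset[str]]:
    """Seed groups by exhaustive enumeration of minimal feasible subsets.

    A subset of compounds is *feasible* when every compound of the
    network is reachable from it; feasibility is monotone under subset
    inclusion, so a feasible set is inclusion-minimal iff dropping any
    single member breaks feasibility.  The minimal feasible sets of a
    network are exactly the transversals picking one compound per seed
    group; this routine enumerates them, reconstructs the group
    structure, and verifies the transversal correspondence.  Intended
    purely as a test oracle — it refuses networks above 12 nodes.
    """
    nodes = sorted(net.nodes)
    n = len(nodes)
    if n > 12:
        raise ValueError("oracle limited to networks with at most 12 nodes")
    idx = {node: i for i, node in enumerate(nodes)}
    full = (1 << n) - 1

    # Per-node reachability closure as bitmasks (includes the node itself).
    succ = [0] * n
    for u, v in net.edges:
        succ[idx[u]] |= 1 << idx[v]
    closure = []
    for start in range(n):
        seen = 1 << start
        frontier = [start]
        while frontier:
            node = frontier.pop()
            rest = succ[node] & ~seen
            while rest:
                low = rest & -rest
                child = low.bit_length() - 1
                seen |= low
                rest &= rest - 1
                frontier.append(child)
        closure.append(seen)

    def reach(mask: int) -> int:
        out = 0
        rest = mask
        while rest:
            low = rest & -rest
            out |= closure[low.bit_length() - 1]
            rest &= rest - 1
        return out

    feasible = [mask for mask in range(1, full + 1) if reach(mask) == full]
    feasible_set = set(feasible)
    minimal = []
    for mask in feasible:
        rest = mask
        is_min = True
        while rest:
            low = rest & -rest
            if (mask & ~low) in feasible_set:
                is_min = False
                break
            rest &= rest - 1
        if is_min:
            minimal.append(mask)
    if not minimal:
        raise RuntimeError("no feasible seed set found (impossible for a finite digraph)")

    # Recover groups from one minimal set: the alternatives for member x
    # are exactly the y for which swapping x -> y stays minimal.
    base = min(minimal)
    minimal_set = set(minimal)
    groups = []
    rest = base
    while rest:
        low = rest & -rest
        rest &= rest - 1
        members = {
            nodes[j]
            for j in range(n)
            if ((base & ~low) | (1 << j)) in minimal_set
        }
        groups.append(frozenset(members))

    # Cross-check: the minimal family must be exactly the set of
    # transversals (one compound per group).
    union = set().union(*groups)
    if sum(len(g) for g in groups) != len(union):
        raise RuntimeError("reconstructed seed groups are not disjoint")
    transversals = {
        sum(1 << idx[c] for c in choice)
        for choice in product(*(sorted(g) for g in groups))
    }
    if transversals != minimal_set:
        raise RuntimeError("minimal feasible sets are not the transversals of a partition")
    return frozenset(groups)
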
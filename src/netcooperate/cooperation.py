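"""Cooperation scoring between pairs of metabolic networks.

Two directed metrics compare the nutritional requirements of a
*consumer* network (the species whose seed groups form the
denominator) against the content of a *provider* network:

* **Biosynthetic Support Score (BSS)** — the fraction of consumer seed
  groups with at least one member compound present *anywhere* in the
  provider network.  Presence is enough: a provider seed node counts as
  support, since the provider itself obtains that compound from its
  environment and the consumer can tap the same pool.  BSS quantifies
  a host's capacity to meet a parasite's or commensal's requirements.
* **Metabolic Complementarity Index (MCI)** — the fraction of consumer
  seed groups with at least one member compound present in the
  provider network but *not* in the provider's own seed set, i.e. a
  compound the provider can actually synthesize.  MCI quantifies the
  potential for syntrophy (cross-feeding) between two microbes.

Both scores lie in [0, 1]; a group is satisfied by a single witness
(no partial credit), and scores are kept as exact rationals
``n_satisfied / n_groups`` so that reports are bit-stable.  Because any
complementing witness is also a supporting witness, MCI ≤ BSS for every
directed pair.  Neither score imposes a cooperation/no-cooperation
cutoff; they are meant to be compared across pairs in the same setting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConsistencyError, UndefinedScoreError
from .network_io import MetabolicNetwork
from .seed_finder import SeedGroup, SeedSet, find_seed_set

__all__ = [
    "CooperationResult",
    "PairwiseReport",
    "biosynthetic_support_score",
    "metabolic_complementarity_index",
    "pair_report",
    "matrix_report",
    "list_supported_compounds",
    "report_table",
]

BSS = "BSS"
MCI = "MCI"


@dataclass(frozen=True)
class CooperationResult:
    """One directed score plus the groups and witnesses behind it.

    ``satisfied_groups`` holds ``(group_index, group, witnesses)``
    triples and ``unsatisfied_groups`` holds ``(group_index, group)``
    pairs; indices are 1-based positions in the consumer seed-set group
    order, so detail tables line up with seed tables.
    """

    metric: str
    consumer: str
    provider: str
    satisfied_groups: tuple[tuple[int, SeedGroup, tuple[str, ...]], ...]
    unsatisfied_groups: tuple[tuple[int, SeedGroup], ...]

    @property
    def n_groups(self) -> int:
        return len(self.satisfied_groups) + len(self.unsatisfied_groups)

    @property
    def n_satisfied(self) -> int:
        return len(self.satisfied_groups)

    @property
    def score(self) -> Fraction:
        return Fraction(self.n_satisfied, self.n_groups)

    @property
    def witnesses(self) -> tuple[str, ...]:
        """All witness compounds across satisfied groups, sorted, deduplicated."""
        return tuple(sorted({w for _, _, ws in self.satisfied_groups for w in ws}))

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "consumer": self.consumer,
            "provider": self.provider,
            "score": float(self.score),
            "numerator": self.n_satisfied,
            "denominator": self.n_groups,
            "satisfied_groups": [
                {"group": i, "compounds": list(g.sorted_compounds), "witnesses": list(ws)}
                for i, g, ws in self.satisfied_groups
            ],
            "unsatisfied_groups": [
                {"group": i, "compounds": list(g.sorted_compounds)}
                for i, g in self.unsatisfied_groups
            ],
        }


def _score_groups(
    metric: str,
    consumer_seeds: SeedSet,
    provider: MetabolicNetwork,
    eligible: frozenset[str],
) -> CooperationResult:
    if consumer_seeds.n_groups == 0:
        raise UndefinedScoreError(
            f"{metric} of {provider.name!r} toward {consumer_seeds.network_name!r} is "
            "undefined: the consumer retains no seed groups (threshold "
            f"{consumer_seeds.threshold_applied} filtered all of them)"
        )
    satisfied = []
    unsatisfied = []
    for idx, group in enumerate(consumer_seeds.groups, start=1):
        witnesses = tuple(sorted(group.compounds & eligible))
        if witnesses:
            satisfied.append((idx, group, witnesses))
        else:
            unsatisfied.append((idx, group))
    return CooperationResult(
        metric=metric,
        consumer=consumer_seeds.network_name,
        provider=provider.name,
        satisfied_groups=tuple(satisfied),
        unsatisfied_groups=tuple(unsatisfied),
    )


def biosynthetic_support_score(
    consumer_seeds: SeedSet, provider: MetabolicNetwork
) -> CooperationResult:
    """BSS of ``provider`` supporting the consumer behind ``consumer_seeds``.

    A consumer seed group is satisfied when at least one of its
    compounds is a node of the provider network — seed or not.
    """
    return _score_groups(BSS, consumer_seeds, provider, provider.nodes)


def metabolic_complementarity_index(
    consumer_seeds: SeedSet,
    provider: MetabolicNetwork,
    provider_seeds: SeedSet | None = None,
) -> CooperationResult:
    """MCI of ``provider`` complementing the consumer behind ``consumer_seeds``.

    A consumer seed group is satisfied when at least one of its
    compounds is a provider node that is *not* itself a provider seed.
    ``provider_seeds`` must have been computed from ``provider`` (it is
    recomputed at threshold 0 when omitted).
    """
    if provider_seeds is None:
        provider_seeds = find_seed_set(provider)
    if provider_seeds.network_name != provider.name:
        raise ConsistencyError(
            f"provider seed set was computed for {provider_seeds.network_name!r}, "
            f"not for provider network {provider.name!r}"
        )
    eligible = provider.nodes - provider_seeds.seed_compounds
    return _score_groups(MCI, consumer_seeds, provider, eligible)


@dataclass(frozen=True)
class PairwiseReport:
    """Both metrics for every ordered pair of a network collection.

    ``networks`` fixes row/column order (row = consumer, column =
    provider); ``results`` maps ``(metric, consumer, provider)`` to the
    full :class:`CooperationResult`.  At threshold 0 the BSS table
    diagonal is 1 (a network trivially contains its own seeds) and the
    MCI diagonal is 0 (its own seeds are never non-seeds).
    """

    networks: tuple[str, ...]
    results: Mapping[tuple[str, str, str], CooperationResult]

    def get(self, metric: str, consumer: str, provider: str) -> CooperationResult:
        return self.results[(metric, consumer, provider)]

    def _table(self, metric: str) -> pd.DataFrame:
        names = list(self.networks)
        data = [
            [float(self.results[(metric, c, p)].score) for p in names] for c in names
        ]
        return pd.DataFrame(data, index=names, columns=names)

    @property
    def bss_table(self) -> pd.DataFrame:
        return self._table(BSS)

    @property
    def mci_table(self) -> pd.DataFrame:
        return self._table(MCI)

    @property
    def directed_results(self) -> tuple[CooperationResult, ...]:
        """Cross-direction results only (diagonal omitted), deterministic order."""
        out = []
        for metric in (BSS, MCI):
            for c in self.networks:
                for p in self.networks:
                    if c != p:
                        out.append(self.results[(metric, c, p)])
        return tuple(out)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "networks": list(self.networks),
            "results": [r.to_dict() for r in self.directed_results],
        }
        return json.dumps(payload, indent=indent)


def _build_report(
    nets: Sequence[MetabolicNetwork],
    thresholds: Mapping[str, float],
) -> PairwiseReport:
    names = [n.name for n in nets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate network names: {sorted(names)}")
    seeds = {n.name: find_seed_set(n, thresholds.get(n.name, 0.0)) for n in nets}
    results: dict[tuple[str, str, str], CooperationResult] = {}
    for consumer in nets:
        for provider in nets:
            key = (consumer.name, provider.name)
            results[(BSS, *key)] = biosynthetic_support_score(
                seeds[consumer.name], provider
            )
            results[(MCI, *key)] = metabolic_complementarity_index(
                seeds[consumer.name], provider, seeds[provider.name]
            )
    return PairwiseReport(networks=tuple(names), results=results)


def _normalize_thresholds(
    nets: Sequence[MetabolicNetwork],
    thresholds: float | Mapping[str, float] | None,
) -> Mapping[str, float]:
    if thresholds is None:
        return {}
    if isinstance(thresholds, Mapping):
        return dict(thresholds)
    return {n.name: float(thresholds) for n in nets}


def pair_report(
    net_a: MetabolicNetwork,
    net_b: MetabolicNetwork,
    min_confidence_a: float = 0.0,
    min_confidence_b: float = 0.0,
) -> PairwiseReport:
    """Score one pair in both directions with both metrics.

    Each seed set is computed exactly once; the report carries the four
    cross-direction results (plus the trivial self-direction entries
    that complete the 2×2 tables).
    """
    if net_a.name == net_b.name:
        raise ValueError(
            f"the two networks must have distinct names (both are {net_a.name!r})"
        )
    thresholds = {net_a.name: min_confidence_a, net_b.name: min_confidence_b}
    return _build_report([net_a, net_b], thresholds)


def matrix_report(
    nets: Sequence[MetabolicNetwork],
    thresholds: float | Mapping[str, float] | None = None,
) -> PairwiseReport:
    """All-vs-all scoring for a collection of ≥2 uniquely named networks.

    Every seed set is computed once; tables have consumers as rows and
    providers as columns, in the order the networks were given.
    ``thresholds`` is a single cutoff for all networks or a mapping
    from network name to cutoff.
    """
    if len(nets) < 2:
        raise ValueError("matrix_report needs at least 2 networks")
    return _build_report(nets, _normalize_thresholds(nets, thresholds))


def list_supported_compounds(result: CooperationResult) -> pd.DataFrame:
    """Witness detail: one (group index, witness compound) row per witness.

    Rows are ordered by group index then compound, so output is
    deterministic.  A zero-score result yields an empty table.
    """
    rows = [
        (idx, witness)
        for idx, _group, witnesses in result.satisfied_groups
        for witness in witnesses
    ]
    return pd.DataFrame(rows, columns=["group", "compound"])


def report_table(report: PairwiseReport, include_self: bool = False) -> pd.DataFrame:
    """Long-format summary: metric, consumer, provider, score, counts."""
    rows = []
    for metric in (BSS, MCI):
        for c in report.networks:
            for p in report.networks:
                if c == p and not include_self:
                    continue
                r = report.results[(metric, c, p)]
                rows.append(
                    (metric, c, p, f"{float(r.score):.4f}", r.n_groups, r.n_satisfied)
                )
    return pd.DataFrame(
        rows, columns=["metric", "consumer", "provider", "score", "n_groups", "n_satisfied"]
    )
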
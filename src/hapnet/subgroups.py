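"""Core-haplotype detection and subgroup partitioning of the MJ network.

A *core haplotype* is a high-frequency, geographically widespread haplotype
at the hub of a star-like expansion. Cores are formalised here by two
thresholds — a minimum individual count and a minimum number of regions of
occurrence — and cores within one mutational step of each other are merged
into a single *core cluster* (so a set of cores forming a one-mutation
parallelogram behaves as one centre).

Subgroups are then the network neighbourhoods of core clusters: every
observed haplotype is assigned to the subgroup whose core cluster is nearest
by network distance. :func:`star_score` quantifies how star-like a subgroup
is (fraction of its haplotypes within one step of the core cluster), and
:func:`haplogroup_components` offers a simple distance-threshold partition
standing in for tree-based haplogrouping: cut all edges longer than ``cut``
mutations and take connected components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .alignment_io import HaplotypeTable
from .mj_network import HaplotypeGraph

__all__ = [
    "CoreSet",
    "SubgroupAssignment",
    "detect_cores",
    "core_clusters",
    "assign_subgroups",
    "star_score",
    "haplogroup_components",
    "write_cores",
    "write_subgroups",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CoreSet:
    """Haplotypes designated as cores, with detection provenance."""

    core_ids: frozenset[str]
    provenance: str = "user_specified"  # or "auto_detected"
    min_freq: int | None = None
    min_regions: int | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("user_specified", "auto_detected"):
            raise ValueError("provenance must be user_specified or auto_detected")


@dataclass
class SubgroupAssignment:
    """Maps every observed haplotype to exactly one subgroup label."""

    assignment: dict[str, str]
    cores: dict[str, frozenset[str]] = field(default_factory=dict)

    def members(self, label: str) -> set[str]:
        return {h for h, s in self.assignment.items() if s == label}

    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))


def detect_cores(
    graph: HaplotypeGraph,
    table: HaplotypeTable,
    min_freq: int = 10,
    min_regions: int = 3,
) -> CoreSet:
    """Observed haplotypes with ≥ ``min_freq`` individuals occurring in
    ≥ ``min_regions`` regions. Empty result warns (the caller may supply
    cores explicitly instead)."""
    observed = set(graph.observed_ids)
    cores = {
        hap
        for hap in table.haplotype_ids
        if hap in observed
        and table.total_count(hap) >= min_freq
        and len(table.regions_of(hap)) >= min_regions
    }
    if not cores:
        warnings.warn(
            f"no haplotype passes core thresholds (min_freq={min_freq}, "
            f"min_regions={min_regions}); supply cores explicitly"
        )
    return CoreSet(
        core_ids=frozenset(cores),
        provenance="auto_detected",
        min_freq=min_freq,
        min_regions=min_regions,
    )


def core_clusters(graph: HaplotypeGraph, cores: CoreSet) -> list[frozenset[str]]:
    """Group cores lying within network distance 1 of each other into
    clusters (connected components of the distance-1 relation), sorted by
    smallest member id."""
    ids = sorted(cores.core_ids)
    for c in ids:
        if c not in graph.graph:
            raise KeyError(f"core {c!r} not in network")
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if graph.distance(a, b) <= 1:
                g.add_edge(a, b)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: min(c))


def _dist_to_set(graph: HaplotypeGraph, sources: Iterable[str]) -> dict[str, float]:
    return nx.multi_source_dijkstra_path_length(
        graph.graph, set(sources), weight="weight"
    )


def assign_subgroups(
    graph: HaplotypeGraph,
    cores: Mapping[str, CoreSet],
    tie_rule: str = "lexicographic",
) -> SubgroupAssignment:
    """Assign each observed haplotype to the subgroup with the nearest core
    cluster (distance = minimum over cluster members). Ties go to the
    lexicographically smallest subgroup label; haplotypes unreachable from
    every core get the sentinel label ``"unassigned"``."""
    if tie_rule != "lexicographic":
        raise ValueError("only the 'lexicographic' tie rule is implemented")
    if not cores or all(not cs.core_ids for cs in cores.values()):
        raise ValueError("at least one nonempty core set is required")
    dist_by_label: dict[str, dict[str, float]] = {}
    for label in sorted(cores):
        cs = cores[label]
        for c in cs.core_ids:
            if c not in graph.graph:
                raise KeyError(f"core {c!r} not in network")
        dist_by_label[label] = _dist_to_set(graph, cs.core_ids)
    assignment: dict[str, str] = {}
    for hap in sorted(graph.observed_ids):
        best_label, best_d = UNASSIGNED, float("inf")
        for label in sorted(dist_by_label):
            d = dist_by_label[label].get(hap, float("inf"))
            if d < best_d:
                best_label, best_d = label, d
        assignment[hap] = best_label if best_d < float("inf") else UNASSIGNED
    return SubgroupAssignment(
        assignment=assignment,
        cores={label: cs.core_ids for label, cs in cores.items()},
    )


def star_score(
    graph: HaplotypeGraph,
    core: str | Iterable[str],
    members: Iterable[str] | None = None,
) -> float:
    """Fraction of a subgroup's observed haplotypes within one mutational
    step of the core cluster (1.0 = perfect star).

    ``core`` may be a single id or a cluster of ids; ``members`` defaults to
    every observed haplotype of the graph. An isolated core with no
    derivatives scores 1.0 (single-node subgroup convention).
    """
    core_ids = {core} if isinstance(core, str) else set(core)
    for c in core_ids:
        if c not in graph.graph:
            raise KeyError(f"core {c!r} not in network")
    pool = set(graph.observed_ids) if members is None else set(members)
    pool |= core_ids
    dist = _dist_to_set(graph, core_ids)
    near = sum(1 for h in pool if dist.get(h, float("inf")) <= 1)
    return near / len(pool)


def haplogroup_components(graph: HaplotypeGraph, cut: int) -> dict[str, str]:
    """Distance-threshold haplogroup candidates.

    Remove every edge with weight > ``cut`` and label the connected
    components by decreasing size of their observed membership
    (``HG1`` largest; ties broken by smallest member id). Only observed
    haplotypes appear in the returned mapping; median vectors merely act
    as connectors.
    """
    if cut < 1:
        raise ValueError("cut must be a positive integer")
    g = nx.Graph()
    g.add_nodes_from(graph.graph.nodes)
    g.add_edges_from(
        (u, v) for u, v, d in graph.graph.edges(data=True) if d["weight"] <= cut
    )
    observed = set(graph.observed_ids)
    comps = [sorted(c & observed) for c in nx.connected_components(g)]
    comps = [c for c in comps if c]
    comps.sort(key=lambda c: (-len(c), c[0]))
    labels: dict[str, str] = {}
    for rank, comp in enumerate(comps, start=1):
        for hap in comp:
            labels[hap] = f"HG{rank}"
    return labels


def write_cores(
    cores: CoreSet,
    clusters: Sequence[frozenset[str]],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("core_id\tcluster\tprovenance\tmin_freq\tmin_regions\n")
        cluster_of = {c: i + 1 for i, cl in enumerate(clusters) for c in cl}
        for core in sorted(cores.core_ids):
            fh.write(
                f"{core}\t{cluster_of.get(core, '')}\t{cores.provenance}\t"
                f"{cores.min_freq if cores.min_freq is not None else ''}\t"
                f"{cores.min_regions if cores.min_regions is not None else ''}\n"
            )


def write_subgroups(
    assignment: SubgroupAssignment,
    graph: HaplotypeGraph,
    path,
) -> None:
    dists: dict[str, dict[str, float]] = {
        label: _dist_to_set(graph, ids)
        for label, ids in assignment.cores.items()
        if ids
    }
    with open(path, "w") as fh:
        fh.write("haplotype_id\tsubgroup\tdistance_to_core\n")
        for hap in sorted(assignment.assignment):
            label = assignment.assignment[hap]
            d = dists.get(label, {}).get(hap, float("inf"))
            d_str = "inf" if d == float("inf") else f"{d:g}"
            fh.write(f"{hap}\t{label}\t{d_str}\n")
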
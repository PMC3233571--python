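"""Median-joining (MJ) haplotype network construction.

The MJ network is built in the classical three-stage loop:

1. **ε-relaxed minimum spanning network (MSN).** An edge ``{u, v}`` of weight
   ``w`` is included when ``u`` and ``v`` lie in different connected
   components of the graph formed by all pairs at distance ``< w − ε``. At
   ``ε = 0`` this is exactly the union of all minimum spanning trees; larger
   ε admits progressively more near-minimal connections.
2. **Quasi-median insertion.** For every feasible triple — three haplotypes
   mutually adjacent in the current MSN — the column-wise majority consensus
   is formed. Columns where all three states differ contribute each of the
   three observed states, so such columns multiply the candidate set
   (the quasi-median set). New sequences are added as *median vectors*
   (unsampled intermediates) and the MSN is rebuilt; the loop runs to a
   fixpoint, guarded by a hard cap on median-node count.
3. **Pruning of obsolete medians.** Median vectors are removed greedily (in
   creation order, iterated to a fixpoint) whenever dropping them neither
   lengthens any observed-observed shortest path nor increases the total
   length of a minimum spanning tree over the remaining nodes. The MST-length
   condition is what keeps genuine Steiner points — e.g. the centre of the
   (AAT, ATA, TAA) triple — while discarding medians that merely subdivide
   an existing geodesic. Finally, any observed-only MSN edge whose endpoints
   ended up further apart than the edge weight (possible on homoplasy-rich
   data when medians mediate a detour) is restored, so the network always
   contains every minimum spanning tree of the observed haplotypes.

All distances are Hamming counts over the retained alignment columns
(optionally position-weighted). Determinism: nodes are processed in a fixed
order (observed haplotypes in table order, then medians in creation order),
triples lexicographically, and median vectors are named ``mv1, mv2, ...`` in
creation order, so identical input yields an identical graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra, minimum_spanning_tree

from .alignment_io import HaplotypeTable

__all__ = [
    "ConvergenceError",
    "DistanceMatrix",
    "HaplotypeGraph",
    "hamming",
    "pairwise_hamming",
    "distance_matrix",
    "minimum_spanning_network",
    "quasi_median",
    "build_mj_network",
    "network_distance",
    "write_gml",
    "write_dot",
    "write_edge_list",
]

_TOL = 1e-9

#: Hard cap on median vectors, as a multiple of the observed haplotype count.
MAX_MEDIAN_FACTOR = 10

#: Columns where all three states of a triple differ each contribute three
#: candidate states; cap the blow-up (3**k candidate sequences per triple).
_MAX_ALL_DIFFERENT_COLUMNS = 12


class ConvergenceError(RuntimeError):
    """Raised when median insertion exceeds the median-node cap."""


def hamming(
    a: str,
    b: str,
    weights: Sequence[float] | None = None,
) -> float:
    """Number (or weighted sum) of mismatching columns between two sequences."""
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if weights is None:
        return sum(x != y for x, y in zip(a, b))
    if len(weights) != len(a):
        raise ValueError("weights length must equal sequence length")
    return float(sum(w for x, y, w in zip(a, b, weights) if x != y))


def _encode(seqs: Sequence[str]) -> np.ndarray:
    return np.array([np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in seqs])


def pairwise_hamming(
    seqs: Sequence[str],
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Symmetric matrix of pairwise (weighted) Hamming distances."""
    n = len(seqs)
    if n == 0:
        return np.zeros((0, 0))
    arr = _encode(seqs)
    w = None if weights is None else np.asarray(weights, dtype=float)
    # chunked to bound the n*n*L boolean intermediate
    D = np.zeros((n, n), dtype=float)
    step = max(1, int(2e8 // (max(1, n) * arr.shape[1])))
    for i0 in range(0, n, step):
        block = arr[i0 : i0 + step, None, :] != arr[None, :, :]
        if w is None:
            D[i0 : i0 + step] = block.sum(axis=2)
        else:
            D[i0 : i0 + step] = (block * w).sum(axis=2)
    return D


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise Hamming distances between haplotypes, in table order."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")


def distance_matrix(
    table: HaplotypeTable,
    weights: Sequence[float] | None = None,
) -> DistanceMatrix:
    ids = tuple(table.haplotype_ids)
    seqs = [s for _h, s in table.haplotypes]
    return DistanceMatrix(ids=ids, d=pairwise_hamming(seqs, weights))


def _msn_edge_indices(D: np.ndarray, epsilon: float) -> list[tuple[int, int, float]]:
    """ε-relaxed MSN edges as (i, j, weight) index triples, i < j.

    Edge (i, j) at distance w is kept iff i and j are disconnected using all
    pairs at distance < w − ε. With ε = 0 this is the union of all MSTs.
    """
    n = D.shape[0]
    if n <= 1:
        return []
    iu, ju = np.triu_indices(n, k=1)
    wts = D[iu, ju]
    edges: list[tuple[int, int, float]] = []
    for w in np.unique(wts):
        # strict threshold: keeps edges whose weight is <= (minimal merging
        # cost + epsilon), and makes the edge set monotone in epsilon
        adj = D < w - epsilon - _TOL
        np.fill_diagonal(adj, False)
        _nc, labels = connected_components(csr_matrix(adj), directed=False)
        sel = np.isclose(wts, w) & (labels[iu] != labels[ju])
        for i, j in zip(iu[sel], ju[sel]):
            edges.append((int(i), int(j), float(w)))
    edges.sort(key=lambda e: (e[2], e[0], e[1]))
    return edges


def minimum_spanning_network(
    D: DistanceMatrix,
    epsilon: float = 0.0,
) -> set[tuple[str, str]]:
    """The ε-relaxed minimum spanning network as a set of id pairs.

    Contains every edge occurring in at least one minimum spanning tree,
    plus (for ε > 0) all connections within ε of the minimal merging cost.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    out: set[tuple[str, str]] = set()
    for i, j, _w in _msn_edge_indices(D.d, epsilon):
        a, b = D.ids[i], D.ids[j]
        out.add((a, b) if a <= b else (b, a))
    return out


def quasi_median(u: str, v: str, w: str) -> set[str]:
    """Quasi-median sequences of a triple, excluding the inputs.

    Column-wise: if at least two of the three states agree the median takes
    that majority state; columns where all three differ contribute each of
    the three observed states (Cartesian product over such columns).
    """
    if not (len(u) == len(v) == len(w)):
        raise ValueError("sequences must have equal length")
    options: list[tuple[str, ...]] = []
    n_all_diff = 0
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            options.append((a,))
        elif b == c:
            options.append((b,))
        else:
            n_all_diff += 1
            options.append((a, b, c))
    if n_all_diff > _MAX_ALL_DIFFERENT_COLUMNS:
        raise ConvergenceError(
            f"quasi-median blow-up: {n_all_diff} all-different columns "
            f"(limit {_MAX_ALL_DIFFERENT_COLUMNS})"
        )
    out = {"".join(choice) for choice in itertools.product(*options)}
    return out - {u, v, w}


@dataclass
class HaplotypeGraph:
    """The MJ network: observed haplotypes plus surviving median vectors.

    Nodes carry ``sequence`` and ``observed`` attributes; edges carry an
    integer/float ``weight`` equal to the Hamming distance of their
    endpoint sequences.
    """

    graph: nx.Graph

    @property
    def observed_ids(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["observed"]]

    @property
    def median_ids(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["observed"]]

    def sequence_of(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["sequence"]

    def distance(self, h1: str, h2: str) -> float:
        return network_distance(self, h1, h2)


def _triple_cost(su: str, sv: str, sw: str) -> int:
    """Connection cost of a triple's quasi-medians: every quasi-median of
    (u, v, w) has the same total distance to the three sequences — one per
    column where exactly two states agree, two per all-different column."""
    cost = 0
    for a, b, c in zip(su, sv, sw):
        if a == b == c:
            continue
        cost += 1 if (a == b or a == c or b == c) else 2
    return cost


def _triangles(n: int, edges: list[tuple[int, int, float]]) -> list[tuple[int, int, int]]:
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j, _w in edges:
        adj[i].add(j)
        adj[j].add(i)
    tris: set[tuple[int, int, int]] = set()
    for i, j, _w in edges:
        for k in adj[i] & adj[j]:
            tris.add(tuple(sorted((i, j, k))))  # type: ignore[arg-type]
    return sorted(tris)


def _sp_observed(
    n: int,
    n_obs: int,
    edges: list[tuple[int, int, float]],
) -> np.ndarray:
    """All-pairs shortest-path lengths between observed nodes (indices
    0..n_obs-1) in the weighted graph given by ``edges``."""
    rows = [e[0] for e in edges] + [e[1] for e in edges]
    cols = [e[1] for e in edges] + [e[0] for e in edges]
    vals = [e[2] for e in edges] * 2
    adj = csr_matrix((vals, (rows, cols)), shape=(n, n))
    sp = dijkstra(adj, directed=False, indices=list(range(n_obs)))
    return sp[:, :n_obs]


def _mst_total(D: np.ndarray) -> float:
    if D.shape[0] <= 1:
        return 0.0
    return float(minimum_spanning_tree(csr_matrix(D)).sum())


def build_mj_network(
    table: HaplotypeTable,
    epsilon: float = 0.0,
    weights: Sequence[float] | None = None,
    max_median_factor: int = MAX_MEDIAN_FACTOR,
) -> HaplotypeGraph:
    """Construct the median-joining network for a haplotype table.

    Parameters
    ----------
    table:
        Collapsed haplotypes (observed nodes).
    epsilon:
        MSN relaxation tolerance; 0 (default) yields the sparsest network.
    weights:
        Optional per-column positive weights for the Hamming distance.
    max_median_factor:
        Abort with :class:`ConvergenceError` if the number of median vectors
        exceeds ``max_median_factor * n_observed``.
    """
    if not table.haplotypes:
        raise ValueError("empty haplotype table")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    obs_ids = list(table.haplotype_ids)
    seqs = [s for _h, s in table.haplotypes]
    if len(set(seqs)) != len(seqs):
        raise ValueError("haplotype table contains duplicate sequences")
    ids = list(obs_ids)
    seq_set = set(seqs)
    n_obs = len(obs_ids)
    cap = max_median_factor * n_obs
    mv_counter = 0

    # --- stages 1+2: alternate MSN construction and quasi-median insertion.
    # Per pass, only median vectors of minimal connection cost are added
    # (the classical greedy criterion); without it, triangles between
    # unrelated haplotypes flood the network with useless medians.
    while True:
        D = pairwise_hamming(seqs, weights)
        edges = _msn_edge_indices(D, epsilon)
        tris = sorted(
            _triangles(len(ids), edges),
            key=lambda t: (_triple_cost(seqs[t[0]], seqs[t[1]], seqs[t[2]]), t),
        )
        new_seqs: list[str] = []
        seen_new: set[str] = set()
        current_cost: float | None = None
        for i, j, k in tris:
            cost = _triple_cost(seqs[i], seqs[j], seqs[k])
            if current_cost is not None and cost > current_cost:
                break
            fresh = [
                qm for qm in sorted(quasi_median(seqs[i], seqs[j], seqs[k]))
                if qm not in seq_set and qm not in seen_new
            ]
            if fresh and current_cost is None:
                current_cost = cost
            for qm in fresh:
                seen_new.add(qm)
                new_seqs.append(qm)
        if not new_seqs:
            break
        if len(ids) - n_obs + len(new_seqs) > cap:
            raise ConvergenceError(
                f"median-node cap exceeded: {len(ids) - n_obs + len(new_seqs)} "
                f"median vectors for {n_obs} observed haplotypes "
                f"(cap {cap}); raise max_median_factor or check the input"
            )
        for qm in new_seqs:
            mv_counter += 1
            ids.append(f"mv{mv_counter}")
            seqs.append(qm)
            seq_set.add(qm)

    # --- stage 3: prune obsolete median vectors
    D = pairwise_hamming(seqs, weights)
    edges = _msn_edge_indices(D, epsilon)
    base_sp = _sp_observed(len(ids), n_obs, edges)
    base_mst = _mst_total(D)
    changed = True
    while changed:
        changed = False
        pos = n_obs
        while pos < len(ids):
            trial = [i for i in range(len(ids)) if i != pos]
            Dt = D[np.ix_(trial, trial)]
            et = _msn_edge_indices(Dt, epsilon)
            sp_t = _sp_observed(len(trial), n_obs, et)
            if (
                np.all(np.isfinite(sp_t))
                and _mst_total(Dt) <= base_mst + _TOL
                and np.all(sp_t <= base_sp + _TOL)
            ):
                del ids[pos], seqs[pos]
                D = Dt
                edges = et
                base_sp = sp_t
                base_mst = _mst_total(Dt)
                changed = True
            else:
                pos += 1

    # guarantee MST containment: every observed-only MSN edge must be
    # realised within its own weight (mediated detours can be longer on
    # homoplasy-rich data; the direct link is then restored)
    obs_edges = _msn_edge_indices(D[:n_obs, :n_obs], epsilon)
    existing = {(i, j) for i, j, _w in edges}
    restored = [
        (i, j, w)
        for i, j, w in obs_edges
        if (i, j) not in existing and base_sp[i, j] > w + _TOL
    ]
    edges = sorted(edges + restored, key=lambda e: (e[2], e[0], e[1]))

    final_ids = ids
    final_seqs = seqs
    g = nx.Graph()
    for node_id, seq in zip(final_ids, final_seqs):
        g.add_node(node_id, sequence=seq, observed=node_id in set(obs_ids))
    for i, j, w in edges:
        wt = int(round(w)) if weights is None else w
        g.add_edge(final_ids[i], final_ids[j], weight=wt)
    return HaplotypeGraph(graph=g)


def network_distance(graph: HaplotypeGraph, h1: str, h2: str) -> float:
    """Shortest-path length (in mutational steps) between two network nodes."""
    g = graph.graph
    for h in (h1, h2):
        if h not in g:
            raise KeyError(f"node {h!r} not in network")
    try:
        return nx.shortest_path_length(g, h1, h2, weight="weight")
    except nx.NetworkXNoPath:
        return float("inf")


# ---------------------------------------------------------------------------
# exports


def _attach_counts(graph: HaplotypeGraph, table: HaplotypeTable) -> None:
    for node in graph.graph.nodes:
        if graph.graph.nodes[node]["observed"]:
            graph.graph.nodes[node]["n_domestic"] = table.total_count(node, "domestic")
            graph.graph.nodes[node]["n_wild"] = table.total_count(node, "wild")
            graph.graph.nodes[node]["regions"] = ",".join(sorted(table.regions_of(node)))


def write_gml(
    graph: HaplotypeGraph,
    path: str | Path,
    table: HaplotypeTable | None = None,
) -> Path:
    path = Path(path)
    g = graph.graph.copy()
    if table is not None:
        _attach_counts(HaplotypeGraph(graph=g), table)
    for node in g.nodes:
        g.nodes[node]["observed"] = int(g.nodes[node]["observed"])
    nx.write_gml(g, path)
    return path


def write_dot(graph: HaplotypeGraph, path: str | Path) -> Path:
    path = Path(path)
    lines = ["graph hapnet {"]
    for node, data in sorted(graph.graph.nodes(data=True)):
        shape = "circle" if data["observed"] else "point"
        lines.append(f'  "{node}" [shape={shape}];')
    for u, v, data in sorted(graph.graph.edges(data=True)):
        lines.append(f'  "{u}" -- "{v}" [label="{data["weight"]}"];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_edge_list(graph: HaplotypeGraph, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v, data in sorted(graph.graph.edges(data=True)):
            a, b = (u, v) if u <= v else (v, u)
            fh.write(f"{a}\t{b}\t{data['weight']}\n")
    return path
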
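"""Independent brute-force oracles used to check the implementation.

Everything here is written against the mathematical definitions, not
against the package's code paths: spanning trees are enumerated, the
Steiner minimum is computed by Dreyfus-Wagner dynamic programming over an
explicit candidate-node set, and shortest paths are found by exhaustive
simple-path recursion.
"""

from __future__ import annotations

import itertools

import numpy as np


def hamming_scan(a: str, b: str) -> int:
    assert len(a) == len(b)
    n = 0
    for i in range(len(a)):
        if a[i] != b[i]:
            n += 1
    return n


def mask_scan(seqs: list[str], drop_ambiguous: bool = True) -> tuple[list[str], list[int]]:
    """Naive per-column scan deleting gap (and optionally ambiguity) columns."""
    L = len(seqs[0])
    keep = []
    for j in range(L):
        col = [s[j] for s in seqs]
        if "-" in col:
            continue
        if drop_ambiguous and any(c not in "ACGT" for c in col):
            continue
        keep.append(j)
    return ["".join(s[j] for j in keep) for s in seqs], keep


def union_of_msts(n: int, weight) -> set[tuple[int, int]]:
    """All edges occurring in at least one minimum spanning tree, by
    exhaustive enumeration of spanning trees (n <= 7)."""
    pairs = list(itertools.combinations(range(n), 2))
    best = None
    trees: list[tuple[tuple[int, int], ...]] = []
    for combo in itertools.combinations(pairs, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if not ok:
            continue
        w = sum(weight(i, j) for i, j in combo)
        if best is None or w < best - 1e-9:
            best = w
            trees = [combo]
        elif abs(w - best) <= 1e-9:
            trees.append(combo)
    out: set[tuple[int, int]] = set()
    for combo in trees:
        out.update(combo)
    return out


def quasi_median_bruteforce(u: str, v: str, w: str) -> set[str]:
    """Enumerate all sequences over {A,C,G,T}^L and keep those obeying the
    column-wise majority / all-different rule; inputs excluded."""
    L = len(u)
    out = set()
    for cand in itertools.product("ACGT", repeat=L):
        ok = True
        for x, (a, b, c) in zip(cand, zip(u, v, w)):
            states = (a, b, c)
            if a == b or a == c:
                major = a
            elif b == c:
                major = b
            else:
                major = None
            if major is not None:
                if x != major:
                    ok = False
                    break
            elif x not in states:
                ok = False
                break
        if ok:
            out.add("".join(cand))
    return out - {u, v, w}


def shortest_path_bruteforce(nodes, edges, s, t) -> float:
    """Minimum-weight simple path by exhaustive recursion.

    ``edges``: dict {(u, v): w} with u < v under some ordering.
    """
    adj: dict = {n: [] for n in nodes}
    for (u, v), w in edges.items():
        adj[u].append((v, w))
        adj[v].append((u, w))
    best = [float("inf")]

    def rec(node, seen, acc):
        if acc >= best[0]:
            return
        if node == t:
            best[0] = acc
            return
        for nxt, w in adj[node]:
            if nxt not in seen:
                rec(nxt, seen | {nxt}, acc + w)

    rec(s, {s}, 0.0)
    return best[0]


def steiner_minimal_length(seqs: list[str], max_candidates: int = 5000) -> float:
    """Exact Steiner minimal network length for terminal sequences in Hamming
    space, by Dreyfus-Wagner DP over the candidate set of all per-column
    combinations of observed states (optimal Steiner points in Hamming space
    can always be chosen coordinate-wise among observed states)."""
    state_sets = [sorted(set(col)) for col in zip(*seqs)]
    n_cand = 1
    for s in state_sets:
        n_cand *= len(s)
    if n_cand > max_candidates:
        raise ValueError(f"candidate blow-up: {n_cand} > {max_candidates}")
    cand = ["".join(p) for p in itertools.product(*state_sets)]
    arr = np.array([np.frombuffer(c.encode(), dtype=np.uint8) for c in cand])
    D = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)
    term_idx = [cand.index(s) for s in seqs]
    t = len(term_idx)
    if t <= 1:
        return 0.0
    n = len(cand)
    INF = 1e18
    S = np.full((n, 1 << t), INF)
    for i, ti in enumerate(term_idx):
        S[:, 1 << i] = D[:, ti]
    for T in range(1, 1 << t):
        if T & (T - 1) == 0:
            continue
        M = np.full(n, INF)
        sub = (T - 1) & T
        while sub:
            comp = T ^ sub
            if sub <= comp:
                np.minimum(M, S[:, sub] + S[:, comp], out=M)
            sub = (sub - 1) & T
        # metric closure: one min-plus relaxation suffices (triangle inequality)
        S[:, T] = np.min(D + M[None, :], axis=1)
    full = (1 << t) - 1
    return float(S[term_idx[0], full ^ 1])
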
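"""Independent reference implementations used only to check results.

These deliberately share no code with the package: alignment statistics
come from a top-down memoized recursion over explicit alignment states
(and, for tiny inputs, full enumeration of alignment paths), and tree
topologies from exhaustive search over all unrooted binary topologies
with least-squares branch fitting.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

MATCH, MISMATCH, OPEN, EXT = 1, -1, -5, -2
UNAMBIG = set("ACGT")


def _gapcost(g: int) -> int:
    return 0 if g == 0 else OPEN + EXT * (g - 1)


def oracle_alignment_stats(x: str, y: str, mode: str = "semi_global"):
    """(score, matches, columns) of the optimal alignment containing at
    least one aligned residue pair; ties broken by max matches then min
    columns. Query terminal gaps are always penalized; reference
    terminal gaps are free in semi_global mode. Opposite gap types are
    never adjacent inside the core."""
    semi = mode == "semi_global"
    n, m = len(x), len(y)

    def sub(a: str, b: str) -> tuple[int, int]:
        if a == b and a in UNAMBIG:
            return MATCH, 1
        return MISMATCH, 0

    NEG = (float("-inf"), 0, 0)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str):
        """Best (score, matches, -cols) continuing after a column of
        ``state`` ended at (i, j); stopping is allowed only after an
        aligned pair."""
        options = []
        if state == "M":
            trail = _gapcost(n - i) + (0 if semi else _gapcost(m - j))
            options.append((trail, 0, 0))
        if i < n and j < m:
            s, mt = sub(x[i], y[j])
            t = rec(i + 1, j + 1, "M")
            options.append((t[0] + s, t[1] + mt, t[2] - 1))
        if i < n and state != "Y":
            cost = EXT if state == "X" else OPEN
            t = rec(i + 1, j, "X")
            options.append((t[0] + cost, t[1], t[2] - 1))
        if j < m and state != "X":
            cost = EXT if state == "Y" else OPEN
            t = rec(i, j + 1, "Y")
            options.append((t[0] + cost, t[1], t[2] - 1))
        # gap states carry no stop option, so alignments whose core ends
        # in a gap bottom out at -inf and are pruned here
        valid = [o for o in options if o[0] != float("-inf")]
        return max(valid) if valid else NEG

    best = NEG
    for i0 in range(n):
        for j0 in range(m):
            lead = _gapcost(i0) + (0 if semi else _gapcost(j0))
            s, mt = sub(x[i0], y[j0])
            t = rec(i0 + 1, j0 + 1, "M")
            cand = (lead + s + t[0], mt + t[1], -1 + t[2])
            best = max(best, cand)
    return best[0], best[1], -best[2]


def enumerate_alignment_stats(x: str, y: str, mode: str = "semi_global"):
    """Same statistic by brute-force enumeration of every core start,
    end, and internal op sequence. Exponential; only for tiny inputs."""
    semi = mode == "semi_global"
    n, m = len(x), len(y)
    best = None

    def walk(i, j, end_i, end_j, prev, score, matches, cols):
        nonlocal best
        if (i, j) == (end_i + 1, end_j + 1):
            if prev == "M":
                trail = _gapcost(n - i) + (0 if semi else _gapcost(m - j))
                cand = (score + trail, matches, -cols)
                if best is None or cand > best:
                    best = cand
            return
        if i <= end_i and j <= end_j:
            a, b = x[i], y[j]
            mt = 1 if (a == b and a in UNAMBIG) else 0
            s = MATCH if mt else MISMATCH
            walk(i + 1, j + 1, end_i, end_j, "M", score + s, matches + mt, cols + 1)
        # the residues at (end_i, end_j) are reserved for the final
        # aligned pair, so internal gaps stop short of them
        if i < end_i and prev != "Y":
            cost = EXT if prev == "X" else OPEN
            walk(i + 1, j, end_i, end_j, "X", score + cost, matches, cols + 1)
        if j < end_j and prev != "X":
            cost = EXT if prev == "Y" else OPEN
            walk(i, j + 1, end_i, end_j, "Y", score + cost, matches, cols + 1)

    for i0 in range(n):
        for j0 in range(m):
            for i1 in range(i0, n):
                for j1 in range(j0, m):
                    lead = _gapcost(i0) + (0 if semi else _gapcost(j0))
                    walk(i0, j0, i1, j1, "start", lead, 0, 0)
    assert best is not None
    return best[0], best[1], -best[2]


# --------------------------------------------------------------------------
# trees


def enumerate_topologies(labels: list[str]):
    """All unrooted binary topologies over the labels, as (edges, nodes)
    with leaves named by label and internal nodes by negative ints."""
    assert len(labels) >= 3
    base_internal = -1
    trees = [([(labels[0], base_internal), (labels[1], base_internal), (labels[2], base_internal)], base_internal - 1)]
    for leaf in labels[3:]:
        new_trees = []
        for edges, next_id in trees:
            for k, (a, b) in enumerate(edges):
                mid = next_id
                new_edges = edges[:k] + edges[k + 1:] + [(a, mid), (b, mid), (leaf, mid)]
                new_trees.append((new_edges, next_id - 1))
        trees = new_trees
    return [edges for edges, _ in trees]


def tree_splits(edges, labels):
    """Non-trivial bipartitions induced by the edge set."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    label_set = frozenset(labels)
    splits = set()
    for a, b in edges:
        # leaves reachable from a without crossing (a, b)
        seen = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v == b and u == a:
                    continue
                if v not in seen and not (u == a and v == b):
                    seen.add(v)
                    stack.append(v)
        side = frozenset(l for l in labels if l in seen)
        if 1 < len(side) < len(labels) - 1:
            splits.add(frozenset({side, label_set - side}))
    return splits


def _path_edges(edges, src, dst):
    adj = {}
    for idx, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, idx))
        adj.setdefault(b, []).append((a, idx))
    stack = [(src, [])]
    seen = {src}
    while stack:
        u, path = stack.pop()
        if u == dst:
            return path
        for v, idx in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append((v, path + [idx]))
    raise AssertionError("disconnected tree")


def least_squares_topology(dist: np.ndarray, labels: list[str]):
    """Exhaustive topology search: fit branch lengths to the distance
    matrix by least squares on every topology and return the splits of
    the best-fitting one."""
    pairs = list(itertools.combinations(range(len(labels)), 2))
    best = None
    for edges in enumerate_topologies(labels):
        A = np.zeros((len(pairs), len(edges)))
        d = np.array([dist[i, j] for i, j in pairs])
        for row, (i, j) in enumerate(pairs):
            for idx in _path_edges(edges, labels[i], labels[j]):
                A[row, idx] = 1.0
        b, *_ = np.linalg.lstsq(A, d, rcond=None)
        sse = float(((A @ b - d) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, edges)
    return tree_splits(best[1], labels), best[0]


def random_additive_tree(labels: list[str], rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths and its
    exact leaf-to-leaf distance matrix."""
    topologies = enumerate_topologies(labels)
    edges = topologies[rng.integers(0, len(topologies))]
    lengths = rng.uniform(0.05, 0.4, len(edges))
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(lengths[idx] for idx in _path_edges(edges, labels[i], labels[j]))
            dist[i, j] = dist[j, i] = d
    return edges, dist


def newick_splits(newick: str, labels: list[str]):
    """Non-trivial splits of a Newick string (tiny recursive parser so
    the check does not depend on the package's own tree code)."""
    import re

    s = newick.strip().rstrip(";")
    pos = 0

    def parse():
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = [parse()]
            while s[pos] == ",":
                pos += 1
                children.append(parse())
            assert s[pos] == ")"
            pos += 1
            if pos < len(s) and s[pos] == ":":
                pos += 1
                while pos < len(s) and (s[pos].isdigit() or s[pos] in ".eE+-"):
                    pos += 1
            return [leaf for child_leaves, _ in children for leaf in child_leaves], children
        m = re.match(r"[^(),:;]+", s[pos:])
        name = m.group(0)
        pos += len(name)
        if pos < len(s) and s[pos] == ":":
            pos += 1
            while pos < len(s) and (s[pos].isdigit() or s[pos] in ".eE+-"):
                pos += 1
        return [name], []

    label_set = frozenset(labels)
    splits = set()

    def collect(node):
        leaves, children = node
        side = frozenset(leaves)
        if 1 < len(side) < len(labels) - 1:
            splits.add(frozenset({side, label_set - side}))
        for c in children:
            collect(c)

    collect(parse())
    return splits
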
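"""Independent brute-force oracles used to cross-check the implementation.

Each oracle takes a route disjoint from the production code path: path
enumeration via exhaustive vertex-sequence checking (small graphs) or
networkx's pairwise simple-path search, containment filtering via naive
pairwise scanning, clustering via pairwise rule application, and the
hypergeometric tail via exact integer combinatorics.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx


def paths_by_permutation(net, min_len=3, max_len=None):
    """Every vertex sequence, kept iff consecutive pairs are edges.

    Factorially expensive; only for graphs with a handful of nodes.
    """
    g = net.graph
    nodes = list(g.nodes)
    hi = min(len(nodes), max_len or len(nodes))
    found = set()
    for k in range(min_len, hi + 1):
        for seq in itertools.permutations(nodes, k):
            if all(g.has_edge(a, b) for a, b in zip(seq, seq[1:])):
                found.add(seq)
    return found


def paths_by_pairwise_search(net, min_len=3, max_len=None):
    """All simple paths via networkx's per-(source, target) enumeration."""
    g = net.graph
    cutoff = None if max_len is None else max_len - 1  # networkx cutoff is edge count
    found = set()
    for u in g.nodes:
        for v in g.nodes:
            if u == v:
                continue
            for p in nx.all_simple_paths(g, u, v, cutoff=cutoff):
                if len(p) >= min_len:
                    found.add(tuple(p))
    return found


def naive_filter_contained(paths):
    """Pairwise contiguous-containment scan."""

    def contained_in(p, q):
        if len(p) >= len(q):
            return False
        return any(q[i : i + len(p)] == p for i in range(len(q) - len(p) + 1))

    unique = set(map(tuple, paths))
    return {p for p in unique if not any(contained_in(p, q) for q in unique)}


def naive_cluster(cascades, interior_key=False):
    """Pairwise application of the clustering rule.

    Returns a set of frozensets of member cascades (>= 2 members each).
    """
    cascades = sorted(set(map(tuple, cascades)))
    groups = set()
    if interior_key:
        for c in cascades:
            if len(c) < 3:
                continue
            members = frozenset(
                d for d in cascades if len(d) == len(c) and d[1:-1] == c[1:-1]
            )
            if len(members) >= 2:
                groups.add(("interior", members))
    else:
        for c in cascades:
            begin = frozenset(d for d in cascades if len(d) == len(c) and d[1:] == c[1:])
            end = frozenset(d for d in cascades if len(d) == len(c) and d[:-1] == c[:-1])
            if len(begin) >= 2:
                groups.add(("begin", begin))
            if len(end) >= 2:
                groups.add(("end", end))
    return groups


def hypergeom_upper_tail_exact(N, K, n, k):
    """P(X >= k) by exact integer PMF summation."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return float(total)
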
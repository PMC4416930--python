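"""Cascade mining: simple-path enumeration and maximality filtration.

A cascade is a simple (vertex-disjoint) directed path of at least three
regulators.  After enumerating every simple path, any path whose element
sequence is completely contained in another path is filtered out, leaving
the maximal cascade set.  "Completely contained" defaults to contiguous,
order-preserving sub-path containment; a gapped-subsequence alternative
is available since curated pipelines differ on this detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from regcascade.network import RegulatoryNetwork

Path_ = tuple[str, ...]


class PathExplosionError(RuntimeError):
    """Raised when enumeration exceeds the configured path-count ceiling."""


@dataclass
class CascadeSet:
    """Canonically ordered (lexicographic) collection of cascades.

    Cascade ids are positional (``c000001`` …) within the canonical
    order, making them stable across reruns on identical input.
    """

    cascades: list[Path_]
    source: RegulatoryNetwork | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.cascades = sorted(set(map(tuple, self.cascades)))

    def __len__(self) -> int:
        return len(self.cascades)

    def __iter__(self) -> Iterator[Path_]:
        return iter(self.cascades)

    def cascade_id(self, index: int) -> str:
        return f"c{index + 1:06d}"

    def with_ids(self) -> list[tuple[str, Path_]]:
        return [(self.cascade_id(i), c) for i, c in enumerate(self.cascades)]


@dataclass
class CascadeLengthStats:
    mean_length: float | None  # None when the set is empty
    max_length: int
    histogram: dict[int, int]


def enumerate_simple_paths(
    net: RegulatoryNetwork,
    min_len: int = 3,
    max_len: int | None = None,
    max_paths: int | None = 5_000_000,
) -> list[Path_]:
    """Enumerate every simple directed path with ``min_len``–``max_len`` elements.

    Depth-first backtracking from every root node; each path is emitted
    exactly once.  The result set is traversal-order independent.  A
    configurable ceiling guards against combinatorial blow-up on dense
    graphs; exceeding it raises :class:`PathExplosionError` advising a
    ``max_len`` bound.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    g = net.graph
    out: list[Path_] = []
    stack: list[str] = []
    on_path: set[str] = set()

    def extend(node: str) -> None:
        stack.append(node)
        on_path.add(node)
        if len(stack) >= min_len:
            out.append(tuple(stack))
            if max_paths is not None and len(out) > max_paths:
                raise PathExplosionError(
                    f"more than {max_paths} simple paths enumerated; "
                    "set max_len (or raise max_paths) to bound the search"
                )
        if max_len is None or len(stack) < max_len:
            for nxt in g.successors(node):
                if nxt not in on_path:
                    extend(nxt)
        on_path.remove(node)
        stack.pop()

    for root in g.nodes:
        extend(root)
    return out


def _is_gapped_subsequence(short: Path_, long: Path_) -> bool:
    it = iter(long)
    return all(elem in it for elem in short)


def filter_contained(paths: Iterable[Path_], containment: str = "contiguous") -> CascadeSet:
    """Drop every path completely contained in another path.

    With ``containment='contiguous'`` (default) a path is dropped iff its
    element sequence occurs as a contiguous ordered run inside a longer
    path; with ``'gapped'`` order-preserving subsequence containment is
    used instead.  Filtration against the full input set coincides with
    filtration against the retained set for contiguous containment
    (containment is transitive through the containing path).
    """
    unique = sorted(set(map(tuple, paths)))
    if containment == "contiguous":
        windows: set[Path_] = set()
        for p in unique:
            n = len(p)
            for w in range(2, n):  # proper windows only
                for i in range(n - w + 1):
                    windows.add(p[i : i + w])
        kept = [p for p in unique if p not in windows]
    elif containment == "gapped":
        by_len = sorted(unique, key=len)
        kept = []
        for p in by_len:
            if not any(len(q) > len(p) and _is_gapped_subsequence(p, q) for q in unique):
                kept.append(p)
    else:
        raise ValueError(f"unknown containment mode {containment!r}")
    return CascadeSet(kept)


def mine_cascades(
    net: RegulatoryNetwork,
    min_len: int = 3,
    max_len: int | None = None,
    containment: str = "contiguous",
    max_paths: int | None = 5_000_000,
) -> CascadeSet:
    """Enumerate simple paths and keep only the maximal ones."""
    paths = enumerate_simple_paths(net, min_len=min_len, max_len=max_len, max_paths=max_paths)
    cs = filter_contained(paths, containment=containment)
    cs.source = net
    return cs


def cascade_length_stats(cs: CascadeSet) -> CascadeLengthStats:
    """Mean, maximum, and per-length histogram of cascade element counts."""
    hist: dict[int, int] = {}
    for c in cs:
        hist[len(c)] = hist.get(len(c), 0) + 1
    total = sum(hist.values())
    if total == 0:
        return CascadeLengthStats(mean_length=None, max_length=0, histogram={})
    mean = sum(l * n for l, n in hist.items()) / total
    return CascadeLengthStats(mean_length=mean, max_length=max(hist), histogram=dict(sorted(hist.items())))


# -- TSV interface ----------------------------------------------------

SEP = " -> "


def write_cascades_tsv(cs: CascadeSet, path: str | Path) -> None:
    """Write ``cascade_id<TAB>EN<TAB>elements`` (elements joined by ' -> ')."""
    with Path(path).open("w") as fh:
        fh.write("cascade_id\tEN\telements\n")
        for cid, c in cs.with_ids():
            fh.write(f"{cid}\t{len(c)}\t{SEP.join(c)}\n")


def read_cascades_tsv(path: str | Path) -> CascadeSet:
    lines = Path(path).read_text().splitlines()
    cascades = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}: line {lineno}: expected 3 columns, got {len(fields)}")
        elements = tuple(fields[2].split(SEP))
        if len(elements) != int(fields[1]):
            raise ValueError(f"{path}: line {lineno}: EN={fields[1]} but {len(elements)} elements")
        cascades.append(elements)
    return CascadeSet(cascades)
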
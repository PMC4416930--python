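"""Clustering of near-identical cascades.

Equal-length cascades that differ only in their first element form a
begin-cluster; those differing only in their last element form an
end-cluster.  The merged rendering replaces the varying position with
"…".  A cascade can belong to at most one begin-cluster and one
end-cluster.  An alternative interior-key mode groups on the shared
interior (positions 2..L-1), letting both ends vary within one cluster.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from regcascade.cascades import SEP, CascadeSet, Path_

BEGIN = "begin"
END = "end"
INTERIOR = "interior"


@dataclass
class Cluster:
    """Group of >=2 equal-length cascades varying at one site."""

    variation_site: str  # begin | end | interior
    shared_segment: Path_
    members: list[Path_]

    def __post_init__(self) -> None:
        self.members = sorted(map(tuple, self.members))
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 member cascades")
        lengths = {len(m) for m in self.members}
        if len(lengths) != 1:
            raise ValueError("cluster members must have identical element counts")

    @property
    def cn(self) -> int:
        return len(self.members)

    @property
    def variants(self) -> tuple[str, ...]:
        if self.variation_site == BEGIN:
            return tuple(m[0] for m in self.members)
        if self.variation_site == END:
            return tuple(m[-1] for m in self.members)
        return tuple(f"{m[0]}|{m[-1]}" for m in self.members)

    @property
    def cluster_id(self) -> str:
        key = f"{self.variation_site}:{'|'.join(self.shared_segment)}"
        return hashlib.sha1(key.encode()).hexdigest()[:12]


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    #: cascade -> ids of the clusters it belongs to (<=1 per site)
    membership: dict[Path_, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clusters = sorted(
            self.clusters, key=lambda cl: (cl.variation_site, cl.shared_segment)
        )
        self.membership = defaultdict(list, self.membership)
        if not self.membership:
            for cl in self.clusters:
                for m in cl.members:
                    self.membership[m].append(cl.cluster_id)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


def cluster_cascades(cs: CascadeSet | Iterable[Path_], interior_key: bool = False) -> ClusterSet:
    """Group cascades under the shared-segment rule.

    Default mode: begin-clusters group cascades with identical positions
    2..L, end-clusters group cascades with identical positions 1..L-1;
    groups of one are not clusters.  With ``interior_key=True`` the key
    is the interior segment (positions 2..L-1) and both ends may vary,
    merging each begin/end pair of clusters into one looser cluster.
    """
    cascades = sorted(set(map(tuple, cs)))
    clusters: list[Cluster] = []
    if interior_key:
        groups: dict[Path_, list[Path_]] = defaultdict(list)
        for c in cascades:
            if len(c) >= 3:
                groups[c[1:-1]].append(c)
        for seg, members in groups.items():
            if len(members) >= 2:
                clusters.append(Cluster(INTERIOR, seg, members))
    else:
        begin_groups: dict[Path_, list[Path_]] = defaultdict(list)
        end_groups: dict[Path_, list[Path_]] = defaultdict(list)
        for c in cascades:
            begin_groups[c[1:]].append(c)
            end_groups[c[:-1]].append(c)
        for seg, members in begin_groups.items():
            if len(members) >= 2:
                clusters.append(Cluster(BEGIN, seg, members))
        for seg, members in end_groups.items():
            if len(members) >= 2:
                clusters.append(Cluster(END, seg, members))
    return ClusterSet(clusters)


ELLIPSIS = "…"


def render_cluster(cl: Cluster) -> str:
    """Merged display string with "…" at the varying site."""
    seg = SEP.join(cl.shared_segment)
    if cl.variation_site == BEGIN:
        return f"{ELLIPSIS}{SEP}{seg}"
    if cl.variation_site == END:
        return f"{seg}{SEP}{ELLIPSIS}"
    return f"{ELLIPSIS}{SEP}{seg}{SEP}{ELLIPSIS}"


def parse_rendered_cluster(rendered: str, variants: Iterable[str]) -> list[Path_]:
    """Recover member sequences from a rendering plus its variant list."""
    parts = rendered.split(SEP)
    if parts[0] == ELLIPSIS and parts[-1] == ELLIPSIS:
        seg = tuple(parts[1:-1])
        return sorted((v.split("|")[0], *seg, v.split("|")[1]) for v in variants)
    if parts[0] == ELLIPSIS:
        seg = tuple(parts[1:])
        return sorted((v, *seg) for v in variants)
    if parts[-1] == ELLIPSIS:
        seg = tuple(parts[:-1])
        return sorted((*seg, v) for v in variants)
    raise ValueError(f"no '{ELLIPSIS}' site in rendering {rendered!r}")


def cluster_stats(clset: ClusterSet) -> dict:
    """Mean member count (CN) and CN histogram."""
    hist: dict[int, int] = {}
    for cl in clset:
        hist[cl.cn] = hist.get(cl.cn, 0) + 1
    total = sum(hist.values())
    mean = sum(cn * n for cn, n in hist.items()) / total if total else None
    return {"mean_CN": mean, "histogram": dict(sorted(hist.items()))}


# -- file interfaces --------------------------------------------------


def write_clusters_json(clset: ClusterSet, path: str | Path, cs: CascadeSet | None = None) -> None:
    """JSON array of clusters; members given as cascade ids when a
    :class:`CascadeSet` is supplied, else as rendered sequences."""
    id_of = {c: cid for cid, c in cs.with_ids()} if cs is not None else None
    payload = [
        {
            "cluster_id": cl.cluster_id,
            "variation_site": cl.variation_site,
            "shared_segment": list(cl.shared_segment),
            "members": [id_of[m] if id_of else SEP.join(m) for m in cl.members],
            "CN": cl.cn,
        }
        for cl in clset
    ]
    Path(path).write_text(json.dumps(payload, indent=1, ensure_ascii=False) + "\n")


def write_clusters_tsv(clset: ClusterSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("cluster_id\tvariation_site\tCN\trendering\tvariants\n")
        for cl in clset:
            fh.write(
                f"{cl.cluster_id}\t{cl.variation_site}\t{cl.cn}\t"
                f"{render_cluster(cl)}\t{','.join(cl.variants)}\n"
            )
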
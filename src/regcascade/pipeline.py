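"""End-to-end pipeline: network -> cascades -> clusters -> scores -> validation.

Writes deterministic artifacts plus a run manifest recording the tool
version, the configuration, input checksums, and the headline counts of
every stage, so reruns on identical inputs are byte-identical and any
discrepancy against external expectations is visible rather than hidden.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from regcascade import __version__
from regcascade.cascades import (
    cascade_length_stats,
    mine_cascades,
    write_cascades_tsv,
)
from regcascade.clusters import cluster_cascades, cluster_stats, write_clusters_json, write_clusters_tsv
from regcascade.enrichment import (
    build_background,
    hypergeom_overlap_test,
    read_cooccurrence,
    reliable_pairs,
)
from regcascade.network import build_network, export_network, network_stats, parse_edge_table
from regcascade.scoring import (
    annotate_cascades,
    extract_novel_pairs,
    load_annotations,
    n_distinct_cascades,
    retrieve_high_dar,
    write_novel_tsv,
    write_scores_tsv,
)


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    Thresholds default to the curated-analysis conventions: cascades
    need at least 3 elements, high-DAR retrieval keeps DAR strictly
    above 0.8, and literature pairs are reliable strictly above 100
    co-occurrences.
    """

    tf_mirna: str
    tf_tf: str
    mirna_tf: str
    annotations: str | None = None
    cooccurrence: str | None = None
    min_length: int = 3
    max_length: int | None = None
    dar_threshold: float = 0.8
    min_cooccurrence: int = 100
    containment: str = "contiguous"  # or "gapped"
    interior_key: bool = False
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest (also written).

    Artifacts: ``network.graphml``, ``network_stats.json``,
    ``cascades.tsv``, ``clusters.json``/``clusters.tsv``, and — when
    annotation / co-occurrence inputs are configured — ``scores.tsv``,
    ``novel_pairs.tsv``, ``enrichment.json``; plus ``manifest.json``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config": asdict(cfg),
        "inputs": {},
        "counts": {},
        "notes": [],
    }
    for role in ("tf_mirna", "tf_tf", "mirna_tf", "annotations", "cooccurrence"):
        p = getattr(cfg, role)
        if p:
            manifest["inputs"][role] = {"path": str(p), "sha256": _sha256(Path(p))}

    edge_lists = [
        parse_edge_table(Path(getattr(cfg, kind)), kind, provenance=kind)
        for kind in ("tf_mirna", "tf_tf", "mirna_tf")
    ]
    net = build_network(edge_lists)
    export_network(net, outdir / "network.graphml")
    stats = network_stats(net)
    (outdir / "network_stats.json").write_text(json.dumps(asdict(stats), indent=1) + "\n")
    manifest["counts"]["network"] = asdict(stats)

    cs = mine_cascades(net, min_len=cfg.min_length, max_len=cfg.max_length,
                       containment=cfg.containment)
    write_cascades_tsv(cs, outdir / "cascades.tsv")
    ls = cascade_length_stats(cs)
    manifest["counts"]["cascades"] = {
        "n_cascades": len(cs),
        "mean_length": ls.mean_length,
        "max_length": ls.max_length,
    }
    if len(cs) == 0:
        manifest["notes"].append("no cascades mined (network too sparse or empty)")

    clset = cluster_cascades(cs, interior_key=cfg.interior_key)
    write_clusters_json(clset, outdir / "clusters.json", cs)
    write_clusters_tsv(clset, outdir / "clusters.tsv")
    st = cluster_stats(clset)
    manifest["counts"]["clusters"] = {"n_clusters": len(clset), "mean_CN": st["mean_CN"]}

    records = []
    if cfg.annotations:
        ann = load_annotations(Path(cfg.annotations))
        records = annotate_cascades(cs, ann)
        write_scores_tsv(records, outdir / "scores.tsv")
        high = retrieve_high_dar(records, cfg.dar_threshold)
        novel = extract_novel_pairs(high, ann, net)
        write_novel_tsv(novel, outdir / "novel_pairs.tsv")
        manifest["counts"]["scoring"] = {
            "n_records": len(records),
            "n_diseases": len({r.disease for r in records}),
            "n_high_dar_records": len(high),
            "n_high_dar_cascades": n_distinct_cascades(high),
            "n_novel_pairs": len(novel),
            "n_novel_tf_pairs": sum(p.element_type == "TF" for p in novel),
            "n_novel_mirna_pairs": sum(p.element_type == "miRNA" for p in novel),
        }

        if cfg.cooccurrence:
            cooc = read_cooccurrence(Path(cfg.cooccurrence))
            ref = reliable_pairs(cooc, cfg.min_cooccurrence)
            pred = {(p.element_id.casefold(), p.disease.casefold()) for p in novel}
            diseases = {p.disease for p in novel}
            elements = {p.element_id for p in novel}
            if pred and ref:
                N, universe = build_background(diseases, elements)
                # restrict the reference to the background universe
                ref_in = ref & universe
                result = hypergeom_overlap_test(N, pred, ref_in)
                (outdir / "enrichment.json").write_text(
                    json.dumps(result.as_dict(), indent=1) + "\n"
                )
                manifest["counts"]["enrichment"] = result.as_dict()
            else:
                manifest["notes"].append("enrichment skipped: empty predicted or reference set")

    cfg.to_yaml(outdir / "config.yaml")
    manifest["artifacts"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
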
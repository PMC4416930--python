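"""Seeded synthetic fixtures: networks, annotations, co-occurrence tables.

The generator emulates the shape of the curated inputs — three typed
edge tables, an element–disease annotation table, and a PubMatrix-style
literature co-occurrence table — at configurable size, so every pipeline
stage is testable without downloads.  Edges are independent
Erdős–Rényi-style draws per kind; no attempt is made to match the degree
distribution of real curated networks.

Co-occurrence counts follow a documented generative rule: annotated
(element, disease) pairs draw Poisson(``cooc_mean_annotated``) counts
and unannotated pairs Poisson(``cooc_mean_background``), so annotated
pairs stochastically exceed the reliability threshold (default 100) far
more often.  This builds a positive control for the enrichment test.

:func:`worked_examples` packages three published case-study fixtures —
a 9-element breast-cancer cascade, an 8-element lymphoma cascade, and a
trio of 7-element PTEN cascades differing only in their first element —
as parsed objects plus matching annotation/edge tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from regcascade.network import EDGE_KINDS, MIRNA, TF, RegulatoryEdge, build_network
from regcascade.scoring import DiseaseAnnotationMap


@dataclass
class FixtureSpec:
    """Size/structure knobs for one synthetic dataset.

    The same spec and seed always yield byte-identical outputs.
    """

    n_tf: int = 20
    n_mirna: int = 10
    p_tf_tf: float = 0.05
    p_tf_mirna: float = 0.05
    p_mirna_tf: float = 0.05
    n_diseases: int = 5
    annotation_prevalence: float = 0.2
    cooc_mean_annotated: float = 400.0
    cooc_mean_background: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_tf_tf, self.p_tf_mirna, self.p_mirna_tf, self.annotation_prevalence):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_tf, self.n_mirna, self.n_diseases) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i + 1:03d}" for i in range(self.n_tf)]

    @property
    def mirna_names(self) -> list[str]:
        return [f"miR-{i + 1:03d}" for i in range(self.n_mirna)]

    @property
    def disease_names(self) -> list[str]:
        return [f"disease_{i + 1:02d}" for i in range(self.n_diseases)]


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # one integer seed governs everything; per-table streams are spawned
    # from it so each generator function is independently reproducible
    return np.random.default_rng([spec.seed, stream])


def generate_network(spec: FixtureSpec, outdir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Draw the three typed edge tables.

    Each candidate ordered non-self pair of the appropriate types is
    kept independently with its kind's probability.  Returns a dict
    keyed by edge kind; with ``outdir`` also writes ``<kind>.tsv`` in
    the standard two-column dialect.
    """
    rng = _rng(spec, 0)
    candidates = {
        "tf_mirna": [(t, m) for t in spec.tf_names for m in spec.mirna_names],
        "tf_tf": [(a, b) for a in spec.tf_names for b in spec.tf_names if a != b],
        "mirna_tf": [(m, t) for m in spec.mirna_names for t in spec.tf_names],
    }
    probs = {"tf_mirna": spec.p_tf_mirna, "tf_tf": spec.p_tf_tf, "mirna_tf": spec.p_mirna_tf}
    tables: dict[str, pd.DataFrame] = {}
    for kind in ("tf_mirna", "tf_tf", "mirna_tf"):  # fixed order for determinism
        pairs = candidates[kind]
        keep = rng.random(len(pairs)) < probs[kind]
        rows = [p for p, k in zip(pairs, keep) if k]
        tables[kind] = pd.DataFrame(rows, columns=["source_id", "target_id"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for kind, df in tables.items():
            df.to_csv(outdir / f"{kind}.tsv", sep="\t", index=False)
    return tables


def generate_annotations(spec: FixtureSpec, outdir: str | Path | None = None) -> pd.DataFrame:
    """Annotate each (element, disease) pair independently with
    probability ``annotation_prevalence``."""
    rng = _rng(spec, 1)
    rows = []
    elements = [(t, TF) for t in spec.tf_names] + [(m, MIRNA) for m in spec.mirna_names]
    for element, etype in elements:
        for disease in spec.disease_names:
            if rng.random() < spec.annotation_prevalence:
                rows.append((element, etype, disease))
    df = pd.DataFrame(rows, columns=["element_id", "element_type", "disease"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    return df


def generate_cooccurrence(
    spec: FixtureSpec, annotations: pd.DataFrame, outdir: str | Path | None = None
) -> pd.DataFrame:
    """Literature co-occurrence counts over the full element x disease
    universe, with annotated pairs drawing from the high-mean Poisson."""
    rng = _rng(spec, 2)
    annotated = {
        (e.casefold(), d.casefold())
        for e, d in zip(annotations["element_id"], annotations["disease"])
    }
    rows = []
    for element in spec.tf_names + spec.mirna_names:
        for disease in spec.disease_names:
            mean = (
                spec.cooc_mean_annotated
                if (element.casefold(), disease.casefold()) in annotated
                else spec.cooc_mean_background
            )
            rows.append((element, disease, int(rng.poisson(mean))))
    df = pd.DataFrame(rows, columns=["element_id", "disease", "count"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "cooccurrence.tsv", sep="\t", index=False)
    return df


def generate_all(spec: FixtureSpec, outdir: str | Path) -> None:
    """Write edge tables, annotations, and co-occurrence for one spec."""
    ann = generate_annotations(spec, outdir)
    generate_network(spec, outdir)
    generate_cooccurrence(spec, ann, outdir)


# -- published worked examples ---------------------------------------

_BREAST = ("Src", "miR-145", "MYC", "YBX1", "EGFR", "miR-21", "STAT3", "AKT1", "miR-181c")
_BREAST_UNANNOTATED = {"YBX1", "miR-181c"}
_LYMPHOMA = ("TP73", "miR-145", "MYC", "miR-15a", "MYB", "miR-155", "SPI1", "miR-338")
_LYMPHOMA_UNANNOTATED = {"MYB"}
_PTEN_SHARED = ("PTEN", "miR-21", "HNRNPK", "AR", "RARA", "RARB")
_PTEN_STARTS = ("NOTCH1", "miR-494", "miR-214")

_TYPES = {
    "Src": TF, "MYC": TF, "YBX1": TF, "EGFR": TF, "STAT3": TF, "AKT1": TF,
    "TP73": TF, "MYB": TF, "SPI1": TF, "NOTCH1": TF, "PTEN": TF,
    "HNRNPK": TF, "AR": TF, "RARA": TF, "RARB": TF,
}


def _node_type(name: str) -> str:
    return _TYPES.get(name, MIRNA if name.startswith("miR-") else TF)


def _edges_for_path(path: tuple[str, ...], provenance: str) -> list[RegulatoryEdge]:
    kind_of = {v: k for k, v in EDGE_KINDS.items()}
    edges = []
    for src, tgt in zip(path, path[1:]):
        kind = kind_of[(_node_type(src), _node_type(tgt))]
        edges.append(RegulatoryEdge(src, tgt, kind, provenance))
    return edges


@dataclass
class WorkedExamples:
    """Case-study cascades with their disease annotations."""

    breast_cascade: tuple[str, ...]
    lymphoma_cascade: tuple[str, ...]
    pten_trio: list[tuple[str, ...]]
    annotations: DiseaseAnnotationMap

    @property
    def all_cascades(self) -> list[tuple[str, ...]]:
        return [self.breast_cascade, self.lymphoma_cascade, *self.pten_trio]

    def edge_tables(self) -> dict[str, str]:
        """The cascades' consecutive edges as the three TSV tables."""
        edges: list[RegulatoryEdge] = []
        for c in self.all_cascades:
            edges.extend(_edges_for_path(c, "worked-example"))
        out = {}
        for kind in EDGE_KINDS:
            rows = [f"{e.source_id}\t{e.target_id}" for e in edges if e.edge_kind == kind]
            out[kind] = "source_id\ttarget_id\n" + "".join(r + "\n" for r in dict.fromkeys(rows))
        return out

    def annotation_table(self) -> str:
        rows = ["element_id\telement_type\tdisease"]
        for c, disease, missing in (
            (self.breast_cascade, "breast cancer", _BREAST_UNANNOTATED),
            (self.lymphoma_cascade, "lymphoma", _LYMPHOMA_UNANNOTATED),
            (self.pten_trio[0], "breast cancer", set()),
        ):
            for e in c:
                if e not in missing:
                    rows.append(f"{e}\t{_node_type(e)}\t{disease}")
        for start in _PTEN_STARTS:
            rows.append(f"{start}\t{_node_type(start)}\tbreast cancer")
        return "\n".join(dict.fromkeys(rows)) + "\n"

    def network(self):
        return build_network([_edges_for_path(c, "worked-example") for c in self.all_cascades])


def worked_examples() -> WorkedExamples:
    """Bundle the published case-study fixtures.

    The breast-cancer cascade has 7 of 9 elements annotated (all but
    YBX1 and miR-181c), giving DAR 7/9 = 77.8% and score
    1 + 1/2 + 1/3 + 1/5 + 1/6 + 1/7 + 1/8 ≈ 2.468.  The lymphoma cascade
    has 7 of 8 annotated (all but MYB): DAR 87.5%.  The PTEN trio shares
    positions 2..7 and differs only at the first element, forming one
    begin-cluster of three cascades.
    """
    ann = DiseaseAnnotationMap()
    for e in _BREAST:
        if e not in _BREAST_UNANNOTATED:
            ann.add(e, _node_type(e), "breast cancer")
    for e in _LYMPHOMA:
        if e not in _LYMPHOMA_UNANNOTATED:
            ann.add(e, _node_type(e), "lymphoma")
    trio = [(start, *_PTEN_SHARED) for start in _PTEN_STARTS]
    for c in trio:
        for e in c:
            ann.add(e, _node_type(e), "breast cancer")
    return WorkedExamples(
        breast_cascade=_BREAST,
        lymphoma_cascade=_LYMPHOMA,
        pten_trio=trio,
        annotations=ann,
    )
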
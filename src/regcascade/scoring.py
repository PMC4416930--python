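"""Disease annotation and cascade scoring.

Two complementary measures relate a cascade to a disease:

* **DAR** (disease annotation ratio) — the fraction DEN/EN of cascade
  elements annotated to the disease; position-blind.
* **score** — the sum of reciprocal 1-based positions of the
  disease-related elements, Σ 1/location(nᵢ).  Upstream regulators are
  assumed more informative about aetiology, so a hit at position 1
  contributes 1, at position 2 contributes 1/2, and so on.

Cascades with a high DAR suggest that their few unannotated elements are
themselves disease-related; those (element, disease) pairs are exported
as novel predictions with their supporting cascades.

Disease names are matched case-insensitively after trimming; no
ontology mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from regcascade.cascades import SEP, CascadeSet, Path_
from regcascade.network import _as_lines


class DiseaseAnnotationMap:
    """element -> set of disease names, with element types.

    Both element ids and disease names are matched case-insensitively
    (first-seen casing preserved for display).
    """

    def __init__(self) -> None:
        self._diseases: dict[str, set[str]] = {}  # element key -> disease keys
        self._etype: dict[str, str] = {}
        self._display: dict[str, str] = {}  # casefolded -> display (elements + diseases)

    def _intern(self, raw: str) -> str:
        key = raw.casefold()
        self._display.setdefault(key, raw)
        return key

    def add(self, element_id: str, element_type: str, disease: str, origin: str = "?") -> None:
        ek = self._intern(element_id.strip())
        dk = self._intern(disease.strip())
        prev = self._etype.get(ek)
        if prev is not None and prev != element_type:
            raise ValueError(
                f"element {self._display[ek]!r} typed {prev} and {element_type} "
                f"across annotation tables ({origin})"
            )
        self._etype[ek] = element_type
        self._diseases.setdefault(ek, set()).add(dk)

    def is_related(self, element_id: str, disease: str) -> bool:
        return disease.strip().casefold() in self._diseases.get(element_id.strip().casefold(), ())

    def diseases_of(self, element_id: str) -> set[str]:
        return {self._display[d] for d in self._diseases.get(element_id.strip().casefold(), ())}

    def element_type(self, element_id: str) -> str | None:
        return self._etype.get(element_id.strip().casefold())

    @property
    def elements(self) -> list[str]:
        return sorted(self._display[e] for e in self._diseases)

    @property
    def diseases(self) -> list[str]:
        return sorted({self._display[d] for ds in self._diseases.values() for d in ds})

    def __len__(self) -> int:
        return len(self._diseases)


def load_annotations(
    tf_stream: str | Path | TextIO, mirna_stream: str | Path | TextIO | None = None
) -> DiseaseAnnotationMap:
    """Read element–disease TSVs (``element_id<TAB>element_type<TAB>disease``).

    TF and miRNA annotations may come as two files or one merged file.
    Duplicate (element, disease) rows collapse; an element typed both TF
    and miRNA raises ``ValueError``.
    """
    ann = DiseaseAnnotationMap()
    for stream in (tf_stream, mirna_stream):
        if stream is None:
            continue
        lines, name = _as_lines(stream)
        for lineno, line in enumerate(lines, start=1):
            if lineno == 1 or not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{name}: line {lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            element, etype, disease = (f.strip() for f in fields)
            if etype not in ("TF", "miRNA"):
                raise ValueError(f"{name}: line {lineno}: unknown element_type {etype!r}")
            ann.add(element, etype, disease, origin=f"{name}:{lineno}")
    return ann


def related_flags(cascade: Sequence[str], disease: str, ann: DiseaseAnnotationMap) -> tuple[bool, ...]:
    return tuple(ann.is_related(e, disease) for e in cascade)


def dar(cascade: Sequence[str], disease: str, ann: DiseaseAnnotationMap) -> float:
    """Disease annotation ratio DEN/EN in [0, 1]."""
    flags = related_flags(cascade, disease, ann)
    return sum(flags) / len(flags)


def score(cascade: Sequence[str], disease: str, ann: DiseaseAnnotationMap) -> float:
    """Location-weighted score Σ 1/position over disease-related elements."""
    return sum(
        1.0 / pos
        for pos, related in enumerate(related_flags(cascade, disease, ann), start=1)
        if related
    )


@dataclass
class DiseaseCascadeScore:
    """Per-(cascade, disease) association record."""

    cascade_id: str
    cascade: Path_
    disease: str
    related_flags: tuple[bool, ...]
    dn: int  # distinct diseases with >=1 annotated element on the cascade

    @property
    def en(self) -> int:
        return len(self.cascade)

    @property
    def den(self) -> int:
        return sum(self.related_flags)

    @property
    def dar(self) -> float:
        return self.den / self.en

    @property
    def score(self) -> float:
        return sum(1.0 / p for p, rel in enumerate(self.related_flags, start=1) if rel)


def annotate_cascades(
    cs: CascadeSet,
    ann: DiseaseAnnotationMap,
    diseases: Iterable[str] | None = None,
) -> list[DiseaseCascadeScore]:
    """One record per (cascade, disease) with at least one related element.

    Sorted by score then DAR (both descending), ties broken
    lexicographically by cascade element sequence then disease.
    """
    wanted = None if diseases is None else {d.strip().casefold() for d in diseases}
    records: list[DiseaseCascadeScore] = []
    for cid, cascade in cs.with_ids():
        hit: dict[str, tuple[bool, ...]] = {}
        for disease in sorted(set().union(*(ann.diseases_of(e) for e in cascade)) if cascade else ()):
            flags = related_flags(cascade, disease, ann)
            if any(flags):
                hit[disease] = flags
        dn = len(hit)
        for disease, flags in hit.items():
            if wanted is not None and disease.casefold() not in wanted:
                continue
            records.append(DiseaseCascadeScore(cid, cascade, disease, flags, dn))
    records.sort(key=lambda r: (-r.score, -r.dar, r.cascade, r.disease))
    return records


def retrieve_high_dar(
    records: Iterable[DiseaseCascadeScore], threshold: float = 0.8
) -> list[DiseaseCascadeScore]:
    """Records with DAR strictly greater than ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    return [r for r in records if r.dar > threshold]


def n_distinct_cascades(records: Iterable[DiseaseCascadeScore]) -> int:
    """Number of distinct cascades among records (a cascade passing for
    several diseases counts once)."""
    return len({r.cascade for r in records})


@dataclass
class NovelPair:
    """Predicted (element, disease) association absent from the annotations."""

    element_id: str
    element_type: str
    disease: str
    supporting: list[tuple[str, float]] = field(default_factory=list)  # (cascade_id, DAR)


def extract_novel_pairs(
    high_dar_records: Iterable[DiseaseCascadeScore],
    ann: DiseaseAnnotationMap,
    net=None,
) -> list[NovelPair]:
    """Unannotated elements of high-DAR records as novel predictions.

    Each element with a False related flag in a (cascade, disease)
    record becomes a candidate pair; candidates are deduplicated across
    cascades, accumulating supporting (cascade_id, DAR) evidence.
    Element types come from the annotation map, falling back to the
    network's node typing for never-annotated elements.
    """
    found: dict[tuple[str, str], NovelPair] = {}
    for rec in high_dar_records:
        for element, related in zip(rec.cascade, rec.related_flags):
            if related:
                continue
            etype = ann.element_type(element)
            if etype is None and net is not None:
                etype = net.node_type(element)
            key = (element.casefold(), rec.disease.casefold())
            pair = found.setdefault(key, NovelPair(element, etype or "?", rec.disease))
            pair.supporting.append((rec.cascade_id, rec.dar))
    return sorted(found.values(), key=lambda p: (p.disease.casefold(), p.element_id.casefold()))


# -- TSV interfaces ---------------------------------------------------


def write_scores_tsv(records: Iterable[DiseaseCascadeScore], path: str | Path) -> None:
    """``cascade_id  disease  EN  DEN  DAR  score  flags`` (flags = 0/1 string).

    DAR is printed as a percentage with 1 decimal and the score with 3
    decimals (round-half-even); full precision is kept in memory.
    """
    with Path(path).open("w") as fh:
        fh.write("cascade_id\tdisease\tEN\tDEN\tDAR\tscore\tflags\n")
        for r in records:
            flags = "".join("1" if f else "0" for f in r.related_flags)
            fh.write(
                f"{r.cascade_id}\t{r.disease}\t{r.en}\t{r.den}\t"
                f"{100 * r.dar:.1f}\t{r.score:.3f}\t{flags}\n"
            )


def write_novel_tsv(pairs: Iterable[NovelPair], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("element_id\telement_type\tdisease\tn_supporting\tsupporting\n")
        for p in pairs:
            support = ",".join(f"{cid}:{100 * d:.1f}" for cid, d in p.supporting)
            fh.write(f"{p.element_id}\t{p.element_type}\t{p.disease}\t{len(p.supporting)}\t{support}\n")
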
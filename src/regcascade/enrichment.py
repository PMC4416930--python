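"""Hypergeometric validation of predicted pairs against literature evidence.

Predictions are compared with a reference set of "reliable" (element,
disease) pairs — those co-occurring in strictly more than a threshold
number of publications (PubMatrix-style counts).  Over-representation of
the overlap within a finite pair universe of size N is assessed with the
upper-tail hypergeometric probability P(X >= k), computed in log space;
the exclusive tail P(X > k) is also reported for comparison.  The test
is symmetric in the two sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd
from scipy.stats import hypergeom

from regcascade.network import _as_lines

Pair = tuple[str, str]  # (element_id, disease), casefolded for matching


def _norm_pair(element: str, disease: str) -> Pair:
    return (element.strip().casefold(), disease.strip().casefold())


def read_cooccurrence(stream: str | Path | TextIO) -> pd.DataFrame:
    """Read ``element_id<TAB>disease<TAB>count`` into a DataFrame.

    One row per (element, disease); duplicate pairs or negative counts
    raise ``ValueError`` naming the line.
    """
    lines, name = _as_lines(stream)
    rows = []
    seen: set[Pair] = set()
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{name}: line {lineno}: expected 3 columns, got {len(fields)}")
        element, disease, raw = (f.strip() for f in fields)
        try:
            count = int(raw)
        except ValueError:
            raise ValueError(f"{name}: line {lineno}: count {raw!r} is not an integer") from None
        if count < 0:
            raise ValueError(f"{name}: line {lineno}: negative count {count}")
        key = _norm_pair(element, disease)
        if key in seen:
            raise ValueError(f"{name}: line {lineno}: duplicate pair ({element}, {disease})")
        seen.add(key)
        rows.append((element, disease, count))
    return pd.DataFrame(rows, columns=["element_id", "disease", "count"])


def reliable_pairs(table: pd.DataFrame, min_count: int = 100) -> set[Pair]:
    """Pairs with literature count strictly greater than ``min_count``."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    hit = table[table["count"] > min_count]
    return {_norm_pair(e, d) for e, d in zip(hit["element_id"], hit["disease"])}


def build_background(diseases: Iterable[str], elements: Iterable[str]) -> tuple[int, set[Pair]]:
    """Cartesian pair universe; N = |diseases| x |elements|."""
    ds = {d.strip().casefold() for d in diseases}
    es = {e.strip().casefold() for e in elements}
    if not ds or not es:
        raise ValueError("diseases and elements must be non-empty")
    universe = {(e, d) for e in es for d in ds}
    return len(universe), universe


@dataclass
class EnrichmentResult:
    """Hypergeometric overlap summary.

    N draws universe, K predicted pairs, n reference pairs, k overlap;
    ``p_value`` = P(X >= k) (inclusive upper tail),
    ``p_value_exclusive`` = P(X > k).
    """

    N: int
    K: int
    n: int
    k: int
    p_value: float
    p_value_exclusive: float

    def as_dict(self) -> dict:
        return {
            "N": self.N,
            "K": self.K,
            "n": self.n,
            "k": self.k,
            "p_value": self.p_value,
            "p_value_exclusive": self.p_value_exclusive,
        }


def hypergeom_overlap_test(
    N: int, predicted: Iterable[Pair], reference: Iterable[Pair]
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of the overlap between two pair sets.

    Symmetric in ``predicted``/``reference``; reported fields follow
    K = |predicted|, n = |reference|.
    """
    pred = set(predicted)
    ref = set(reference)
    if len(pred | ref) > N:
        raise ValueError(f"sets cover {len(pred | ref)} pairs but background N = {N}")
    k = len(pred & ref)
    # survival function of the hypergeometric; log-gamma based internally
    p_incl = float(hypergeom.sf(k - 1, N, len(pred), len(ref)))
    p_excl = float(hypergeom.sf(k, N, len(pred), len(ref)))
    return EnrichmentResult(N=N, K=len(pred), n=len(ref), k=k,
                            p_value=min(p_incl, 1.0), p_value_exclusive=min(p_excl, 1.0))
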
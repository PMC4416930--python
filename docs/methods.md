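# Methods

## Model and procedure

The object of study is a directed, typed regulatory network. Nodes are
transcription factors (TFs) or microRNAs (miRNAs); edges come from three
curated tables and each edge kind fixes its endpoint types: `tf_mirna`
(TF → miRNA), `tf_tf` (TF → TF), `mirna_tf` (miRNA → TF). miRNA → miRNA
regulation is not represented, matching the curated sources the format
emulates. Edges are deduplicated on the ordered (source, target) pair;
identifiers are matched case-insensitively after trimming, with the
first-seen casing kept for display, because curated symbol tables mix
casings. Self-loops are dropped with a warning rather than rejected: a
self-loop can never appear inside a simple path, so it cannot affect any
downstream result. An id claimed as both TF and miRNA across tables is a
hard error naming both provenances.

**Cascades.** A cascade is a simple directed path with at least three
elements (`EN ≥ 3`). All simple paths are enumerated by depth-first
backtracking from every node; the enumerated *set* is
traversal-order-independent, so the choice of traversal is an
implementation detail, not part of the contract. Any path whose element
sequence occurs as a contiguous, order-preserving run inside another
path is then filtered out ("completely contained"), leaving the maximal
cascade set. Containment is taken as contiguous because a path's
sub-paths are contiguous; a gapped-subsequence alternative
(`--containment gapped`) is provided since curated pipelines are not
explicit on this point, and gapped filtering is strictly more
aggressive, so the two modes bracket the possible cascade counts.
Filtering against the full enumerated set equals filtering against the
retained set for contiguous containment (a witness of containment is
itself contained in some retained path). Output order is lexicographic
on the element sequence; cascade ids are positional within that order,
so reruns on identical input are byte-identical.

**Clusters.** Equal-length cascades that differ only at position 1 form
a begin-cluster (shared segment = positions 2..L); those differing only
at position L form an end-cluster (shared segment = positions 1..L−1).
Groups of one are not clusters. Variation is per-cluster at exactly one
site, so a cascade can belong to at most one cluster of each kind. An
`--interior-key` mode implements the looser reading in which both ends
may vary within one cluster (key = positions 2..L−1); merging each
begin/end pair can only reduce the cluster count, so the modes again
bracket. Cluster ids are deterministic hashes of (site, shared segment).
The merged rendering prints the shared segment with `…` at the varying
site; members reconstruct exactly from the rendering plus the variant
list.

**Disease scoring.** Annotations map elements to free-text disease
names, matched case-insensitively after trimming; no ontology mapping is
attempted, mirroring how free-text disease names are matched across
curated gene- and miRNA-disease resources. For a cascade and disease,
`DEN` is the number of related elements, `DAR = DEN/EN`, and
`score = Σ 1/position` over related 1-based positions. The score is
position-sensitive by design — a hit at position 1 contributes 1, at
position `i` contributes `1/i` — encoding the assumption that upstream
regulators matter more for aetiology. `DN` counts distinct diseases with
at least one annotated element on the cascade. Scores are kept at full
float precision internally; display rounds the score half-even to 3
decimals and DAR to one decimal as a percentage. Result listings sort by
score then DAR (descending), with lexicographic tie-breaks, since no
canonical tie rule exists.

**Novel pairs and validation.** High-DAR retrieval keeps records with
DAR *strictly* above the threshold (default 0.8); both the record count
and the distinct-cascade count are reported, since either convention is
defensible. Every unannotated element of a retained (cascade, disease)
record becomes a candidate (element, disease) pair, deduplicated across
cascades with supporting (cascade id, DAR) evidence, and partitioned
into TF and miRNA pairs. Validation compares predictions with
literature co-occurrence counts: pairs in strictly more than
`min_cooccurrence` publications (default 100) are reliable. With a
background universe of N = |diseases| × |elements| pairs, the overlap k
between the predicted (K) and reliable (n) sets is assessed by the
inclusive upper tail P(X ≥ k) of the hypergeometric distribution —
the standard over-representation convention — computed via scipy's
log-gamma-based survival function so that N ≈ 10⁴ is exact to working
precision; the exclusive tail P(X > k) is reported alongside for
comparison. The test is symmetric in the two sets; reported fields
follow K = predicted, n = reference. No multiple-testing correction is
applied: the validation is a single global test.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_length` | 3 | minimum cascade elements (EN); the definition of a cascade |
| `max_length` | unbounded | optional EN cap to tame dense graphs |
| `max_paths` | 5·10⁶ | enumeration ceiling; exceeding it raises with advice |
| `containment` | `contiguous` | sub-path containment; `gapped` = subsequence |
| `interior_key` | off | cluster on interior segment (both ends may vary) |
| `dar_threshold` | 0.8 | strict lower bound for high-DAR retrieval |
| `min_cooccurrence` | 100 | strict lower bound for reliable literature pairs |

All thresholds are strict (`>`), matching the conventions the defaults
come from.

## Synthetic data

The fixture generator draws each candidate ordered non-self pair of the
appropriate type independently with its kind's probability
(Erdős–Rényi per kind), annotates each (element, disease) pair
independently with `annotation_prevalence`, and draws co-occurrence
counts Poisson(`cooc_mean_annotated` = 400) for annotated pairs and
Poisson(`cooc_mean_background` = 20) otherwise, so annotated pairs
exceed the reliability threshold of 100 essentially always and
unannotated ones essentially never. This plants a positive control: the
overlap between annotation-derived pairs and reliable pairs should test
as enriched, which the suite verifies across 100 seeds. One integer
seed governs all randomness; the three generator functions use fixed
per-table streams spawned from it, so each is independently
reproducible and a full run is byte-identical under the same spec.

The generator reproduces the *shape* of curated inputs, not their
statistics: it makes no attempt to match the degree distribution,
component structure, or annotation sparsity of real curated networks.
Passing tests therefore demonstrate correctness of the operations and
their invariants, not that real-data global counts (tens of thousands
of cascades, specific mean lengths) would be reproduced; those depend
on the actual curated tables, which the tool consumes but does not
ship. The defaults used in the test suite (networks of roughly 12–50
nodes, 4–6 diseases, prevalence 0.2–0.3) keep brute-force oracle
comparison exact and fast.

Three published case-study fixtures are packaged as parsed objects with
matching annotation and edge tables: the 9-element breast-cancer
cascade (7 annotated elements → DAR 77.8%, score 2.468), the 8-element
lymphoma cascade (7 annotated → DAR 87.5%), and the trio of 7-element
cascades sharing positions 2..7 that forms one begin-cluster of three.

## Numerical and design choices

- Score bounds: `0 ≤ score ≤ H(EN)` (the EN-th harmonic number), with
  `score = 0 ⇔ DAR = 0`; `DAR·EN` is always an integer (= DEN). Both are
  asserted as properties.
- The hypergeometric tail is validated against exact integer PMF
  summation (`math.comb` over `Fraction`) for all N ≤ 60 at 12
  significant digits.
- Path enumeration is validated against two independent oracles:
  exhaustive vertex-sequence checking on tiny graphs and per-pair
  simple-path search (networkx) on 200 seeded 12-node graphs; the
  containment filter against a naive pairwise scan; clustering against
  brute-force pairwise grouping.
- Degenerate inputs: an empty network yields all-zero statistics and an
  empty cascade file with exit 0; an empty cascade set has an undefined
  (None) mean length rather than NaN; enrichment is skipped with a
  manifest note when either set is empty.
- The pipeline manifest records tool version, configuration, input
  checksums (SHA-256), per-stage counts, and artifact checksums, so
  discrepancies against external expectations are visible rather than
  hidden and identical inputs reproduce byte-identical artifacts.

## Limitations

- Global counts from full curated datasets are sensitive to the exact
  containment and cluster-membership semantics; the bracketing modes
  expose this rather than resolving it.
- Free-text disease matching will split synonymous disease names; an
  alias table handles identifier synonymy but no ontology reasoning is
  done.
- Path enumeration is exponential in the worst case; the ceiling and
  `max_length` guard it, but very dense networks require bounding.
- Feed-forward/feedback loop motifs, weighted path scoring, and any
  web/database front end are out of scope.
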
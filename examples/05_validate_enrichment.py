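"""Validate predictions with the hypergeometric overlap test.

Reproduces the published validation setting: a background universe of
21 diseases x 304 regulators = 6384 pairs, 689 predicted novel pairs,
514 literature-reliable pairs (co-occurrence count > 100), and an
overlap of 93.
"""

from regcascade import build_background, hypergeom_overlap_test

N, universe = build_background([f"d{i}" for i in range(21)], [f"e{i}" for i in range(304)])
pairs = sorted(universe)
predicted = set(pairs[:689])
reference = set(pairs[:93]) | set(pairs[689 : 689 + 514 - 93])

result = hypergeom_overlap_test(N, predicted, reference)
print(f"background N = {result.N} pairs (21 diseases x 304 regulators)")
print(f"predicted K = {result.K}, reference n = {result.n}, overlap k = {result.k}")
print(f"P(X >= {result.k}) = {result.p_value:.3g}   (exclusive tail "
      f"P(X > {result.k}) = {result.p_value_exclusive:.3g})")
print("\nUnder random draws from the 6384-pair universe, an overlap of 93 is")
print("vanishingly unlikely (p ~ 1.5e-7): the predictions are strongly")
print("enriched for literature-supported disease associations.")
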
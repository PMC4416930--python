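"""Score cascades against diseases: DAR and the location-weighted score.

Uses the two published case-study cascades.  DAR = DEN/EN is the
fraction of cascade elements annotated to the disease; the score sums
1/position over the related elements, so upstream hits weigh more.
"""

from regcascade import dar, score, worked_examples

ex = worked_examples()

s = score(ex.breast_cascade, "breast cancer", ex.annotations)
d = dar(ex.breast_cascade, "breast cancer", ex.annotations)
print("breast-cancer cascade:", " -> ".join(ex.breast_cascade))
print(f"  DAR = {100 * d:.1f}%   score = {s:.3f}")

s2 = score(ex.lymphoma_cascade, "lymphoma", ex.annotations)
d2 = dar(ex.lymphoma_cascade, "lymphoma", ex.annotations)
print("lymphoma cascade:     ", " -> ".join(ex.lymphoma_cascade))
print(f"  DAR = {100 * d2:.1f}%   score = {s2:.3f}")

print("\n7 of 9 elements of the first cascade are breast-cancer annotated")
print("(all but YBX1 and miR-181c): DAR 77.8%, score 1 + 1/2 + 1/3 + 1/5 +")
print("1/6 + 1/7 + 1/8 = 2.468. The two unannotated elements riding such a")
print("high-DAR cascade become novel disease-association candidates.")
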
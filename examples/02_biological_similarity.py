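"""GO-annotation and protein-complex similarity on small hand-built inputs.

GO similarity is the information content of the most specific shared term:
-log(min term size / largest term size). Complex similarity sums, over
complexes containing both genes, density x internal-weight ratio.
"""

import math

import dignifi as dg

# Two genes share a term annotating only them; a 100-gene term sets S_max.
mapping = {"A": {"GO:SPECIFIC"}, "B": {"GO:SPECIFIC"}}
mapping.update({f"G{i}": {"GO:BROAD"} for i in range(100)})
annot = dg.GOAnnotationSet(mapping)
print("S_max:", annot.s_max)
print("SimGO(A, B):", dg.go_similarity(annot, "A", "B"),
      "= ln 50 =", math.log(50))
# Sharing a 2-gene term out of a corpus whose broadest term covers 100
# genes is highly informative; sharing only GO:BROAD would score 0.

toys = {desc: net for net, desc in dg.degenerate_cases()}
tri = toys["triangle"]
catalog = dg.ComplexCatalog.from_mapping({"CPX1": {"A", "B", "C"}})
print("isolated-triangle complex score:",
      dg.complex_score(tri, {"A", "B", "C"}))
# 1.0 — a fully wired complex with no boundary edges is maximally reliable.
print("SimCOM(A, B):", dg.complex_similarity(catalog, tri, "A", "B"))
# 1.0 — the one shared complex contributes its full reliability score.
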
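"""Topological similarity on tiny graphs: direct neighbors vs. local random walk.

Adjacent gene pairs are scored by their shared neighborhood (self-inclusive,
normalized by the larger node strength to penalize hubs); non-adjacent pairs
by a truncated t-step random walk.
"""

import dignifi as dg

toys = {desc: net for net, desc in dg.degenerate_cases()}

dyad = toys["isolated dyad"]
print("isolated dyad A-B, direct-neighbor score:",
      dg.dn_similarity(dyad, "A", "B"))
# 2.0 — both endpoints contribute 1 to the numerator; strengths are 1.

tri = toys["triangle"]
print("triangle edge A-B:", dg.topo_similarity(tri, "A", "B"))
# 3/sqrt(2) ~ 2.1213 — endpoints plus one shared neighbor, strengths 2.

path = toys["three-node path"]
print("path ends A..C, 2-step walk:", dg.topo_similarity(path, "A", "C", t=2))
# 0.5 — the walker starting at either end sits on the far end with
# probability 0.5 after two steps; both directions contribute (1/2)(0.5).

two = toys["two disconnected triangles"]
print("across components A..X:", dg.topo_similarity(two, "A", "X"))
# 0.0 — a t-step walker cannot cross components, so there is no evidence.

hub = toys["hub with six leaves and two chords"]
print("hub edge HUB-A:", dg.dn_similarity(hub, "HUB", "A"))
print("triangle edge for comparison:", dg.dn_similarity(tri, "A", "B"))
# same numerator (3) but the hub's strength 6 shrinks the score — the
# hub penalty keeps highly connected genes from dominating rankings.
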
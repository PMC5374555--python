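"""Enrich a curated PPI network with literature co-occurrence pairs.

Gene pairs co-mentioned in at least 30 articles are added as ordinary
binary interactions (weight 1.0); pairs already present are left alone.
"""

import dignifi as dg

bundle = dg.generate(dg.FixtureSpec())
net, cooc = bundle.network, bundle.cooccurrence

enriched = dg.enrich_with_cooccurrence(net, cooc, min_articles=30)
print(f"curated:  {net.n_nodes} genes, {net.n_edges} interactions")
print(f"enriched: {enriched.n_nodes} genes, {enriched.n_edges} interactions")
print(f"added {enriched.n_edges - net.n_edges} literature-derived edges")
# A denser network gives the walk more paths between related genes; on
# real data this raised ranking performance, at the cost of admitting
# co-mention pairs that are not physical interactions.
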
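"""Filter unreliable interactions and add missing ones by embedding similarity.

Weights every edge of a synthetic PPI network with the cosine similarity of
its endpoints' node embeddings, then sweeps a similarity threshold to show
how many edges filtering would remove and how many high-similarity new edges
augmentation would admit — the curves used to pick the operating threshold.
"""

import numpy as np

from ppicomplex import (Node2VecParams, RefinementConfig, SynthConfig,
                        augment_edges, filter_edges, generate, refine,
                        weight_edges)
from ppicomplex.embedding import embed_network

net, _, _ = generate(SynthConfig(seed=3))
emb = embed_network(net, Node2VecParams(), seed=3)
wnet = weight_edges(net, emb)

print("simi-thres  edges kept  edges added")
for thres in np.linspace(0.0, 0.9, 10):
    kept = filter_edges(wnet, thres).number_of_edges()
    added = augment_edges(net, emb, thres).number_of_edges() - net.number_of_edges()
    print(f"{thres:10.2f}  {kept:10d}  {added:11d}")

refined, report = refine(net, emb, RefinementConfig(filter_thres=0.6,
                                                    add_thres=0.6))
print(f"\nfilter at 0.6 then add at 0.6: removed {report['n_edges_removed']}, "
      f"added {report['n_edges_added']}; "
      f"{report['n_edges_in']} -> {report['n_edges_out']} edges")
# low-similarity edges are the likely false positives of the assay; the most
# similar non-neighbor of each protein is a candidate missing interaction.
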
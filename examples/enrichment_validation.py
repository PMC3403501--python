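"""Validate clusters against an annotation collection with a random baseline.

Builds a small synthetic annotation collection (200-gene universe, a few
gene sets), one cluster whose host genes sit inside one term and one
random cluster, and compares hypergeometric enrichment of the real
clusters against size-matched random gene sets.
"""

import numpy as np

from cosplice import (
    AnnotationCollection,
    FrequentCoSplicingCluster,
    baseline_fold_ratio,
    enrich_clusters,
)

rng = np.random.default_rng(1)
universe = sorted(f"g{i:03d}" for i in range(200))
terms = {
    f"T{j}": frozenset(rng.choice(universe, size=15, replace=False))
    for j in range(10)
}
terms["splicing_term"] = frozenset(f"g{i:03d}" for i in range(8))
collection = AnnotationCollection(
    name="functional",
    terms=terms,
    universe=frozenset(universe),
    p_threshold=0.01,
    max_term_size=300,
)

# cluster 0: five exons whose host genes all lie in splicing_term
# cluster 1: five exons with arbitrary host genes
exon_to_gene = {f"c0_e{i}": f"g{i:03d}" for i in range(5)}
exon_to_gene.update({f"c1_e{i}": f"g{g:03d}" for i, g in enumerate((17, 63, 121, 154, 190))})
nets = frozenset({"d1", "d2", "d3"})
clusters = [
    FrequentCoSplicingCluster(frozenset(f"c0_e{i}" for i in range(5)), nets, 0.6),
    FrequentCoSplicingCluster(frozenset(f"c1_e{i}" for i in range(5)), nets, 0.5),
]

for res in enrich_clusters(clusters, exon_to_gene, collection):
    if res.enriched:
        print(f"{res.cluster_id} enriched in {res.term_id}: "
              f"overlap {res.overlap}/{res.cluster_size}, p = {res.p_value:.2e}")

pct_real, pct_random, fold = baseline_fold_ratio(
    clusters, exon_to_gene, collection, reps=500, seed=1
)
print(f"real clusters enriched: {pct_real:.1f}%  random: {pct_random:.1f}%  "
      f"fold ratio: {'undefined' if fold is None else f'{fold:.1f}'}")
print(
    "The coherent cluster is recovered (five of its genes sit in one small"
    " term, p << 0.01) while size-matched random gene sets rarely reach the"
    " threshold, so the fold ratio is large - the signature of biologically"
    " meaningful clusters."
)
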
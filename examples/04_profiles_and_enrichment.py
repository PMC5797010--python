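"""Cluster activity profiles and test target-class enrichment among hits.

The AUC activity matrix (compounds x cell lines; 0 = inactive) is clustered
hierarchically; compounds active in at least one line form the hit set for
a hypergeometric over-representation test of the annotated target classes.
A small q-value means that target class contributes more hits than expected
from its share of the screened, annotated library.
"""

import qscreen as q

series = q.make_dilution_series(46e-6, 11, 3)
library = q.generate_library(60, {"complete_full": 0.3, "inactive": 0.7},
                             seed=21)
plates = q.simulate_viability_screen(library, ["TC32", "RD", "SK-N-SH"],
                                     series, noise_cv=0.05, seed=22)
result = q.analyze_viability_screen(plates)

matrix = q.build_matrix(result.consensus, "auc")
clustering = q.hierarchical_cluster(matrix)
print(f"activity matrix: {matrix.shape[0]} compounds x {matrix.shape[1]} lines")
print("column (cell line) leaf order:", clustering.col_order)

active = set(result.consensus.loc[result.consensus.is_active, "compound_id"])
hits = sorted(active)
background = [r.compound_id for r in library]
targets = {r.compound_id: r.target_moa for r in library}
print(f"\n{len(hits)} hit compounds; enrichment over annotated background:")
for r in q.enrichment_test(hits, background, targets)[:5]:
    print(f"  {r.category:<24} k/K = {r.k}/{r.K}  p = {r.p_value:.3g}  "
          f"q = {r.q_value:.3g}")
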
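"""TSS dip detection and promoter GC content.

In the synthetic "knockout" condition, remodeler (SMARCA4) signal is focally
lost in a narrow central window at planted promoters. The dip ratio — mean
central (±250 bp) over mean flanking (±250..±2000 bp) signal — calls a dip
when below 0.5. Dip promoters are planted with CpG-island-like GC, so their
200 bp TSS GC content separates from the rest of the genome's promoters.
"""

import numpy as np

from bafkit import SimulationConfig, call_dips, gc_content, kruskal_wallis, simulate

sim = simulate(SimulationConfig(seed=4, n_genes=100, chrom_length=5_000_000))

calls = call_dips(sim.tracks["SMARCA4_ko"], sim.promoters, ratio_max=0.5)
truth = {g.gene_id: g.dip for g in sim.truth.genes}
n_called = sum(c.is_dip for c in calls)
n_true = sum(c.is_dip and truth[c.gene_id] for c in calls)
print(f"{n_called} dip promoters called, {n_true} match the planted truth")

gc = {p.gene_id: gc_content(sim.sequences, p, window=200) for p in sim.promoters}
dip_gc = [gc[c.gene_id] for c in calls if c.is_dip]
other_gc = [gc[c.gene_id] for c in calls if not c.is_dip]
kw = kruskal_wallis([dip_gc, other_gc])
print(f"GC at dip promoters: {np.mean(dip_gc):.3f}  "
      f"others: {np.mean(other_gc):.3f}  Kruskal-Wallis p = {kw.pvalue:.2e}")
# The dip set carries island-level GC (~0.65) against a ~0.42 baseline, so
# the rank test rejects decisively - the direction expected when remodeler
# loss concentrates at CpG-island promoters.
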
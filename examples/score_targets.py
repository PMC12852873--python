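"""Loop-weighted cumulative fusion/H2AK119ub target scores.

Builds a small synthetic genome where SAT-pattern promoters loop to distal
enhancers, filters loops at FDR < 0.05, and computes for each promoter the
summed fusion + H2AK119ub enrichment at TSS ± 2 kb (promoter component)
plus the loop-score-weighted enrichment over each distal anchor's 4 kb
window (distal component).
"""

from bafkit import SimulationConfig, cumulative_target_score, filter_loops, simulate

sim = simulate(SimulationConfig(seed=2, n_genes=100, chrom_length=5_000_000),
               with_sequence=False)
tracks = {k: sim.tracks[k] for k in ("fusion", "H2AK119ub")}
high_conf = filter_loops(sim.loops, fdr_max=0.05)
print(f"{len(high_conf)} high-confidence loops of {len(sim.loops)} called")

scored = []
for p, g in zip(sim.promoters, sim.truth.genes):
    ts = cumulative_target_score(p, high_conf, tracks)
    if ts.n_loops:
        scored.append((ts, g))

ts, g = scored[0]
print(f"{ts.gene_id} ({g.planted_class}): promoter={ts.promoter_component:.1f} "
      f"distal={ts.distal_component:.1f} total={ts.total:.1f} loops={ts.n_loops}")
print(f"truth-table analytic value: "
      f"{g.expected_promoter_score + g.expected_distal_score:.1f}")
# The two numbers agree exactly at zero track noise: the score is a linear
# functional of the track, so planted rectangle heights predict it in closed
# form. Promoters without loops score only their promoter component.
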
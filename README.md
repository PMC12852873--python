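# bafkit

Integrative downstream analysis for fusion-oncoprotein epigenomics in
synovial sarcoma models: combinatorial histone-mark classification of
promoters and enhancers, broad-vs-narrow fusion peak profiling at TSSs,
HiChIP loop-weighted target scoring, TSS dip detection with promoter GC
content, glycerol-gradient deconvolution of BAF-subtype abundances, and the
accompanying group statistics — all driven by a seeded synthetic-data
generator that plants known truth, so every stage is testable without any
sequencing data.

## Who this is for

Computational biologists working downstream of peak calling and loop
calling: the package consumes called peaks (narrowPeak/BED), signal tracks
(bedGraph), chromatin loops (BEDPE), TSS tables, FASTA and densitometry
TSVs. Read alignment, peak calling and loop calling are out of scope.

## The methods at its core

**Promoter signature classification.** A promoter window (TSS ± 2 kb)
carries a mark iff a called peak of that mark with q < 0.001 overlaps it.
Classes, in precedence order over the flags (H2AK119ub, H3K4me3, H3K27ac,
H3K27me3):

- `SAT_PATTERN` — ub⁺ K4me3⁺ K27ac⁺ K27me3⁻ (the fusion-target signature)
- `BIVALENT` — K4me3⁺ K27me3⁺
- `REPRESSED` — K27me3⁺ K4me3⁻
- `ACTIVE` — K4me3⁺ K27ac⁺

Distal enhancers require H3K4me1 and H3K27ac, split by H2AK119ub status.

**Loop-weighted target score.** For promoter *p* with high-confidence loops
(FDR < 0.05) to distal anchors *a* with loop scores *w*:

    score(p) = Σ_tracks [ S(TSS ± 2 kb) + Σ_loops w · S(anchor midpoint ± 2 kb) ]

with S(·) the summed per-base signal and tracks = {fusion, H2AK119ub}.

**Gradient deconvolution.** Subtype markers (BRD9→GBAF, DPF2→CBAF,
PBRM1→PBAF) are fitted as Gaussians over fractions 12–24; the observed
SMARCC1 profile is matched to the convex mixture Σ (pct_s/100)·φ_s by
exhaustive search over all 5,151 integer triples summing to 100, minimizing
the sum of squared differences. A log-scale residual bootstrap gives
percentile intervals.

**Dip detection.** dip_ratio = mean signal in TSS ± 250 bp over pooled mean
in the ±250..±2000 bp flanks; a promoter is a dip when the ratio is defined
(flanks above a noise floor) and < 0.5. GC content is the G+C fraction of
the 200 bp around the TSS.

**Statistics.** Welch's heteroscedastic t, Kruskal–Wallis with ties
correction, Dunn's post hoc with Bonferroni, Wilcoxon rank-sum (exact
enumeration for n ≤ 12), binned Pearson track correlation, caliper tumor
volume D·d²/2, area-weighted nuclear shape index, nuclear density per
500 µm².

## Worked example

```python
from bafkit import (SimulationConfig, simulate, signature_at,
                    classify_promoter, make_tss_window)

sim = simulate(SimulationConfig(seed=1, n_genes=100, chrom_length=5_000_000),
               with_sequence=False)
calls = {}
for p in sim.promoters:
    sig = signature_at(make_tss_window(p, 2000), sim.peaksets, q_max=1e-3)
    calls[p.gene_id] = classify_promoter(sig).value
correct = sum(calls[g.gene_id] == g.planted_class for g in sim.truth.genes)
print(f"recovered {correct}/{len(calls)} planted classes")
```

prints

```
recovered 100/100 planted classes
```

— at zero flip rate the signature rule recovers every planted class; with
flip rate ε the accuracy follows the exact closed-form confusion of the
rule set (see `bafkit.chromstate.expected_recovery`). The other
capabilities are walked through in `examples/` (one script each for
classification, target scoring, gradient deconvolution, dip/GC and the
statistics); for instance `examples/deconvolve_gradient.py` prints

```
best mixture (GBAF, CBAF, PBAF) = (55, 16, 29)%  sse = 1.76e-04
planted truth                   = (55, 15, 30)%
```

A thin CLI (`bafkit simulate | classify-promoters | profile-tss-peaks |
score-targets | detect-dips | gc-promoters | deconvolve-gradient | run-all`)
wraps the same library calls for shell use; `run-all` drives every stage
from one YAML config and writes per-stage TSVs plus a JSON run report.

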
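# Methods

This note records the models, conventions and open design choices behind
each stage, what the synthetic generator does and does not emulate, and the
numerical details a maintainer would need.

## Coordinates, formats and interval algebra

All coordinates are 0-based half-open, the native convention of
BED/narrowPeak/bedGraph/BEDPE; TSS tables are documented as 0-based.
narrowPeak q-values are −log10-scaled on disk and linear in memory; plain
BED rows receive enrichment 0 and q-value 0. Writers sort records
(chromosome lexicographic, then start) so identical inputs always produce
byte-identical files — the basis of the round-trip and idempotence tests.

A `SignalTrack` is a per-chromosome set of sorted, non-overlapping
`(start, end, value)` runs. Window queries sum value × overlap per run, so
they are exact and additive over partitions. A bedGraph does not know
chromosome lengths, so the track's "mean signal" (used for the dip noise
floor) is defined over covered bases only.

Replicate merging first rescales each track so its genome-wide sum equals
the mean of the input sums (read-depth normalization), then takes the
per-base arithmetic mean, treating bases a replicate does not cover as 0.
A zero-signal track cannot be depth-normalized and is rejected.

Blacklist filtering removes a peak on any overlap with a blacklist
interval — the strictest testable rule, matching common ENCODE-blacklist
practice.

## Promoter and enhancer classification

Mark presence is "some called peak with q < 0.001 (strict) overlapping the
TSS ± 2 kb window"; whether presence should instead require overlap of the
TSS itself is not derivable from the source material, so window overlap —
consistent with every other windowed computation here — was adopted. The
class rule is evaluated in precedence order SAT > bivalent > repressed >
active > unclassified; precedence only matters for flag combinations that
no named class enumerates (e.g. ub⁺ K4me3⁺ K27ac⁺ K27me3⁺ falls to
bivalent because K27me3 vetoes the SAT pattern). `ACTIVE`
(K4me3⁺ K27ac⁺ ub⁻) names the housekeeping-like (MAT) bucket. A mark whose
peak set was not assayed yields an unknown flag and the promoter is
`UNCLASSIFIED` rather than guessed.

Under independent per-flag flips with rate ε, the expected classification
accuracy has an exact closed form obtained by enumerating all 2⁴ flag
outcomes per planted class (`expected_recovery`); the simulator's measured
accuracy converges to it, which is the property the acceptance suite
checks.

Broad/narrow peak shape uses a configurable boundary, default 2,000 bp
(strict >): the bimodality is real but no printed cutoff exists, so the
default is a declared convention and a data-driven alternative
(1-D two-means on log widths, `split_widths_two_means`) is provided.

## Loop-weighted target scoring

Loops are filtered at FDR < 0.05 (strict). A loop is assigned to a promoter
iff exactly one anchor overlaps the TSS ± 2 kb window; the other anchor is
distal. Loops with both anchors in the window are degenerate (no distal
element) and dropped. Distal anchor windows are 4 kb centered on the anchor
midpoint — centering is a convention chosen so the window is independent of
the loop caller's native anchor width. The loop-score weight applies to the
distal term only; whether the H2AK119ub component should be weighted like
the fusion component is ambiguous in the source material, so both are
weighted identically by default with `weight_all_tracks=False` restricting
the weight to the fusion track. The score is linear in the track and
additive over loops; both properties are tested against brute-force
oracles.

## Gradient deconvolution

Only fractions 12–24 (where assembled BAF complexes sediment) enter the
fit. Component fitting is nonlinear least squares of amplitude·N(mean, sd)
with intensity-weighted moment initialization and a moment fallback on
non-convergence; both agree exactly on noise-free Gaussian input. A fitted
sd below 0.1 fractions is rejected as degenerate. Component densities are
renormalized to unit sum over fractions 12–24 before mixing, and the
observed SMARCC1 profile likewise, so the SSE compares probability-like
13-vectors and the estimate is invariant to uniform intensity rescaling.
The mixture search enumerates all 5,151 integer triples (grid step 1
percentage point), vectorized as a single matrix product; ties break
lexicographically on (GBAF, CBAF, PBAF) for determinism.

Bootstrap intervals resample the best fit's residuals on the **log** scale:
densitometry noise is multiplicative, so log-ratio residuals are the
exchangeable quantity, and resampling them preserves the
magnitude-proportional error structure (plain additive residual resampling
measurably undercovers). Intervals are percentile at 90% by default,
widened if necessary to contain the point estimate, and are zero-width on
noise-free input.

## Dip detection and GC

The source material shows the focal remodeler loss in heatmaps without a
quantitative rule, so the rule here is a declared stand-in with every
parameter exposed: dip_ratio = mean central (TSS ± 250 bp) over pooled mean
flanking (±250..±2000 bp) signal; a dip requires a defined ratio < 0.5
(strict). The ratio is undefined — no call, never a negative call — when
the flank mean is at or below a noise floor, default 10% of the track's
covered-base mean, preventing noise-over-noise ratios at unexpressed
promoters. The ratio is invariant to uniform track rescaling.

GC content is (G+C)/(A+C+G+T) over the 200 bp window centered on the TSS
(±100 bp), case-insensitive, with N and other ambiguity codes excluded from
both counts; an all-N window yields no call. G+C is complement-symmetric,
so the measure is strand-invariant.

## Statistics

Welch's t uses the Welch–Satterthwaite df; two identical constant samples
return t = 0, p = 1 by convention. Kruskal–Wallis always applies the
midrank ties correction (whether the original analyses did is unknowable;
correction is the conservative standard). Dunn's z uses pooled midranks
with the Σ(t³−t)/(12(N−1)) ties term and Bonferroni over all k(k−1)/2
pairs. Wilcoxon rank-sum switches to exact enumeration of all C(n, nₓ)
rank assignments when nₓ+nᵧ ≤ 12 — exactness where it is cheap — and
otherwise uses the normal approximation with ties and continuity
correction; the branches agree within 0.02 at the cutover. Binned Pearson
partitions the genome (or a supplied site list, e.g. remodeler binding
sites) into fixed bins and correlates per-bin summed signal.

Phenotype formulas: tumor volume D·d²/2 (mm³, D ≥ d enforced); nuclear
shape index Σ_regions fraction × mean(long/orthogonal over 3 nuclei);
nuclear density reported in the native unit (count per 500 µm² square) with
an explicit ×2000 conversion to mm⁻², avoiding silent unit drift.

## The synthetic generator

The generator emulates the *structure* of the real data — promoter classes
with their defining mark peaks, broad fusion/GBAF signal coincident with
H2AK119ub versus narrow CBAF/PBAF signal at TSSs, loops joining SAT
promoters to distal enhancers with decoys failing the FDR filter, planted
knockout dips, CpG-island GC at dip promoters, gradient mixtures with known
truth — not its texture: no mappability artifacts, no copy-number waves, no
read-level sampling, and signal is piecewise-constant rectangles rather
than realistic peak shapes. Passing tests therefore demonstrate
correctness of the computations on data with known truth, not robustness
to every artifact of real ChIP-seq.

Defaults (every value overridable): 2 chromosomes × 10 Mb, 300 genes, class
mix 0.2/0.2/0.2/0.4 (SAT/bivalent/repressed/active), broad fusion widths
lognormal with 6 kb median (capped at 20 kb), narrow 400 bp median, 2 loops
per SAT promoter at 20 kb spacing, 70% of enhancers H2AK119ub⁺, decoy
loops at 20% of the real count with FDR ≥ 0.05, gradient components at
fraction means 14/17/20 with sd 1.2 and true mixture (55, 15, 30)%, GC
baseline 0.42 versus island 0.65 over 600 bp, dip depth 0.8 (planted ratio
0.2). Flip rate and track noise default to 0 — the reference condition —
and gradient noise to 5%, the level used for the error-bound simulations.
TSSs sit on a fixed grid with spacing validated against the largest
possible peak and the enhancer span, so windows never collide and the
truth table's closed-form expected scores (height × overlap × loop score,
accumulated in the same per-track order as the scorer for bitwise
equality) are exact at zero noise. Noise models: Bernoulli flag flips for
peak calls, additive truncated-Gaussian per run for tracks, multiplicative
lognormal for densitometry — the simplest models matching each data type's
support. SAT-pattern promoters double as the dip/island set, mirroring
remodeler loss concentrating at CpG-island fusion-target promoters. One
seed (split via `SeedSequence.spawn`) fixes every emitted byte.

Morphometry emulates two tumor groups with shifted nuclear shape
(lognormal ratios, long ≥ orthogonal enforced) and density (Poisson); the
caliper table recomputes volume from the rounded reported diameters so the
emitted columns are internally consistent.

## Pipeline and problem sizes

`run_all` executes classify → profile → target scores → dips → GC →
deconvolution → statistics, validates every path before writing anything,
and emits per-stage TSVs plus a JSON report (record counts, parameter echo,
config hash excluding the output directory, version). Reruns are
byte-identical for fixed inputs and seed.

Test and acceptance runs use desk-scale sizes chosen as comfortable for a
laptop: the 300-gene default genome for recovery and scoring checks, 50
seeds × 300 genes for the flip-rate accuracy comparison, 100 random triples
plus 200 noisy replicates for the gradient, 2,000 replicates for null
type-I calibration, and 1,000-interval random sets for the quadratic
interval oracles.

## Known limitations

- The dip rule, the broad/narrow boundary and the anchor-window centering
  are declared conventions where the underlying study printed none; counts
  derived from them (e.g. the number of dip promoters) are not expected to
  match any particular published count.
- The gradient model assumes exactly three Gaussian components with
  subtype-specific markers as clean proxies; partially assembled complexes
  in fractions 1–11 are ignored by design.
- The exact Wilcoxon branch enumerates C(n, nₓ) combinations and is
  deliberately capped at n = 12.
- `signature_at` scans peak lists linearly per window — fine at desk scale;
  an interval index would be the first optimization for genome-scale peak
  sets.
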
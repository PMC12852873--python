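"""Seeded synthetic data with a planted truth table.

Generates everything the pipeline consumes — a small genome (FASTA + TSS
table), per-mark called peaks, fusion peaks, signal tracks, HiChIP-style
loops, gradient densitometry and morphometry tables — with every planted
feature recorded in a :class:`TruthTable`, so each downstream stage can be
checked against known truth without any sequencing data.

Design notes
------------
Promoters are placed on a fixed grid with spacing wide enough that TSS
windows and their looped enhancers never collide. Signal tracks are
piecewise-constant rectangles, so the expected window sums (and hence the
loop-weighted target scores) are exact closed-form products recorded in the
truth table. Class flags are flipped independently with rate ``flip_rate``
to emulate peak-calling error; tracks receive additive truncated-Gaussian
noise per run; densitometry receives multiplicative lognormal noise.

Promoters planted as SAT_PATTERN double as the dip/CpG-island set: in the
"knockout" remodeler track their central ±250 bp drops by ``dip_depth``,
and their TSS-proximal sequence carries island-level GC.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chromstate import PLANTED_SIGNATURES, PromoterClass
from .intervals import GenomicInterval, Peak, PromoterAnnotation, SignalTrack
from .loops import Loop

__all__ = ["SimulationConfig", "TruthTable", "Simulation", "simulate", "simulate_to_dir"]

_PROMOTER_MARKS = ("H2AK119ub", "H3K4me3", "H3K27ac", "H3K27me3")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, each with a desk-scale default."""

    seed: int = 0

    # genome
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 300
    class_mix: dict = field(default_factory=lambda: {
        "SAT_PATTERN": 0.2, "BIVALENT": 0.2, "REPRESSED": 0.2, "ACTIVE": 0.4,
    })
    mat_fraction_of_active: float = 0.5   # ACTIVE promoters labelled MAT
    sst_fraction_of_repressed: float = 0.5  # REPRESSED promoters labelled SST
    flank: int = 2000

    # peak calling emulation
    flip_rate: float = 0.0
    mark_peak_width: int = 1000
    broad_width_median: float = 6000.0
    broad_width_sigma: float = 0.3
    broad_width_max: int = 20000
    narrow_width_median: float = 400.0
    narrow_width_sigma: float = 0.3
    broad_enrich_shape: float = 2.0
    broad_enrich_scale: float = 5.0
    narrow_enrich_shape: float = 2.0
    narrow_enrich_scale: float = 25.0
    narrow_active_fraction: float = 0.5  # ACTIVE promoters with a narrow fusion peak

    # tracks
    track_noise_sd: float = 0.0
    dip_depth: float = 0.8
    promoter_rect_half: int = 1000
    enhancer_rect_half: int = 500
    dip_central_half: int = 250

    # loops
    loops_per_sat: int = 2
    enhancer_offset: int = 20000
    enhancer_ub_fraction: float = 0.7
    loop_score_median: float = 2.0
    loop_score_sigma: float = 0.5
    decoy_fraction: float = 0.2

    # sequence
    gc_baseline: float = 0.42
    gc_island: float = 0.65
    island_width: int = 600

    # gradient
    gradient_means: tuple = (14.0, 17.0, 20.0)
    gradient_sds: tuple = (1.2, 1.2, 1.2)
    gradient_amplitudes: tuple = (1000.0, 1500.0, 800.0)
    true_pct: tuple = (55, 15, 30)
    gradient_noise: float = 0.05

    # morphometry
    n_tumors_per_group: int = 6
    shape_means: tuple = (2.0, 1.3)
    shape_sigma: float = 0.12
    density_means: tuple = (40.0, 25.0)
    n_timepoints: int = 5

    def validate(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if sum(self.true_pct) != 100:
            raise ValueError("true_pct must sum to 100")
        spacing = self._spacing()
        need = 2 * (self.flank + self.broad_width_max)
        enh_extent = self.loops_per_sat * self.enhancer_offset + 2 * self.flank
        if spacing < max(need, enh_extent):
            raise ValueError(
                f"genes too dense: spacing {spacing} < required {max(need, enh_extent)}"
            )

    def _genes_per_chrom(self) -> list[int]:
        base = self.n_genes // self.n_chromosomes
        extra = self.n_genes % self.n_chromosomes
        return [base + (1 if i < extra else 0) for i in range(self.n_chromosomes)]

    def _spacing(self) -> int:
        per = max(self._genes_per_chrom())
        return self.chrom_length // (per + 1)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    gene_label: str
    planted_class: str
    dip: bool
    island: bool
    # per-loop: (enhancer_mid, loop_score, ub_positive)
    loops: list = field(default_factory=list)
    expected_promoter_score: float = 0.0  # fusion + ub, TSS ± flank
    expected_distal_score: float = 0.0    # Σ loop_score × (fusion + ub) enhancer sums


@dataclass
class TruthTable:
    genes: list[GeneTruth]
    true_pct: tuple[int, int, int]
    n_real_loops: int = 0
    n_decoy_loops: int = 0
    morphometry_groups: dict = field(default_factory=dict)

    def by_class(self, cls: str) -> list[GeneTruth]:
        return [g for g in self.genes if g.planted_class == cls]

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.genes:
            out[g.planted_class] = out.get(g.planted_class, 0) + 1
        return out

    def to_json(self) -> str:
        payload = {
            "true_pct": list(self.true_pct),
            "n_real_loops": self.n_real_loops,
            "n_decoy_loops": self.n_decoy_loops,
            "morphometry_groups": self.morphometry_groups,
            "genes": [dataclasses.asdict(g) for g in self.genes],
        }
        return json.dumps(payload, sort_keys=True, indent=1)


@dataclass
class Simulation:
    """In-memory bundle of everything one seeded simulation produced."""

    config: SimulationConfig
    promoters: list[PromoterAnnotation]
    sequences: dict[str, str]                 # chrom -> sequence (may be empty)
    peaksets: dict[str, list[Peak]]           # mark -> peaks
    fusion_peaks: list[Peak]
    tracks: dict[str, SignalTrack]
    loops: list[Loop]
    gradient: pd.DataFrame                    # marker × f1..f24
    morphometry: pd.DataFrame
    tumors: pd.DataFrame
    truth: TruthTable


def _largest_remainder(n: int, proportions: dict[str, float]) -> dict[str, int]:
    keys = list(proportions)
    raw = np.array([proportions[k] * n for k in keys])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(4, size=length, p=p).astype(np.uint8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate(cfg: SimulationConfig | None = None, with_sequence: bool = True) -> Simulation:
    """Run the full generator; one seed fixes every emitted value."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    (rng_genome, rng_peaks, rng_tracks, rng_loops,
     rng_gradient, rng_morpho, rng_seq) = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )

    # ---------------------------------------------------------- genome
    per_chrom = cfg._genes_per_chrom()
    spacing = cfg._spacing()
    counts = _largest_remainder(cfg.n_genes, cfg.class_mix)
    classes = [c for c, k in counts.items() for _ in range(k)]
    classes = [classes[i] for i in rng_genome.permutation(cfg.n_genes)]

    truth_genes: list[GeneTruth] = []
    promoters: list[PromoterAnnotation] = []
    gi = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        for j in range(per_chrom[ci]):
            tss = (j + 1) * spacing
            cls = classes[gi]
            strand = "+" if rng_genome.random() < 0.5 else "-"
            if cls == "SAT_PATTERN":
                label = "SAT"
            elif cls == "ACTIVE":
                label = "MAT" if rng_genome.random() < cfg.mat_fraction_of_active else "none"
            elif cls == "REPRESSED":
                label = "SST" if rng_genome.random() < cfg.sst_fraction_of_repressed else "none"
            else:
                label = "none"
            gene_id = f"gene{gi:04d}"
            is_sat = cls == "SAT_PATTERN"
            promoters.append(PromoterAnnotation(gene_id, chrom, tss, strand, label))
            truth_genes.append(GeneTruth(
                gene_id=gene_id, chrom=chrom, tss=tss, strand=strand,
                gene_label=label, planted_class=cls, dip=is_sat, island=is_sat,
            ))
            gi += 1

    sequences: dict[str, str] = {}
    if with_sequence:
        for ci in range(cfg.n_chromosomes):
            chrom = f"chr{ci + 1}"
            codes = _random_sequence(rng_seq, cfg.chrom_length, cfg.gc_baseline)
            half = cfg.island_width // 2
            for g in truth_genes:
                if g.chrom == chrom and g.island:
                    lo, hi = max(0, g.tss - half), min(cfg.chrom_length, g.tss + half)
                    codes[lo:hi] = _random_sequence(rng_seq, hi - lo, cfg.gc_island)
            sequences[chrom] = _BASES[codes].tobytes().decode()

    # ------------------------------------------------- enhancers & loops
    # planted before peaks so enhancer marks land in the peak files
    enh_ivs: list[tuple[GeneTruth, GenomicInterval, bool]] = []
    loops: list[Loop] = []
    for g in truth_genes:
        if g.planted_class != "SAT_PATTERN":
            continue
        for k in range(cfg.loops_per_sat):
            mid = g.tss + (k + 1) * cfg.enhancer_offset
            enh = GenomicInterval(
                g.chrom, mid - cfg.enhancer_rect_half, mid + cfg.enhancer_rect_half
            )
            ub_pos = rng_loops.random() < cfg.enhancer_ub_fraction
            score = float(np.exp(np.log(cfg.loop_score_median)
                                 + cfg.loop_score_sigma * rng_loops.standard_normal()))
            fdr = float(rng_loops.uniform(1e-6, 0.049))
            anchor1 = GenomicInterval(g.chrom, g.tss - 500, g.tss + 500)
            loops.append(Loop(anchor1, enh, score, fdr,
                              name=f"{g.gene_id}_loop{k}"))
            enh_ivs.append((g, enh, ub_pos))
            g.loops.append({"enhancer_mid": mid, "loop_score": score,
                            "ub_positive": ub_pos})
    n_real = len(loops)
    n_decoy = int(round(cfg.decoy_fraction * n_real))
    for k in range(n_decoy):
        ci = int(rng_loops.integers(cfg.n_chromosomes))
        chrom = f"chr{ci + 1}"
        a = int(rng_loops.integers(10_000, cfg.chrom_length - 60_000))
        b = a + int(rng_loops.integers(30_000, 50_000))
        score = float(np.exp(np.log(cfg.loop_score_median)
                             + cfg.loop_score_sigma * rng_loops.standard_normal()))
        fdr = float(rng_loops.uniform(0.05, 0.5))
        loops.append(Loop(GenomicInterval(chrom, a, a + 1000),
                          GenomicInterval(chrom, b, b + 1000),
                          score, fdr, name=f"decoy{k}"))

    # ---------------------------------------------------------- peaks
    peaksets: dict[str, list[Peak]] = {m: [] for m in _PROMOTER_MARKS + ("H3K4me1",)}
    half_mark = cfg.mark_peak_width // 2

    def _qval(rng):
        return float(rng.uniform(1e-6, 9.99e-4))

    for g in truth_genes:
        planted = dict(zip(_PROMOTER_MARKS, PLANTED_SIGNATURES[PromoterClass(g.planted_class)]))
        for mark in _PROMOTER_MARKS:
            present = planted[mark]
            if cfg.flip_rate > 0 and rng_peaks.random() < cfg.flip_rate:
                present = not present
            if present:
                iv = GenomicInterval(g.chrom, g.tss - half_mark, g.tss + half_mark)
                peaksets[mark].append(Peak(
                    iv, enrichment=float(rng_peaks.gamma(2.0, 4.0)),
                    qvalue=_qval(rng_peaks), name=f"{g.gene_id}_{mark}",
                ))
    for g, enh, ub_pos in enh_ivs:
        for mark, emit in (("H3K4me1", True), ("H3K27ac", True), ("H2AK119ub", ub_pos)):
            if emit:
                peaksets[mark].append(Peak(
                    enh, enrichment=float(rng_peaks.gamma(2.0, 4.0)),
                    qvalue=_qval(rng_peaks), name=f"{g.gene_id}_enh_{mark}",
                ))

    fusion_peaks: list[Peak] = []
    for g in truth_genes:
        if g.planted_class == "SAT_PATTERN":
            w = np.exp(np.log(cfg.broad_width_median)
                       + cfg.broad_width_sigma * rng_peaks.standard_normal())
            w = int(min(w, cfg.broad_width_max))
            enr = float(rng_peaks.gamma(cfg.broad_enrich_shape, cfg.broad_enrich_scale))
        elif (g.planted_class == "ACTIVE"
              and rng_peaks.random() < cfg.narrow_active_fraction):
            w = int(np.exp(np.log(cfg.narrow_width_median)
                           + cfg.narrow_width_sigma * rng_peaks.standard_normal()))
            enr = float(rng_peaks.gamma(cfg.narrow_enrich_shape, cfg.narrow_enrich_scale))
        else:
            continue
        iv = GenomicInterval(g.chrom, max(0, g.tss - w // 2), g.tss + w - w // 2)
        fusion_peaks.append(Peak(iv, enrichment=enr, qvalue=_qval(rng_peaks),
                                 name=f"{g.gene_id}_fusion"))

    # ---------------------------------------------------------- tracks
    prom_half = cfg.promoter_rect_half
    fus_runs, ub_runs, gbaf_runs, cbaf_runs, pbaf_runs = [], [], [], [], []
    wt_runs, ko_runs = [], []
    enh_by_gene: dict[str, list[tuple[GenomicInterval, bool]]] = {}
    for g, enh, ub_pos in enh_ivs:
        enh_by_gene.setdefault(g.gene_id, []).append((enh, ub_pos))

    for g in truth_genes:
        prom_iv = GenomicInterval(g.chrom, max(0, g.tss - prom_half), g.tss + prom_half)
        exp_prom = 0.0
        if g.planted_class == "SAT_PATTERN":
            h_fus = float(rng_tracks.gamma(3.0, 2.0)) + 1.0
            h_ub = float(rng_tracks.gamma(3.0, 1.5)) + 1.0
            fus_runs.append((prom_iv, h_fus))
            ub_runs.append((prom_iv, h_ub))
            gbaf_runs.append((prom_iv, h_fus * 0.8))
            exp_prom = prom_iv.width * h_fus + prom_iv.width * h_ub
            # accumulate the expected distal term per track, matching the
            # score's track-major summation order bit for bit
            exp_fus_distal = 0.0
            exp_ub_distal = 0.0
            for (enh, ub_pos), rec in zip(enh_by_gene.get(g.gene_id, []), g.loops):
                he_fus = float(rng_tracks.gamma(3.0, 2.0)) + 1.0
                he_ub = (float(rng_tracks.gamma(3.0, 1.5)) + 1.0) if ub_pos else 0.0
                fus_runs.append((enh, he_fus))
                gbaf_runs.append((enh, he_fus * 0.8))
                if ub_pos:
                    ub_runs.append((enh, he_ub))
                c_fus = enh.width * he_fus * rec["loop_score"]
                c_ub = enh.width * he_ub * rec["loop_score"]
                rec["expected_distal_contrib"] = c_fus + c_ub
                exp_fus_distal += c_fus
                exp_ub_distal += c_ub
            g.expected_distal_score = exp_fus_distal + exp_ub_distal
        g.expected_promoter_score = exp_prom

        if g.planted_class in ("SAT_PATTERN", "ACTIVE"):
            h_c = float(rng_tracks.gamma(3.0, 2.0)) + 1.0
            narrow_iv = GenomicInterval(g.chrom, max(0, g.tss - 250), g.tss + 250)
            cbaf_runs.append((narrow_iv, h_c))
            pbaf_runs.append((narrow_iv, h_c * 0.6))
            # remodeler occupancy: flat across TSS ± flank, focally lost in KO
            h_s = float(rng_tracks.gamma(3.0, 2.0)) + 2.0
            wt_iv = GenomicInterval(g.chrom, max(0, g.tss - cfg.flank), g.tss + cfg.flank)
            wt_runs.append((wt_iv, h_s))
            if g.dip:
                c0, c1 = g.tss - cfg.dip_central_half, g.tss + cfg.dip_central_half
                ko_runs.append((GenomicInterval(g.chrom, wt_iv.start, c0), h_s))
                ko_runs.append((GenomicInterval(g.chrom, c0, c1),
                                h_s * (1.0 - cfg.dip_depth)))
                ko_runs.append((GenomicInterval(g.chrom, c1, wt_iv.end), h_s))
            else:
                ko_runs.append((wt_iv, h_s))

    def _to_track(runs):
        if cfg.track_noise_sd > 0:
            noisy = []
            for iv, v in runs:
                nv = v + rng_tracks.normal(0.0, cfg.track_noise_sd)
                noisy.append((iv, max(nv, 0.0)))
            runs = noisy
        return SignalTrack(runs)

    tracks = {
        "fusion": _to_track(fus_runs),
        "H2AK119ub": _to_track(ub_runs),
        "GBAF": _to_track(gbaf_runs),
        "CBAF": _to_track(cbaf_runs),
        "PBAF": _to_track(pbaf_runs),
        "SMARCA4_wt": _to_track(wt_runs),
        "SMARCA4_ko": _to_track(ko_runs),
    }

    # --------------------------------------------------------- gradient
    gradient = simulate_gradient(cfg, rng_gradient)

    # ------------------------------------------------------ morphometry
    morphometry, tumors, groups = simulate_morphometry(cfg, rng_morpho)

    truth = TruthTable(
        genes=truth_genes, true_pct=tuple(cfg.true_pct),
        n_real_loops=n_real, n_decoy_loops=n_decoy,
        morphometry_groups=groups,
    )
    return Simulation(
        config=cfg, promoters=promoters, sequences=sequences,
        peaksets=peaksets, fusion_peaks=fusion_peaks, tracks=tracks,
        loops=loops, gradient=gradient, morphometry=morphometry,
        tumors=tumors, truth=truth,
    )


def simulate_gradient(cfg: SimulationConfig, rng=None) -> pd.DataFrame:
    """Densitometry table: subtype markers as Gaussians, SMARCC1 their mixture.

    Each marker row samples an amplitude-scaled Gaussian at fractions 1–24;
    the SMARCC1 row mixes the three component densities (each unit-sum over
    fractions 12–24) with the true percentage triple, so at zero noise the
    grid search recovers ``true_pct`` with zero SSE.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    x = np.arange(1, 25, dtype=float)
    rows = {}
    densities = []
    markers = ("BRD9", "DPF2", "PBRM1")
    for marker, mean, sd, amp in zip(markers, cfg.gradient_means,
                                     cfg.gradient_sds, cfg.gradient_amplitudes):
        pdf = norm.pdf(x, loc=mean, scale=sd)
        rows[marker] = amp * pdf
        densities.append(pdf / pdf[11:24].sum())
    mix = sum((p / 100.0) * d for p, d in zip(cfg.true_pct, densities))
    rows["SMARCC1"] = 1000.0 * mix
    df = pd.DataFrame(rows).T
    df.columns = [f"f{i}" for i in range(1, 25)]
    df.index.name = "marker"
    if cfg.gradient_noise > 0:
        noise = np.exp(rng.normal(0.0, cfg.gradient_noise, size=df.shape))
        df = df * noise
    return df


def simulate_morphometry(cfg: SimulationConfig, rng=None):
    """Two tumor groups with shifted nuclear shape and density.

    Returns (morphometry long table, tumor caliper table, group map).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    morpho_rows = []
    tumor_rows = []
    groups = {}
    for gi, (shape_mean, dens_mean) in enumerate(
        zip(cfg.shape_means, cfg.density_means)
    ):
        for t in range(cfg.n_tumors_per_group):
            tid = f"g{gi}_t{t}"
            groups[tid] = gi
            fracs = rng.dirichlet([2.0, 2.0])
            count = int(rng.poisson(dens_mean))
            for ri, frac in enumerate(fracs):
                for n in range(3):
                    ortho = float(np.exp(np.log(5.0) + 0.1 * rng.standard_normal()))
                    ratio = max(1.0, float(np.exp(
                        np.log(shape_mean) + cfg.shape_sigma * rng.standard_normal()
                    )))
                    morpho_rows.append((tid, ri, round(frac, 6), n,
                                        round(ortho * ratio, 4), round(ortho, 4),
                                        count))
            D = 5.0
            for day in range(cfg.n_timepoints):
                D *= float(np.exp(rng.normal(0.15, 0.03)))
                d = D * float(rng.uniform(0.6, 0.95))
                # volume recomputed from the reported (rounded) calipers
                Dr, dr = round(D, 3), round(d, 3)
                tumor_rows.append((tid, day * 3, Dr, dr,
                                   round(Dr * dr * dr / 2.0, 4)))
    morphometry = pd.DataFrame(
        morpho_rows, columns=["tumor_id", "region", "region_fraction",
                              "nucleus", "long_axis_um", "ortho_axis_um",
                              "count_per_500um2"],
    )
    tumors = pd.DataFrame(
        tumor_rows, columns=["tumor_id", "day", "D_mm", "d_mm", "volume_mm3"]
    )
    return morphometry, tumors, groups


def simulate_to_dir(cfg: SimulationConfig, outdir, with_sequence: bool = True) -> Simulation:
    """Run the generator and write every output format plus truth + manifest."""
    from . import io as bio

    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)
    sim = simulate(cfg, with_sequence=with_sequence)

    if sim.sequences:
        with open(out / "genome.fa", "w") as fh:
            for chrom in sorted(sim.sequences):
                fh.write(f">{chrom}\n")
                seq = sim.sequences[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    bio.write_tss_table(sim.promoters, out / "tss.tsv")
    for mark, peaks in sim.peaksets.items():
        bio.write_peaks(peaks, out / "peaks" / f"{mark}.narrowPeak")
    bio.write_peaks(sim.fusion_peaks, out / "peaks" / "fusion.narrowPeak")
    for name, track in sim.tracks.items():
        bio.write_bedgraph(track, out / "tracks" / f"{name}.bedGraph")
    bio.write_loops(sim.loops, out / "loops.bedpe")
    bio.write_gradient_table(sim.gradient, out / "gradient.tsv")
    sim.morphometry.to_csv(out / "morphometry.tsv", sep="\t", index=False)
    sim.tumors.to_csv(out / "tumors.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        fh.write(sim.truth.to_json())
    manifest = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                "config": dataclasses.asdict(cfg)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1, default=str)
    return sim
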
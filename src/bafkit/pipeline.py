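"""End-to-end pipeline: classify → score targets → dips/GC → deconvolve → stats.

A single :class:`RunConfig` names every input path and parameter; ``run_all``
executes the stages in order, writes one TSV per stage plus a JSON run
report with per-stage record counts, and is idempotent — re-running with
the same inputs and seed reproduces every output byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import chromstate, dipgc, gradient, io, loops as loopmod, stats
from .intervals import make_tss_window

__all__ = ["RunConfig", "run_all"]

MARKS = chromstate.MARKS


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    tss_path: str
    peak_paths: dict = field(default_factory=dict)   # mark -> narrowPeak
    fusion_peaks_path: str | None = None
    track_paths: dict = field(default_factory=dict)  # name -> bedGraph
    loops_path: str | None = None
    fasta_path: str | None = None
    gradient_path: str | None = None
    outdir: str = "results"

    qmax: float = 1e-3
    flank: int = 2000
    fdr_max: float = 0.05
    broad_min_width: int = 2000
    dip_central: int = 250
    dip_flank: int = 2000
    dip_ratio_max: float = 0.5
    gc_window: int = 200
    n_random_promoters: int = 100
    seed: int = 0
    boot: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.tss_path, self.fusion_peaks_path, self.loops_path,
                 self.fasta_path, self.gradient_path]
        paths += list(self.peak_paths.values()) + list(self.track_paths.values())
        missing = [p for p in paths if p is not None and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")
        if not 0 < self.qmax <= 1 or not 0 < self.fdr_max <= 1:
            raise ValueError("qmax and fdr_max must lie in (0, 1]")
        if not 0 < self.dip_ratio_max < 1:
            raise ValueError("dip_ratio_max must lie in (0, 1)")

    def config_hash(self) -> str:
        # the hash covers inputs and parameters, not where results land
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def classify_promoters_stage(cfg: RunConfig, promoters, peaksets) -> pd.DataFrame:
    rows = []
    for p in promoters:
        w = make_tss_window(p, cfg.flank)
        sig = chromstate.signature_at(w, peaksets, cfg.qmax)
        cls = chromstate.classify_promoter(sig)
        rows.append({
            "gene_id": p.gene_id, "gene_label": p.gene_label,
            "class": cls.value,
            **{m: sig.flag(m) for m in MARKS},
        })
    return pd.DataFrame(rows)


def score_targets_stage(cfg: RunConfig, promoters, all_loops, tracks) -> pd.DataFrame:
    hi = loopmod.filter_loops(all_loops, cfg.fdr_max)
    rows = []
    for p in promoters:
        ts = loopmod.cumulative_target_score(
            p, hi, tracks, flank=cfg.flank,
            required_tracks=tuple(tracks),
        )
        row = {"gene_id": p.gene_id,
               "promoter_component": ts.promoter_component,
               "distal_component": ts.distal_component,
               "total": ts.total, "n_loops": ts.n_loops}
        for name, (prom, dist) in ts.per_track.items():
            row[f"{name}_promoter"] = prom
            row[f"{name}_distal"] = dist
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> dict:
    """Execute every configured stage; returns the run report dict."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "parameters": {
            "qmax": cfg.qmax, "flank": cfg.flank, "fdr_max": cfg.fdr_max,
            "dip_ratio_max": cfg.dip_ratio_max, "gc_window": cfg.gc_window,
            "seed": cfg.seed,
        },
        "stages": {},
    }

    promoters = io.read_tss_table(cfg.tss_path)
    report["stages"]["tss"] = {"n_promoters": len(promoters)}

    peaksets = {m: io.read_peaks(p) for m, p in cfg.peak_paths.items()}
    classes = None
    if peaksets:
        classes = classify_promoters_stage(cfg, promoters, peaksets)
        classes.to_csv(out / "promoter_classes.tsv", sep="\t", index=False)
        report["stages"]["classify_promoters"] = {
            "n": len(classes),
            "class_counts": classes["class"].value_counts().to_dict(),
        }

    if cfg.fusion_peaks_path:
        fusion = io.read_peaks(cfg.fusion_peaks_path)
        profiles = chromstate.profile_tss_peaks(
            fusion, promoters, cfg.flank, cfg.broad_min_width
        )
        pdf = pd.DataFrame([dataclasses.asdict(t) for t in profiles])
        pdf.to_csv(out / "tss_peak_profiles.tsv", sep="\t", index=False)
        report["stages"]["profile_tss_peaks"] = {
            "n_fusion_peaks": len(fusion), "n_at_tss": len(profiles),
            "n_broad": int((pdf["shape"] == "BROAD").sum()) if len(pdf) else 0,
        }

    tracks = {name: io.read_bedgraph(p) for name, p in cfg.track_paths.items()}

    if cfg.loops_path:
        score_tracks = {k: v for k, v in tracks.items()
                        if k in ("fusion", "H2AK119ub")} or tracks
        all_loops = io.read_loops(cfg.loops_path)
        scores = score_targets_stage(cfg, promoters, all_loops, score_tracks)
        scores.to_csv(out / "target_scores.tsv", sep="\t", index=False,
                      float_format="%.6f")
        report["stages"]["score_targets"] = {
            "n_loops_input": len(all_loops),
            "n_loops_highconf": len(loopmod.filter_loops(all_loops, cfg.fdr_max)),
            "n_promoters_scored": len(scores),
            "n_promoters_looped": int((scores["n_loops"] > 0).sum()),
        }

    dips = None
    if "SMARCA4_ko" in tracks:
        calls = dipgc.call_dips(
            tracks["SMARCA4_ko"], promoters, cfg.dip_ratio_max,
            cfg.dip_central, cfg.dip_flank,
        )
        dips = pd.DataFrame([dataclasses.asdict(c) for c in calls])
        dips.to_csv(out / "dip_calls.tsv", sep="\t", index=False,
                    float_format="%.6f")
        report["stages"]["detect_dips"] = {
            "n_called": int(dips["is_dip"].sum()),
            "n_defined": int(dips["dip_ratio"].notna().sum()),
        }

    gc_df = None
    if cfg.fasta_path:
        genome = io.read_fasta(cfg.fasta_path)
        recs = dipgc.gc_records(genome, promoters, cfg.gc_window)
        gc_df = pd.DataFrame([dataclasses.asdict(r) for r in recs])
        gc_df.to_csv(out / "gc_content.tsv", sep="\t", index=False,
                     float_format="%.6f")
        report["stages"]["gc_promoters"] = {"n": len(gc_df)}

    if cfg.gradient_path:
        table = io.read_gradient_table(cfg.gradient_path)
        comps = {
            sub: gradient.fit_component(
                gradient.GradientProfile(marker, table.loc[marker].to_numpy()), sub
            )
            for sub, marker in gradient.SUBTYPE_MARKERS.items()
        }
        est = gradient.fit_mixture(
            comps, gradient.GradientProfile("SMARCC1", table.loc["SMARCC1"].to_numpy())
        )
        result = {
            "pct": dict(zip(("GBAF", "CBAF", "PBAF"), est.pct)),
            "sse": est.sse,
            "components": {
                s: {"mean": c.mean, "sd": c.sd, "amplitude": c.amplitude}
                for s, c in comps.items()
            },
        }
        if cfg.boot >= 100:
            ivs = gradient.bootstrap_mixture(
                comps, gradient.GradientProfile("SMARCC1",
                                                table.loc["SMARCC1"].to_numpy()),
                n_boot=cfg.boot, seed=cfg.seed,
            )
            result["intervals"] = {s: list(v) for s, v in ivs.items()}
        with open(out / "gradient_deconvolution.json", "w") as fh:
            json.dump(result, fh, sort_keys=True, indent=1)
        report["stages"]["deconvolve_gradient"] = {"pct": result["pct"],
                                                   "sse": est.sse}

    # summary statistics across stages
    comparisons = []
    if classes is not None and cfg.fusion_peaks_path and len(pdf):
        by_label = {lab: pdf.loc[pdf.nearest_gene_label == lab, "width"]
                    for lab in ("SAT", "MAT")}
        if all(len(v) >= 2 for v in by_label.values()):
            r = stats.welch_t(by_label["SAT"], by_label["MAT"])
            comparisons.append({
                "comparison": "fusion_peak_width_SAT_vs_MAT", "test": r.test,
                "statistic": r.statistic, "pvalue": r.pvalue,
            })
    if dips is not None and gc_df is not None:
        merged = dips.merge(gc_df, on="gene_id")
        dip_gc = merged.loc[merged.is_dip, "gc_fraction"].dropna()
        rng_gc = merged.loc[~merged.is_dip, "gc_fraction"].dropna()
        if len(dip_gc) >= 2 and len(rng_gc) >= 2:
            r = stats.kruskal_wallis([dip_gc, rng_gc])
            comparisons.append({
                "comparison": "gc_dip_vs_other_promoters", "test": r.test,
                "statistic": r.statistic, "pvalue": r.pvalue,
            })
    if comparisons:
        pd.DataFrame(comparisons).to_csv(out / "stats_report.tsv", sep="\t",
                                         index=False, float_format="%.6g")
        report["stages"]["stats_report"] = {"n_comparisons": len(comparisons)}

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return report
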
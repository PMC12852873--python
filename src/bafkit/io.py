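"""Readers and writers for BED/narrowPeak, bedGraph, BEDPE, TSS tables,
densitometry TSVs and FASTA windows.

Writers emit deterministic ordering (chromosome lexicographic, then start)
so identical inputs always produce byte-identical files. narrowPeak q-values
are −log10-scaled on disk per the ENCODE standard and converted to linear
probabilities in memory.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .intervals import GenomicInterval, Peak, PromoterAnnotation, SignalTrack
from .loops import Loop

__all__ = [
    "read_peaks",
    "write_peaks",
    "read_bedgraph",
    "write_bedgraph",
    "read_loops",
    "write_loops",
    "read_tss_table",
    "write_tss_table",
    "read_gradient_table",
    "write_gradient_table",
]


class FormatError(ValueError):
    """A malformed record in an on-disk file, reported with its line number."""


def _fmt(x: float) -> str:
    """Compact numeric formatting: integers without a decimal point."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


# ---------------------------------------------------------------- peaks

def read_peaks(path) -> list[Peak]:
    """Read a BED3/BED6/narrowPeak file into sorted :class:`Peak` records.

    narrowPeak (10 columns) carries fold-enrichment in column 7 and a
    −log10 q-value in column 9, decoded as ``qvalue = 10**(-col9)``.
    Plain BED rows get enrichment 0 and qvalue 0 (minimal-dialect defaults).
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            name = f[3] if len(f) > 3 else "."
            if len(f) >= 10:  # narrowPeak
                enrichment = float(f[6])
                qvalue = 10.0 ** (-float(f[8]))
            else:
                enrichment = 0.0
                qvalue = 0.0
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), enrichment, min(qvalue, 1.0), name)
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def write_peaks(peaks: list[Peak], path, dialect: str = "narrowPeak") -> None:
    """Write peaks sorted by (chrom, start) in narrowPeak or BED6 dialect."""
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    with open(path, "w") as fh:
        for p in rows:
            iv = p.interval
            if dialect == "narrowPeak":
                neglog_q = -math.log10(p.qvalue) if p.qvalue > 0 else 0.0
                fh.write(
                    "\t".join(
                        [iv.chrom, str(iv.start), str(iv.end), p.name, "0", ".",
                         _fmt(p.enrichment), "-1", _fmt(neglog_q), "-1"]
                    ) + "\n"
                )
            elif dialect == "bed6":
                fh.write(
                    "\t".join(
                        [iv.chrom, str(iv.start), str(iv.end), p.name,
                         _fmt(p.enrichment), "."]
                    ) + "\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ------------------------------------------------------------- bedGraph

def read_bedgraph(path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(f)}")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
                val = float(f[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph row") from exc
            pairs.append((iv, val))
    return SignalTrack(pairs)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


# ---------------------------------------------------------------- BEDPE

def read_loops(path, fdr_col: int = 8) -> list[Loop]:
    """Read a BEDPE loop file.

    Expected columns: chrom1 start1 end1 chrom2 start2 end2 name score, with
    the FDR in 0-based column ``fdr_col`` (default: column after the score).
    """
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) <= fdr_col or len(f) < 8:
                raise FormatError(f"{path}:{lineno}: too few BEDPE columns")
            try:
                a1 = GenomicInterval(f[0], int(f[1]), int(f[2]))
                a2 = GenomicInterval(f[3], int(f[4]), int(f[5]))
                score = float(f[7])
                fdr = float(f[fdr_col])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed BEDPE row") from exc
            loops.append(Loop(a1, a2, score, fdr, name=f[6]))
    loops.sort(key=lambda l: (l.anchor1.chrom, l.anchor1.start, l.anchor2.chrom, l.anchor2.start))
    return loops


def write_loops(loops: list[Loop], path) -> None:
    rows = sorted(loops, key=lambda l: (l.anchor1.chrom, l.anchor1.start,
                                        l.anchor2.chrom, l.anchor2.start))
    with open(path, "w") as fh:
        for l in rows:
            fh.write(
                "\t".join(
                    [l.anchor1.chrom, str(l.anchor1.start), str(l.anchor1.end),
                     l.anchor2.chrom, str(l.anchor2.start), str(l.anchor2.end),
                     l.name, _fmt(l.loop_score), _fmt(l.fdr)]
                ) + "\n"
            )


# ------------------------------------------------------------ TSS table

def read_tss_table(path) -> list[PromoterAnnotation]:
    """Read a TSV of promoters: gene_id, chrom, tss (0-based), strand, label."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand", "gene_label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        PromoterAnnotation(r.gene_id, r.chrom, int(r.tss), r.strand, r.gene_label)
        for r in df.itertuples()
    ]


def write_tss_table(promoters: list[PromoterAnnotation], path) -> None:
    rows = sorted(promoters, key=lambda p: (p.chrom, p.tss, p.gene_id))
    df = pd.DataFrame(
        [(p.gene_id, p.chrom, p.tss, p.strand, p.gene_label) for p in rows],
        columns=["gene_id", "chrom", "tss", "strand", "gene_label"],
    )
    df.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------- gradient TSV

def read_gradient_table(path) -> pd.DataFrame:
    """Read densitometry: one row per marker, columns marker, f1..f24."""
    df = pd.read_csv(path, sep="\t")
    cols = ["marker"] + [f"f{i}" for i in range(1, 25)]
    missing = set(cols) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df[cols].set_index("marker")


def write_gradient_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "marker"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_fasta(path):
    """Open a FASTA for random access (indexed)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
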
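"""Genomic interval algebra and run-length signal tracks.

All coordinates are 0-based half-open, matching BED/narrowPeak/bedGraph.
A :class:`SignalTrack` is a per-chromosome set of sorted, non-overlapping
``(start, end, value)`` runs — the in-memory form of a bedGraph — queried
by window for summed per-base signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "PromoterAnnotation",
    "Blacklist",
    "SignalTrack",
    "make_tss_window",
    "overlaps",
    "filter_blacklist",
    "window_signal",
    "merge_tracks",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval with fold-enrichment and linear q-value."""

    interval: GenomicInterval
    enrichment: float = 0.0
    qvalue: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.enrichment < 0:
            raise ValueError(f"enrichment must be >= 0, got {self.enrichment}")
        if not 0.0 <= self.qvalue <= 1.0:
            raise ValueError(f"qvalue must lie in [0, 1], got {self.qvalue}")


@dataclass(frozen=True)
class PromoterAnnotation:
    """A TSS with strand and gene-set label (SAT / MAT / SST / none)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    gene_label: str = "none"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.gene_label not in ("SAT", "MAT", "SST", "none"):
            raise ValueError(f"unknown gene_label {self.gene_label!r}")


@dataclass
class Blacklist:
    """A set of intervals whose overlapping peaks are discarded."""

    intervals: list[GenomicInterval] = field(default_factory=list)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


class SignalTrack:
    """Run-length encoded per-base signal over a genome.

    Parameters
    ----------
    runs
        Mapping ``chrom -> (starts, ends, values)`` arrays, or an iterable of
        ``(GenomicInterval, value)`` pairs. Runs within a chromosome must be
        sortable into non-overlapping order; zero-valued runs are kept (they
        still count as covered bases).
    """

    def __init__(self, runs=None):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs is None:
            return
        if isinstance(runs, dict):
            items = runs.items()
            for chrom, (s, e, v) in items:
                self._set_chrom(chrom, np.asarray(s), np.asarray(e), np.asarray(v, dtype=float))
        else:
            by_chrom: dict[str, list[tuple[int, int, float]]] = {}
            for iv, val in runs:
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, float(val)))
            for chrom, triples in by_chrom.items():
                triples.sort()
                s = np.array([t[0] for t in triples])
                e = np.array([t[1] for t in triples])
                v = np.array([t[2] for t in triples])
                self._set_chrom(chrom, s, e, v)

    def _set_chrom(self, chrom, starts, ends, values):
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(ends[:-1] > starts[1:]):
            raise ValueError(f"overlapping runs on {chrom}")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite signal values on {chrom}")
        self._runs[chrom] = (starts.astype(np.int64), ends.astype(np.int64), values)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str):
        """Return the ``(starts, ends, values)`` arrays for one chromosome."""
        return self._runs[chrom]

    def iter_runs(self):
        for chrom in self.chromosomes:
            s, e, v = self._runs[chrom]
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), float(v[i])

    def total_signal(self) -> float:
        """Genome-wide sum of per-base signal."""
        return float(
            sum(((e - s) * v).sum() for s, e, v in self._runs.values())
        )

    def covered_bases(self) -> int:
        return int(sum((e - s).sum() for s, e, _ in self._runs.values()))

    def mean_signal(self) -> float:
        """Mean per-base signal over covered bases (0 if the track is empty)."""
        cov = self.covered_bases()
        return self.total_signal() / cov if cov else 0.0

    def scale(self, factor: float) -> "SignalTrack":
        out = SignalTrack()
        for chrom, (s, e, v) in self._runs.items():
            out._runs[chrom] = (s.copy(), e.copy(), v * factor)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if set(self._runs) != set(other._runs):
            return False
        return all(
            np.array_equal(self._runs[c][0], other._runs[c][0])
            and np.array_equal(self._runs[c][1], other._runs[c][1])
            and np.allclose(self._runs[c][2], other._runs[c][2])
            for c in self._runs
        )


def make_tss_window(p: PromoterAnnotation, flank: int) -> GenomicInterval:
    """Symmetric window ``[tss - flank, tss + flank)`` clipped at 0.

    The window is strand-symmetric: a ±flank window does not depend on
    transcription direction.
    """
    if flank <= 0:
        raise ValueError(f"flank must be > 0, got {flank}")
    return GenomicInterval(p.chrom, max(0, p.tss - flank), p.tss + flank)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the half-open intervals share a chromosome and ≥1 base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def filter_blacklist(peaks: list[Peak], bl: Blacklist) -> list[Peak]:
    """Drop every peak overlapping any blacklist interval (any-overlap rule)."""
    if not len(bl):
        return list(peaks)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in bl:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept = []
    for pk in peaks:
        ivs = by_chrom.get(pk.interval.chrom, ())
        if not any(overlaps(pk.interval, b) for b in ivs):
            kept.append(pk)
    return kept


def window_signal(track: SignalTrack, w: GenomicInterval) -> float:
    """Summed per-base signal over window ``w``.

    Additive over a partition of the window. A chromosome absent from the
    track contributes 0 (with a warning).
    """
    if w.chrom not in track.chromosomes:
        warnings.warn(f"chromosome {w.chrom!r} absent from track; returning 0")
        return 0.0
    s, e, v = track.runs(w.chrom)
    lo = np.maximum(s, w.start)
    hi = np.minimum(e, w.end)
    ov = np.maximum(hi - lo, 0)
    return float((ov * v).sum())


def window_mean(track: SignalTrack, w: GenomicInterval) -> float:
    """Mean per-base signal over window ``w`` (uncovered bases count as 0)."""
    return window_signal(track, w) / w.width


def merge_tracks(tracks: list[SignalTrack]) -> SignalTrack:
    """Average replicate tracks after depth normalization.

    Each track is first rescaled so its genome-wide sum equals the mean of
    the input sums (read-depth normalization), then the per-base arithmetic
    mean across replicates is taken; bases not covered by a replicate count
    as 0 for that replicate.
    """
    if not tracks:
        raise ValueError("need at least one track")
    sums = [t.total_signal() for t in tracks]
    if any(s == 0 for s in sums):
        raise ValueError("cannot depth-normalize a zero-signal track")
    target = float(np.mean(sums))
    scaled = [t.scale(target / s) for t, s in zip(tracks, sums)]
    if len(scaled) == 1:
        return scaled[0]

    chroms = sorted(set().union(*(set(t.chromosomes) for t in scaled)))
    out = SignalTrack()
    n = len(scaled)
    for chrom in chroms:
        # break the chromosome at every run boundary of every replicate
        bounds: set[int] = set()
        for t in scaled:
            if chrom in t.chromosomes:
                s, e, _ = t.runs(chrom)
                bounds.update(s.tolist())
                bounds.update(e.tolist())
        edges = np.array(sorted(bounds), dtype=np.int64)
        seg_s, seg_e = edges[:-1], edges[1:]
        acc = np.zeros(len(seg_s))
        for t in scaled:
            if chrom not in t.chromosomes:
                continue
            s, e, v = t.runs(chrom)
            # run index containing each segment start, if any
            idx = np.searchsorted(s, seg_s, side="right") - 1
            valid = (idx >= 0) & (seg_s < e[np.clip(idx, 0, None)])
            acc[valid] += v[idx[valid]]
        mean = acc / n
        keep = mean != 0
        if keep.any():
            out._runs[chrom] = (seg_s[keep], seg_e[keep], mean[keep])
    return out
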
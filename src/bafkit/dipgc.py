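"""TSS dip detection and promoter GC content.

A "dip" is a focal depletion of remodeler (e.g. SMARCA4) ChIP signal in a
narrow central window at the TSS relative to its flanks: the dip ratio is
the central mean signal per base (TSS ± 250 bp by default) divided by the
pooled mean over the flanking bands (±250..±2000 bp), and a promoter is a
dip iff the ratio is defined and below a threshold (default 0.5, strict).
Promoters whose flanks carry less than a noise floor (10% of the track's
mean covered-base signal by default) are left uncalled rather than risk a
ratio of noise over noise.

GC content is the G+C fraction of the 200 bp surrounding the TSS
(±100 bp), case-insensitive, with N bases excluded from both counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval, PromoterAnnotation, SignalTrack, window_signal

__all__ = [
    "DipCall",
    "GcRecord",
    "dip_ratio",
    "call_dips",
    "gc_content",
    "gc_records",
]

DEFAULT_CENTRAL_HALF = 250
DEFAULT_FLANK_OUTER = 2000
DEFAULT_RATIO_MAX = 0.5
DEFAULT_NOISE_FLOOR_FRAC = 0.10
DEFAULT_GC_WINDOW = 200


@dataclass
class DipCall:
    gene_id: str
    central_mean: float
    flank_mean: float
    dip_ratio: float | None  # None when flanks fall below the noise floor
    is_dip: bool


@dataclass
class GcRecord:
    gene_id: str
    gc_fraction: float | None  # None when the window is entirely N


def dip_ratio(
    track: SignalTrack,
    p: PromoterAnnotation,
    central_half: int = DEFAULT_CENTRAL_HALF,
    flank_outer: int = DEFAULT_FLANK_OUTER,
    noise_floor: float | None = None,
    ratio_max: float = DEFAULT_RATIO_MAX,
) -> DipCall:
    """Central/flank mean-signal ratio at one promoter.

    central = [tss − central_half, tss + central_half); flanks = the two
    bands out to ``flank_outer`` pooled. ``noise_floor`` defaults to 10% of
    the track's mean per-base signal over covered bases; a flank mean at or
    below it yields no call (``dip_ratio`` None, ``is_dip`` False).
    """
    if not flank_outer > central_half > 0:
        raise ValueError("need flank_outer > central_half > 0")
    if noise_floor is None:
        noise_floor = DEFAULT_NOISE_FLOOR_FRAC * track.mean_signal()

    c_lo = max(0, p.tss - central_half)
    central = GenomicInterval(p.chrom, c_lo, p.tss + central_half)
    central_mean = window_signal(track, central) / central.width

    flank_sum = 0.0
    flank_bases = 0
    left_lo = max(0, p.tss - flank_outer)
    left_hi = max(0, p.tss - central_half)
    if left_hi > left_lo:
        iv = GenomicInterval(p.chrom, left_lo, left_hi)
        flank_sum += window_signal(track, iv)
        flank_bases += iv.width
    right = GenomicInterval(p.chrom, p.tss + central_half, p.tss + flank_outer)
    flank_sum += window_signal(track, right)
    flank_bases += right.width
    flank_mean = flank_sum / flank_bases if flank_bases else 0.0

    if flank_mean <= noise_floor:
        return DipCall(p.gene_id, central_mean, flank_mean, None, False)
    ratio = central_mean / flank_mean
    return DipCall(p.gene_id, central_mean, flank_mean, ratio, ratio < ratio_max)


def call_dips(
    track: SignalTrack,
    promoters: list[PromoterAnnotation],
    ratio_max: float = DEFAULT_RATIO_MAX,
    central_half: int = DEFAULT_CENTRAL_HALF,
    flank_outer: int = DEFAULT_FLANK_OUTER,
    noise_floor: float | None = None,
) -> list[DipCall]:
    """Dip calls for every promoter; ``is_dip`` iff defined ratio < ratio_max."""
    if not 0 < ratio_max < 1:
        raise ValueError(f"ratio_max must lie in (0, 1), got {ratio_max}")
    if noise_floor is None:
        noise_floor = DEFAULT_NOISE_FLOOR_FRAC * track.mean_signal()
    return [
        dip_ratio(track, p, central_half, flank_outer, noise_floor, ratio_max)
        for p in promoters
    ]


def gc_content(genome, p: PromoterAnnotation, window: int = DEFAULT_GC_WINDOW) -> float | None:
    """G+C fraction of the ``window`` bp surrounding the TSS (±window/2).

    ``genome`` is an indexed FASTA (pyfaidx.Fasta) or any mapping of
    chromosome name to sequence string. Case-insensitive; N and other
    ambiguity codes are excluded from numerator and denominator. Returns
    None when no unambiguous base lies in the window.
    """
    half = window // 2
    lo = max(0, p.tss - half)
    hi = p.tss + (window - half)
    seq = str(genome[p.chrom][lo:hi]).upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def gc_records(
    genome, promoters: list[PromoterAnnotation], window: int = DEFAULT_GC_WINDOW
) -> list[GcRecord]:
    return [GcRecord(p.gene_id, gc_content(genome, p, window)) for p in promoters]
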
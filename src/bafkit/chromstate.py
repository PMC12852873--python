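"""Combinatorial histone-mark classification of promoters and enhancers,
and broad/narrow fusion-peak profiling at TSSs.

A promoter window carries a mark iff at least one called peak of that mark
with q-value below threshold (default 0.001, strict) overlaps the window.
The promoter classes are defined on four marks:

========================  ===========  ========  ========  =========
class                     H2AK119ub    H3K4me3   H3K27ac   H3K27me3
========================  ===========  ========  ========  =========
SAT_PATTERN               +            +         +         −
BIVALENT                  (any)        +         (any)     +
REPRESSED                 (any)        −         (any)     +
ACTIVE                    (any)        +         +         (any)
========================  ===========  ========  ========  =========

evaluated in that precedence order; anything else is UNCLASSIFIED.
Distal enhancers require H3K4me1 and H3K27ac, and split on H2AK119ub.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .intervals import (
    GenomicInterval,
    Peak,
    PromoterAnnotation,
    make_tss_window,
    overlaps,
)

__all__ = [
    "MARKS",
    "MarkSignature",
    "PromoterClass",
    "EnhancerClass",
    "TssPeakProfile",
    "signature_at",
    "classify_promoter",
    "classify_enhancer",
    "profile_tss_peaks",
    "classify_peak_shape",
    "select_random_promoters",
    "expected_recovery",
]

MARKS = ("H2AK119ub", "H3K4me3", "H3K27ac", "H3K27me3", "H3K4me1")

DEFAULT_QMAX = 1e-3
DEFAULT_FLANK = 2000
DEFAULT_BROAD_MIN_WIDTH = 2000


@dataclass(frozen=True)
class MarkSignature:
    """Presence flags per histone mark; ``None`` means the mark was not assayed."""

    H2AK119ub: bool | None = False
    H3K4me3: bool | None = False
    H3K27ac: bool | None = False
    H3K27me3: bool | None = False
    H3K4me1: bool | None = False

    def flag(self, mark: str) -> bool | None:
        return getattr(self, mark)


class PromoterClass(str, Enum):
    SAT_PATTERN = "SAT_PATTERN"
    BIVALENT = "BIVALENT"
    REPRESSED = "REPRESSED"
    ACTIVE = "ACTIVE"
    UNCLASSIFIED = "UNCLASSIFIED"
    RANDOM_CONTROL = "RANDOM_CONTROL"


class EnhancerClass(str, Enum):
    ENHANCER_UB_POS = "ENHANCER_UB_POS"
    ENHANCER_UB_NEG = "ENHANCER_UB_NEG"
    NOT_ENHANCER = "NOT_ENHANCER"


@dataclass(frozen=True)
class TssPeakProfile:
    name: str
    width: int
    enrichment: float
    shape: str  # "BROAD" | "NARROW"
    nearest_gene_label: str


def signature_at(
    window: GenomicInterval,
    peaksets: dict[str, list[Peak]],
    q_max: float = DEFAULT_QMAX,
) -> MarkSignature:
    """Mark-presence signature of a window from per-mark called peaks.

    A mark is present iff some peak of that mark with ``qvalue < q_max``
    (strict) overlaps the window. A mark whose peakset is missing from
    ``peaksets`` is flagged ``None`` (unknown).
    """
    if not 0 < q_max <= 1:
        raise ValueError(f"q_max must lie in (0, 1], got {q_max}")
    flags: dict[str, bool | None] = {}
    for mark in MARKS:
        if mark not in peaksets:
            flags[mark] = None
            continue
        flags[mark] = any(
            p.qvalue < q_max and overlaps(p.interval, window)
            for p in peaksets[mark]
        )
    return MarkSignature(**flags)


def classify_promoter(sig: MarkSignature) -> PromoterClass:
    """Map a mark signature to a promoter class (precedence: SAT > bivalent
    > repressed > active > unclassified); any unknown flag among the four
    promoter marks yields UNCLASSIFIED."""
    ub, k4, ac, k27 = sig.H2AK119ub, sig.H3K4me3, sig.H3K27ac, sig.H3K27me3
    if None in (ub, k4, ac, k27):
        return PromoterClass.UNCLASSIFIED
    if ub and k4 and ac and not k27:
        return PromoterClass.SAT_PATTERN
    if k4 and k27:
        return PromoterClass.BIVALENT
    if k27 and not k4:
        return PromoterClass.REPRESSED
    if k4 and ac:
        return PromoterClass.ACTIVE
    return PromoterClass.UNCLASSIFIED


def classify_enhancer(
    sig: MarkSignature,
    window: GenomicInterval | None = None,
    promoter_windows: list[GenomicInterval] | None = None,
) -> EnhancerClass:
    """Classify a distal window: active enhancers carry H3K4me1 and H3K27ac,
    split by H2AK119ub. If ``promoter_windows`` is given the window must be
    distal (no overlap with any promoter window)."""
    if window is not None and promoter_windows:
        if any(overlaps(window, pw) for pw in promoter_windows):
            raise ValueError(f"window {window} overlaps a promoter window; not distal")
    if sig.H3K4me1 and sig.H3K27ac:
        if sig.H2AK119ub:
            return EnhancerClass.ENHANCER_UB_POS
        return EnhancerClass.ENHANCER_UB_NEG
    return EnhancerClass.NOT_ENHANCER


def classify_peak_shape(width: int, broad_min_width: int = DEFAULT_BROAD_MIN_WIDTH) -> str:
    """BROAD iff ``width > broad_min_width`` (strict), else NARROW."""
    if width <= 0:
        raise ValueError(f"width must be > 0, got {width}")
    return "BROAD" if width > broad_min_width else "NARROW"


def profile_tss_peaks(
    peaks: list[Peak],
    promoters: list[PromoterAnnotation],
    flank: int = DEFAULT_FLANK,
    broad_min_width: int = DEFAULT_BROAD_MIN_WIDTH,
) -> list[TssPeakProfile]:
    """Profile fusion peaks lying within ``flank`` of any TSS.

    A peak is retained iff its interval overlaps any TSS ± flank window;
    each retained peak appears once, annotated with its width, enrichment,
    broad/narrow shape and the gene label of the nearest TSS (by distance
    from the peak midpoint).
    """
    windows = [(make_tss_window(p, flank), p) for p in promoters]
    out = []
    for pk in peaks:
        near = [p for w, p in windows if overlaps(pk.interval, w)]
        if not near:
            continue
        mid = pk.interval.midpoint
        nearest = min(near, key=lambda p: (abs(p.tss - mid), p.gene_id))
        out.append(
            TssPeakProfile(
                name=pk.name,
                width=pk.interval.width,
                enrichment=pk.enrichment,
                shape=classify_peak_shape(pk.interval.width, broad_min_width),
                nearest_gene_label=nearest.gene_label,
            )
        )
    return out


def split_widths_two_means(widths) -> float:
    """Data-driven broad/narrow boundary: 1-D two-means on log widths.

    Returns the boundary (bp) halfway between the two cluster centers.
    """
    logw = np.log(np.asarray(widths, dtype=float))
    lo, hi = logw.min(), logw.max()
    c = np.array([lo, hi])
    for _ in range(100):
        assign = np.abs(logw[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([
            logw[assign == k].mean() if (assign == k).any() else c[k]
            for k in range(2)
        ])
        if np.allclose(new, c):
            break
        c = new
    return float(np.exp(c.mean()))


def select_random_promoters(
    promoters: list[PromoterAnnotation], n: int, seed: int
) -> list[PromoterAnnotation]:
    """Uniform sample of promoters without replacement; the random-control set."""
    if n > len(promoters):
        raise ValueError(f"cannot sample {n} from {len(promoters)} promoters")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(promoters), size=n, replace=False)
    return [promoters[i] for i in sorted(idx)]


# --------------------------------------------------- closed-form recovery

#: canonical planted signature per class, over the four promoter marks
#: (H2AK119ub, H3K4me3, H3K27ac, H3K27me3)
PLANTED_SIGNATURES = {
    PromoterClass.SAT_PATTERN: (True, True, True, False),
    PromoterClass.BIVALENT: (False, True, False, True),
    PromoterClass.REPRESSED: (False, False, False, True),
    PromoterClass.ACTIVE: (False, True, True, False),
}


def expected_recovery(class_mix: dict[PromoterClass, float], flip_rate: float) -> float:
    """Exact expected classification accuracy under independent flag flips.

    Each of the four promoter-mark flags flips independently with
    probability ``flip_rate``; the expected accuracy is the class-mix
    weighted probability that the flipped signature still classifies to the
    planted class, obtained by enumerating all 2^4 outcomes.
    """
    eps = flip_rate
    total = 0.0
    for cls, weight in class_mix.items():
        truth = PLANTED_SIGNATURES[cls]
        p_correct = 0.0
        for observed in itertools.product([False, True], repeat=4):
            prob = 1.0
            for t, o in zip(truth, observed):
                prob *= eps if t != o else (1 - eps)
            sig = MarkSignature(
                H2AK119ub=observed[0], H3K4me3=observed[1],
                H3K27ac=observed[2], H3K27me3=observed[3],
            )
            if classify_promoter(sig) is cls:
                p_correct += prob
        total += weight * p_correct
    return total
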
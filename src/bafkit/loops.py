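"""HiChIP loop filtering and loop-weighted cumulative target scoring.

High-confidence loops (FDR < 0.05) connect a promoter-proximal anchor to a
distal anchor. For each promoter, the target score sums the fusion and
H2AK119ub signal in the TSS ± 2 kb window (promoter component) with, over
every assigned loop, the signal in a 4 kb window centered on the distal
anchor midpoint multiplied by the loop score (distal component).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import (
    GenomicInterval,
    PromoterAnnotation,
    SignalTrack,
    make_tss_window,
    overlaps,
    window_signal,
)

__all__ = [
    "Loop",
    "TargetScore",
    "filter_loops",
    "anchor_window",
    "assign_loops_to_promoter",
    "distal_score",
    "cumulative_target_score",
]

DEFAULT_FDR_MAX = 0.05
DEFAULT_ANCHOR_HALF_WIDTH = 2000
DEFAULT_FLANK = 2000


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two anchors with a loop score and an FDR."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    loop_score: float
    fdr: float
    name: str = "."

    def __post_init__(self) -> None:
        if self.loop_score < 0:
            raise ValueError(f"loop_score must be >= 0, got {self.loop_score}")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr must lie in [0, 1], got {self.fdr}")


@dataclass
class TargetScore:
    """Per-promoter cumulative fusion + H2AK119ub target score.

    ``per_track`` maps track name -> (promoter_component, distal_component);
    the headline components sum over tracks, and total = promoter + distal.
    """

    gene_id: str
    promoter_component: float = 0.0
    distal_component: float = 0.0
    n_loops: int = 0
    per_track: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.promoter_component + self.distal_component


def filter_loops(loops: list[Loop], fdr_max: float = DEFAULT_FDR_MAX) -> list[Loop]:
    """Retain high-confidence loops with ``fdr < fdr_max`` (strict)."""
    if not 0 < fdr_max <= 1:
        raise ValueError(f"fdr_max must lie in (0, 1], got {fdr_max}")
    return [l for l in loops if l.fdr < fdr_max]


def anchor_window(
    anchor: GenomicInterval, half_width: int = DEFAULT_ANCHOR_HALF_WIDTH
) -> GenomicInterval:
    """A 2×half_width window centered on the anchor midpoint, clipped at 0."""
    if half_width <= 0:
        raise ValueError(f"half_width must be > 0, got {half_width}")
    mid = anchor.midpoint
    return GenomicInterval(anchor.chrom, max(0, mid - half_width), mid + half_width)


def assign_loops_to_promoter(
    p: PromoterAnnotation, loops: list[Loop], flank: int = DEFAULT_FLANK
) -> list[tuple[Loop, GenomicInterval]]:
    """Assign loops whose proximal anchor overlaps the promoter window.

    Returns (loop, distal_anchor) pairs. A loop is assigned iff exactly one
    anchor overlaps the TSS ± flank window; the other anchor is distal.
    Loops with both anchors in the promoter window are degenerate
    (no distal element) and excluded.
    """
    w = make_tss_window(p, flank)
    out = []
    for l in loops:
        hit1 = overlaps(l.anchor1, w)
        hit2 = overlaps(l.anchor2, w)
        if hit1 and not hit2:
            out.append((l, l.anchor2))
        elif hit2 and not hit1:
            out.append((l, l.anchor1))
    return out


def distal_score(
    assigned: list[tuple[Loop, GenomicInterval]],
    track: SignalTrack,
    half_width: int = DEFAULT_ANCHOR_HALF_WIDTH,
) -> float:
    """Σ over loops of (distal anchor-window summed signal × loop score)."""
    return sum(
        window_signal(track, anchor_window(a, half_width)) * l.loop_score
        for l, a in assigned
    )


def cumulative_target_score(
    p: PromoterAnnotation,
    loops: list[Loop],
    tracks: dict[str, SignalTrack],
    flank: int = DEFAULT_FLANK,
    anchor_half_width: int = DEFAULT_ANCHOR_HALF_WIDTH,
    required_tracks: tuple[str, ...] = ("fusion", "H2AK119ub"),
    weight_all_tracks: bool = True,
) -> TargetScore:
    """Cumulative loop-weighted target score for one promoter.

    For each track the promoter component is the summed signal over
    TSS ± flank and the distal component is the loop-score-weighted summed
    signal over the assigned distal anchor windows; the headline score sums
    the tracks. ``weight_all_tracks=False`` restricts loop-score weighting
    to the fusion track, leaving the others unweighted.
    """
    for name in required_tracks:
        if name not in tracks:
            raise ValueError(f"missing required track {name!r}")
    assigned = assign_loops_to_promoter(p, loops, flank)
    w = make_tss_window(p, flank)
    score = TargetScore(gene_id=p.gene_id, n_loops=len(assigned))
    for name, track in tracks.items():
        prom = window_signal(track, w)
        if weight_all_tracks or name == "fusion":
            dist = distal_score(assigned, track, anchor_half_width)
        else:
            dist = sum(
                window_signal(track, anchor_window(a, anchor_half_width))
                for _, a in assigned
            )
        score.per_track[name] = (prom, dist)
        score.promoter_component += prom
        score.distal_component += dist
    return score
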
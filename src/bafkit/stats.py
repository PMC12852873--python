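"""Group statistics and quantitative phenotype formulas.

Wraps the standard tests (Welch's heteroscedastic t, Kruskal–Wallis with
ties correction, Wilcoxon rank-sum) and implements Dunn's post hoc z with
Bonferroni adjustment, plus the phenotype arithmetic: caliper tumor volume
D·d²/2, area-weighted nuclear long/orthogonal axis ratio, and nuclear
density per 500 µm² photomicrograph square.

Wilcoxon switches to exact enumeration of the rank-sum null when the
combined sample size is at most 12; otherwise a normal approximation with
midrank ties correction and continuity correction is used.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .intervals import GenomicInterval, SignalTrack, window_signal

__all__ = [
    "TestResult",
    "MorphometryRecord",
    "welch_t",
    "kruskal_wallis",
    "dunn_posthoc",
    "wilcoxon_rank_sum",
    "binned_pearson",
    "tumor_volume",
    "nuclear_shape_index",
    "nuclear_density",
]

EXACT_WILCOXON_MAX_N = 12


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    df: float | None = None
    adjusted_pvalue: float | None = None
    adjust_method: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0 + 1e-12:
            raise ValueError(f"p-value out of [0,1]: {self.pvalue}")


@dataclass
class MorphometryRecord:
    """One tumor's histomorphometry.

    ``regions`` is a list of (area_fraction, [(long, orthogonal)] × 3)
    per histomorphologically distinct area; fractions sum to 1 and each
    nucleus has long ≥ orthogonal axis (µm).
    """

    tumor_id: str
    regions: list[tuple[float, list[tuple[float, float]]]]
    nucleus_count: int = 0  # nuclei in a 500 µm² square

    def __post_init__(self) -> None:
        total = sum(f for f, _ in self.regions)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"region fractions sum to {total}, not 1")
        for _, pairs in self.regions:
            for long_ax, ortho_ax in pairs:
                if long_ax < ortho_ax:
                    raise ValueError(
                        f"long axis {long_ax} < orthogonal axis {ortho_ax}"
                    )


def welch_t(x, y) -> TestResult:
    """Two-tailed heteroscedastic (Welch's) t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        # identical constant samples: no evidence of a difference
        return TestResult("welch_t", 0.0, 1.0, df=float(len(x) + len(y) - 2))
    nx, ny = len(x), len(y)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return TestResult("welch_t", float(t), float(p), df=float(df))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H with midrank ties correction; chi-square p on k−1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or sum(len(g) for g in groups) < 3:
        raise ValueError("need >= 2 groups with total n >= 3")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, df=float(len(groups) - 1))
    h, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", float(h), float(p), df=float(len(groups) - 1))


def _midranks_and_tie_term(pooled: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    return ranks, tie_term


def dunn_posthoc(groups, labels=None) -> dict[tuple, TestResult]:
    """Dunn's pairwise z tests on pooled midranks, Bonferroni-adjusted.

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j)]
    with T = Σ(t³ − t) over tie groups; adjusted p = min(1, p·k(k−1)/2).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if labels is None:
        labels = list(range(k))
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks, tie_term = _midranks_and_tie_term(pooled)
    mean_ranks = []
    i0 = 0
    for g in groups:
        mean_ranks.append(ranks[i0:i0 + len(g)].mean())
        i0 += len(g)
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    m = k * (k - 1) // 2
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        out[(labels[i], labels[j])] = TestResult(
            "dunn", float(z), float(p),
            adjusted_pvalue=min(1.0, p * m), adjust_method="bonferroni",
        )
    return out


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n, nx) rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    sums = np.array(
        [sum(c) for c in itertools.combinations(ranks, nx)]
    )
    mean_w = sums.mean()
    dev = abs(w_obs - mean_w)
    p = float((np.abs(sums - mean_w) >= dev - 1e-9).mean())
    return min(1.0, p)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration of the permutation null when nₓ + nᵧ ≤ 12; otherwise
    the normal approximation with ties and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each sample needs n >= 1")
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = float(ranks[: len(x)].sum())
    if len(x) + len(y) <= EXACT_WILCOXON_MAX_N:
        p = _exact_rank_sum_p(x, y)
    else:
        _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
    return TestResult("wilcoxon_rank_sum", w, p)


def binned_pearson(
    track_a: SignalTrack,
    track_b: SignalTrack,
    bin_size: int,
    chrom_sizes: dict[str, int] | None = None,
    restrict: list[GenomicInterval] | None = None,
) -> float:
    """Pearson r between two tracks over fixed genomic bins.

    The genome (or the ``restrict`` site list, e.g. remodeler binding sites)
    is partitioned into bins of ``bin_size`` bp; per-bin summed signal from
    each track is correlated.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be > 0, got {bin_size}")
    bins: list[GenomicInterval] = []
    if restrict is not None:
        bins = list(restrict)
    else:
        if chrom_sizes is None:
            chrom_sizes = {}
            for t in (track_a, track_b):
                for c in t.chromosomes:
                    _, e, _ = t.runs(c)
                    chrom_sizes[c] = max(chrom_sizes.get(c, 0), int(e[-1]))
        for chrom in sorted(chrom_sizes):
            size = chrom_sizes[chrom]
            for s in range(0, size, bin_size):
                bins.append(GenomicInterval(chrom, s, min(s + bin_size, size)))
    if len(bins) < 2:
        raise ValueError("need at least 2 bins")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent-chromosome bins sum to 0
        a = np.array([window_signal(track_a, b) for b in bins])
        b = np.array([window_signal(track_b, b) for b in bins])
    return float(np.corrcoef(a, b)[0, 1])


def tumor_volume(D: float, d: float) -> float:
    """Caliper tumor volume (mm³): D·d²/2 with D the long, d the short diameter."""
    if d <= 0 or D <= 0:
        raise ValueError("diameters must be positive")
    if d > D:
        raise ValueError(f"short diameter d={d} exceeds long diameter D={D}")
    return D * d * d / 2.0


def nuclear_shape_index(rec: MorphometryRecord) -> float:
    """Area-weighted mean of per-region mean long/orthogonal axis ratios.

    Per region, the ratio is averaged over its three measured nuclei and
    multiplied by the region's fractional area; regions sum to the index.
    Round nuclei everywhere give the minimum, 1.0.
    """
    total = 0.0
    for fraction, pairs in rec.regions:
        ratios = [long_ax / ortho_ax for long_ax, ortho_ax in pairs]
        total += fraction * (sum(ratios) / len(ratios))
    return total


def nuclear_density(count: int, to_mm2: bool = False) -> float:
    """Nuclear density from a count in a 500 µm² square.

    Reported per 500 µm² square by default; ``to_mm2=True`` converts to
    nuclei per mm² (×2000, since 1 mm² = 2000 × 500 µm²).
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    return count * 2000.0 if to_mm2 else float(count)
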
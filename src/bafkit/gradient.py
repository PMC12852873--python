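"""Glycerol-gradient deconvolution of BAF-subtype abundances.

Nuclear extract sedimented through a 10–30% glycerol gradient is collected
in 24 fractions; Western densitometry of a subtype-specific marker per
complex (BRD9 → GBAF, DPF2 → CBAF, PBRM1 → PBAF) traces each subtype's
migration profile, and SMARCC1 (common to all three) traces the total.
Only fractions 12–24 carry assembled complexes and enter the fit.

Each subtype profile is modeled as a Gaussian in fraction-index space;
the observed SMARCC1 profile is decomposed as a convex mixture of the three
fitted component densities by exhaustive search over all integer
percentage triples summing to 100 (5,151 candidates), minimizing the sum
of squared differences over fractions 12–24.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

__all__ = [
    "SUBTYPE_MARKERS",
    "GradientProfile",
    "GaussianComponent",
    "MixtureEstimate",
    "normalize_profile",
    "fit_component",
    "predict_mixture",
    "fit_mixture",
    "bootstrap_mixture",
    "enumerate_triples",
]

#: subtype-specific Western markers
SUBTYPE_MARKERS = {"GBAF": "BRD9", "CBAF": "DPF2", "PBAF": "PBRM1"}
SUBTYPES = ("GBAF", "CBAF", "PBAF")

FIT_FRACTIONS = np.arange(12, 25)  # fractions 12..24 inclusive
N_FIT = len(FIT_FRACTIONS)  # 13


@dataclass
class GradientProfile:
    """Densitometry of one marker across the 24 gradient fractions."""

    marker: str
    intensities: np.ndarray  # length 24, fraction 1..24

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (24,):
            raise ValueError(f"expected 24 fractions, got {self.intensities.shape}")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        if self.intensities[11:24].sum() <= 0:
            raise ValueError("no signal within fractions 12-24")

    def fit_range_values(self) -> np.ndarray:
        """Intensities over fractions 12..24 (13 values)."""
        return self.intensities[11:24]


@dataclass
class GaussianComponent:
    """A subtype's migration profile: amplitude · N(mean, sd) in fraction units."""

    subtype: str
    mean: float
    sd: float
    amplitude: float
    converged: bool = True

    def density(self, fractions: np.ndarray | None = None) -> np.ndarray:
        """Unit-sum density sampled at the fit fractions (12..24)."""
        x = FIT_FRACTIONS if fractions is None else fractions
        phi = norm.pdf(x, loc=self.mean, scale=self.sd)
        return phi / phi.sum()


@dataclass
class MixtureEstimate:
    """Best integer-percentage mixture (GBAF, CBAF, PBAF) and its fit."""

    pct: tuple[int, int, int]
    sse: float
    residuals: np.ndarray  # observed − predicted over fractions 12..24

    def __post_init__(self) -> None:
        if sum(self.pct) != 100 or any(p < 0 for p in self.pct):
            raise ValueError(f"pct must be nonnegative and sum to 100, got {self.pct}")


def normalize_profile(p: GradientProfile) -> np.ndarray:
    """Unit-sum vector over fractions 12..24."""
    v = p.fit_range_values()
    total = v.sum()
    if total <= 0:
        raise ValueError(f"{p.marker}: zero signal over fractions 12-24")
    return v / total


def _gauss(x, amplitude, mean, sd):
    return amplitude * norm.pdf(x, loc=mean, scale=sd)


def fit_component(p: GradientProfile, subtype: str) -> GaussianComponent:
    """Least-squares Gaussian fit to a marker profile over fractions 12–24.

    Initialized from intensity-weighted moments; falls back to the moment
    estimates if the nonlinear fit does not converge. A fitted sd below 0.1
    fractions is rejected as a degenerate profile.
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}")
    x = FIT_FRACTIONS.astype(float)
    y = p.fit_range_values()
    w = y / y.sum()
    m0 = float((w * x).sum())
    var0 = float((w * (x - m0) ** 2).sum())
    sd0 = max(np.sqrt(var0), 0.3)
    a0 = float(y.sum())
    try:
        popt, _ = curve_fit(
            _gauss, x, y, p0=[a0, m0, sd0],
            bounds=([0.0, 10.0, 0.05], [np.inf, 26.0, 10.0]),
            maxfev=10_000,
        )
        amplitude, mean, sd = map(float, popt)
        converged = True
    except RuntimeError:
        amplitude, mean, sd, converged = a0, m0, sd0, False
    if sd < 0.1:
        raise ValueError(
            f"{p.marker}: fitted sd {sd:.3g} fractions below 0.1 (degenerate profile)"
        )
    return GaussianComponent(subtype=subtype, mean=mean, sd=sd,
                             amplitude=amplitude, converged=converged)


def predict_mixture(
    components: dict[str, GaussianComponent], pct: tuple[int, int, int]
) -> np.ndarray:
    """Convex mixture of unit-sum component densities at fractions 12..24.

    ``pct`` is the (GBAF, CBAF, PBAF) integer-percentage triple; the output
    sums to 1.
    """
    if sum(pct) != 100:
        raise ValueError(f"pct must sum to 100, got {pct}")
    out = np.zeros(N_FIT)
    for share, subtype in zip(pct, SUBTYPES):
        if share:
            out += (share / 100.0) * components[subtype].density()
    return out


_GRID_CACHE: np.ndarray | None = None


def _grid() -> np.ndarray:
    global _GRID_CACHE
    if _GRID_CACHE is None:
        _GRID_CACHE = np.array(list(enumerate_triples()), dtype=float)
    return _GRID_CACHE


def enumerate_triples():
    """All 5,151 nonnegative integer triples summing to 100, lexicographic."""
    for g in range(101):
        for c in range(101 - g):
            yield (g, c, 100 - g - c)


def fit_mixture(
    components: dict[str, GaussianComponent], observed: GradientProfile
) -> MixtureEstimate:
    """Exhaustive integer-percentage grid search minimizing SSE.

    The observed SMARCC1 profile is unit-normalized over fractions 12–24 and
    compared with every candidate mixture; ties break lexicographically on
    (GBAF, CBAF, PBAF).
    """
    obs = normalize_profile(observed)
    phis = np.stack([components[s].density() for s in SUBTYPES])  # 3 × 13
    # vectorized SSE over the full simplex grid, then a lexicographic argmin
    grid = _grid()  # 5151 × 3
    pred = (grid / 100.0) @ phis  # 5151 × 13
    sse = ((pred - obs) ** 2).sum(axis=1)
    best = int(np.argmin(sse))  # grid is lexicographic; argmin takes first tie
    pct = tuple(int(v) for v in grid[best])
    return MixtureEstimate(
        pct=pct, sse=float(sse[best]), residuals=obs - pred[best]
    )


def bootstrap_mixture(
    components: dict[str, GaussianComponent],
    observed: GradientProfile,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.90,
) -> dict[str, tuple[int, int]]:
    """Residual-resampling bootstrap percentile intervals for the mixture.

    Densitometry noise is multiplicative, so the best fit's residuals are
    taken on the log scale — where they are exchangeable — centered,
    resampled with replacement and reapplied to the fitted profile before
    re-running the grid search. Per-subtype percentile intervals are widened
    to contain the point estimate.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    point = fit_mixture(components, observed)
    obs = normalize_profile(observed)
    fitted = obs - point.residuals
    log_resid = np.log(np.where((obs > 0) & (fitted > 0), obs / fitted, 1.0))
    log_resid = log_resid - log_resid.mean()
    reps = np.empty((n_boot, 3), dtype=int)
    for b in range(n_boot):
        resampled = fitted * np.exp(rng.choice(log_resid, size=N_FIT, replace=True))
        if resampled.sum() <= 0:
            reps[b] = point.pct
            continue
        intens = np.zeros(24)
        intens[11:24] = resampled
        est = fit_mixture(components, GradientProfile(observed.marker, intens))
        reps[b] = est.pct
    alpha = (1.0 - level) / 2.0
    out = {}
    for i, subtype in enumerate(SUBTYPES):
        lo, hi = np.percentile(reps[:, i], [100 * alpha, 100 * (1 - alpha)])
        out[subtype] = (
            int(min(np.floor(lo), point.pct[i])),
            int(max(np.ceil(hi), point.pct[i])),
        )
    return out
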
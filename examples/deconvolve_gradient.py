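"""Glycerol-gradient deconvolution of BAF-subtype abundances.

Simulates Western densitometry across 24 gradient fractions — BRD9 (GBAF),
DPF2 (CBAF) and PBRM1 (PBAF) migrate as Gaussians, SMARCC1 (common to all
three) as their mixture — then fits each component and exhaustively searches
all 5,151 integer percentage triples for the SSE-minimizing mixture over
fractions 12-24.
"""

from bafkit import SimulationConfig, bootstrap_mixture, fit_component, fit_mixture
from bafkit.gradient import SUBTYPE_MARKERS, GradientProfile
from bafkit.simulate import simulate_gradient

cfg = SimulationConfig(seed=3, true_pct=(55, 15, 30), gradient_noise=0.05)
table = simulate_gradient(cfg)

components = {
    subtype: fit_component(GradientProfile(marker, table.loc[marker].to_numpy()),
                           subtype)
    for subtype, marker in SUBTYPE_MARKERS.items()
}
for s, c in components.items():
    print(f"{s}: mean fraction {c.mean:.2f}, sd {c.sd:.2f}")

observed = GradientProfile("SMARCC1", table.loc["SMARCC1"].to_numpy())
est = fit_mixture(components, observed)
print(f"best mixture (GBAF, CBAF, PBAF) = {est.pct}%  sse = {est.sse:.2e}")
print(f"planted truth                   = {tuple(cfg.true_pct)}%")

intervals = bootstrap_mixture(components, observed, n_boot=200, seed=3)
for s, (lo, hi) in intervals.items():
    print(f"{s}: 90% bootstrap interval [{lo}, {hi}]%")
# At 5% multiplicative noise the estimate lands within ~2 percentage points
# of the planted triple; at zero noise recovery is exact with sse = 0.
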
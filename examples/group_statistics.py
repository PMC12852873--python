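"""The statistics toolbox: Welch t, Kruskal-Wallis, Dunn, Wilcoxon, and the
phenotype formulas (caliper tumor volume, nuclear shape index and density).
"""

from bafkit import (
    MorphometryRecord,
    dunn_posthoc,
    kruskal_wallis,
    nuclear_density,
    nuclear_shape_index,
    tumor_volume,
    welch_t,
    wilcoxon_rank_sum,
)

r = welch_t([10, 11, 12], [1, 2, 3])
print(f"Welch t = {r.statistic:.3f}, df = {r.df:.1f}, p = {r.pvalue:.4f}")

r = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
print(f"Kruskal-Wallis H = {r.statistic:.1f}, p = {r.pvalue:.4f}")
# H = 7.2 is the exact rank-formula value for three separated triples.

for pair, res in dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]]).items():
    print(f"Dunn {pair}: z = {res.statistic:.2f}, "
          f"Bonferroni p = {res.adjusted_pvalue:.3f}")

r = wilcoxon_rank_sum([1, 2], [3, 4])
print(f"Wilcoxon rank-sum exact p = {r.pvalue:.4f}")  # 1/3 by enumeration

print(f"tumor volume D=10, d=5 mm: {tumor_volume(10, 5):.1f} mm^3")  # D*d^2/2

rec = MorphometryRecord("t1", [
    (0.6, [(2.0, 1.0), (2.2, 1.1), (1.8, 0.9)]),   # spindled region
    (0.4, [(1.1, 1.0), (1.0, 1.0), (1.2, 1.1)]),   # epithelioid region
], nucleus_count=25)
print(f"area-weighted nuclear shape index: {nuclear_shape_index(rec):.3f}")
print(f"nuclear density: {nuclear_density(25)} per 500 um^2 "
      f"({nuclear_density(25, to_mm2=True):.0f} per mm^2)")
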
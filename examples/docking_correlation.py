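"""Docking-affinity vs activity agreement and descriptor importance.

Correlates the docking binding free energies (kcal/mol; more negative =
stronger predicted binding) with measured pIC50 across 25 compounds, then
ranks the model's descriptors by standardized contribution |aj|·sd(xj).
"""

from qsarkit import (
    affinity_activity_correlation,
    descriptor_contributions,
    fit,
)
from qsarkit.fixtures import load_affinity_table, load_descriptor_table

corr = affinity_activity_correlation(load_affinity_table())
print(f"Binding affinity vs pIC50 over {corr.n} compounds:")
print(f"  r = {corr.r:.3f}   r² = {corr.r2:.2f}")
print(f"  pIC50 = {corr.intercept:.2f} {corr.slope:+.2f} × affinity")
print("  (negative r: stronger predicted binding goes with higher potency,")
print("   so the docking protocol is consistent with the assay data)")

ds = load_descriptor_table()
contrib = descriptor_contributions(fit(ds), ds)
print("\nRelative descriptor contributions (standardized, sum to 1):")
for name, value in sorted(contrib.items(), key=lambda kv: -kv[1]):
    print(f"  {name:<12} {value:.3f}")
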
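"""Descriptor multicollinearity screening on the chalcone training set.

Prints the descriptor/activity correlation matrix and the tolerance and
variance-inflation factor of each descriptor.  VIF < 5 throughout means the
four selected descriptors carry largely independent information and can all
enter one linear model.
"""

from qsarkit import correlation_matrix, screen
from qsarkit.fixtures import load_descriptor_table

ds = load_descriptor_table()

print("Pearson correlations (training subset):")
print(correlation_matrix(ds, subset="train").round(4))

report = screen(ds, max_vif=5.0)
print(f"\nKept descriptors: {report.kept}")
if report.dropped:
    print(f"Dropped: {report.dropped}")
print(f"{'descriptor':<12} {'tolerance':>9} {'VIF':>7}")
for name in report.kept:
    print(f"{name:<12} {report.tolerance[name]:>9.4f} {report.vif[name]:>7.4f}")
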
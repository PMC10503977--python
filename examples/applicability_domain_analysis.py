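"""Williams-plot applicability domain of the chalcone model.

Predictions are only trusted for compounds with leverage below
h* = 3(d+1)/n and standardized residual within ±2σ.  The script prints the
classification of all 25 compounds and saves the Williams plot.
"""

from qsarkit import applicability_domain, fit
from qsarkit.fixtures import load_descriptor_table
from qsarkit.plotting import williams_plot

ds = load_descriptor_table()
model = fit(ds)
ad = applicability_domain(model, ds, residual_sigma_mult=2.0)

print(f"h* = {ad.h_star:.2f}  (d=4 descriptors, n=20 training compounds)")
print(f"{'compound':<9} {'h':>6} {'std resid':>10}  label")
for cid in ds.ids:
    print(f"{cid:<9} {ad.leverages[cid]:>6.3f} {ad.std_residuals[cid]:>10.2f}  "
          f"{ad.labels[cid]}")

outliers = [c for c, lab in ad.labels.items() if lab != "inside"]
print(f"\nOutliers: {outliers or 'none'}")
print("(a response outlier is mispredicted; a structural outlier sits in an")
print(" unpopulated region of descriptor space — its prediction is an extrapolation)")

ax = williams_plot(ad)
ax.figure.savefig("williams_plot.svg")
print("Williams plot written to williams_plot.svg")
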
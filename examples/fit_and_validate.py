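"""Fit the chalcone MAO-B activity model and run the full validation battery.

Loads the packaged 25-compound dataset (20 train / 5 test), refits the
four-descriptor linear model and prints every internal and external
validation statistic.  A model is considered predictive when Q²_LOO > 0.5,
r²_test > 0.6, cRp² > 0.5, and all four Golbraikh–Tropsha conditions hold.
"""

from qsarkit import fit, fit_statistics, validation_report
from qsarkit.fixtures import load_descriptor_table

ds = load_descriptor_table()
model = fit(ds)

print("Model: pIC50 =", f"{model.intercept:+.3f}", end="")
for name, coef in model.coefficients.items():
    print(f" {coef:+.3f}*{name}", end="")
print()

stats = fit_statistics(model, ds)
print(f"\nTraining fit (n={stats.n}, p={stats.p}):")
print(f"  r² = {stats.r2:.2f}   r²_adj = {stats.r2_adj:.2f}   "
      f"RMSE = {stats.rmse:.2f}   MAE = {stats.mae:.2f}   F = {stats.f_stat:.2f}")

rep = validation_report(ds, n_runs=100, seed=0)
print(f"\nLeave-one-out: Q² = {rep.loo.q2_loo:.2f}   "
      f"RMSE_LOO = {rep.loo.rmse_loo:.2f}   MAE_LOO = {rep.loo.mae_loo:.2f}")
print(f"r²m (LOO, scaled) = {rep.rm_loo.rm2:.2f}")
print(f"\nY-randomization ({rep.y_randomization.n_runs} runs): "
      f"avg R² = {rep.y_randomization.avg_r2:.2f}   "
      f"avg Q² = {rep.y_randomization.avg_q2:.2f}   "
      f"cRp² = {rep.y_randomization.crp2:.2f}")
print(f"\nExternal (5 test compounds): r²_test = {rep.external.r2_test:.2f}   "
      f"Q²(F2) = {rep.external.q2_f2:.2f}")
print(f"Through-origin slopes: k = {rep.rm_test.k:.2f}   k' = {rep.rm_test.k_prime:.2f}")
print("Golbraikh–Tropsha checklist:")
for name, item in rep.external.gt_checklist.items():
    print(f"  {name:>14}: {'pass' if item['passed'] else 'FAIL'}  ({item['threshold']})")
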
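# qsarkit

Building and validating 2D-QSAR models for small-molecule activity data.

A quantitative structure–activity relationship (QSAR) model maps numeric
molecular descriptors to a biological activity, here the pIC50
(−log₁₀ of the molar IC50) of monoamine oxidase B (MAO-B) inhibitors —
chalcone-type unsaturated ketones of interest for Parkinson's disease.
`qsarkit` implements the complete workflow a medicinal-chemistry modeller
runs around a linear QSAR model, and ships a fully worked 25-compound
chalcone dataset against which every statistic can be checked:

* **Dataset handling** — delimited compound/descriptor/activity tables,
  IC50 → pIC50 conversion, seeded 80/20 train/test splits
  (`qsarkit.datasets`, `qsarkit.fixtures`).
* **Descriptor screening** — variance and response-correlation filters,
  Pearson correlation matrices, tolerance and variance-inflation factors
  with iterative removal at VIF > 5 (`qsarkit.screening`).
* **Model fitting** — ordinary least squares for
  `y = a₀ + a₁x₁ + … + a_p x_p` with r², adjusted r²,
  RMSE = √(SSE/(n−p−1)), MAE, Fisher F and coefficient t-tests
  (`qsarkit.regression`).
* **Validation battery** — leave-one-out Q², Roy's r²m metrics,
  Y-randomization with cRp² = R·√(R² − (avg R_r)²), external r²test,
  predictive Q²(F2), and the four Golbraikh–Tropsha criteria
  (`qsarkit.validation`).
* **Applicability domain** — leverages h = x̃ᵀ(X̃ᵀX̃)⁻¹x̃, the
  h\* = 3(d+1)/n threshold, and Williams-plot classification
  (`qsarkit.domain`).
* **Drug-likeness** — Lipinski, Veber, Egan, Muegge and Ghose rule filters
  and the Abbott bioavailability score (`qsarkit.druglikeness`).
* **Reporting** — docking-affinity vs activity correlation and
  standardized descriptor contributions (`qsarkit.report`), plus a
  seeded synthetic-data generator with known ground truth
  (`qsarkit.synthetic`).

## Worked example

```python
from qsarkit import fit, fit_statistics, validation_report
from qsarkit.fixtures import load_descriptor_table

ds = load_descriptor_table()          # 25 chalcones, 20 train / 5 test
model = fit(ds)                       # OLS on the training subset
stats = fit_statistics(model, ds)
rep = validation_report(ds, n_runs=100, seed=0)

print(f"r2={stats.r2:.2f} rmse={stats.rmse:.2f} q2_loo={rep.loo.q2_loo:.2f} "
      f"r2_test={rep.external.r2_test:.2f} crp2={rep.y_randomization.crp2:.2f}")
```

prints

```
r2=0.88 rmse=0.29 q2_loo=0.81 r2_test=0.71 crp2=0.79
```

meaning: the four descriptors (BCUT_SMR_2, logP(o/w), SlogP_VSA4,
vsurf_IW3) explain 88 % of the training activity variance with a residual
standard error of 0.29 log units; the model still explains 81 % of the
variance when each training compound is predicted by a model that never
saw it (internal validation), explains 71 % of the variance of the five
held-out test compounds (external validation), and sits far above the
chance-correlation level established by refitting on 100 scrambled
activity vectors (cRp² ≫ 0.5).  The `examples/` directory contains one
short script per capability (screening, validation, applicability domain,
drug-likeness, docking correlation, synthetic pipeline).

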
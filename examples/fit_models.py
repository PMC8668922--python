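"""Fit linear and degree-1 MARS models predicting eRGC from ERG markers.

Generates a synthetic glaucoma cohort (55 individuals, paired
near-independent eyes, saturating amplitude-severity links), then fits
both model families on the chromatic-stimulus marker amplitudes with
tenfold grouped cross-validation and prints apparent and
cross-validated R².
"""
from ergpred import CohortConfig, cv_linear, cv_tune, generate_cohort
from ergpred.analysis import feature_table_from_truth

cohort = generate_cohort(CohortConfig(seed=42))
table = feature_table_from_truth(cohort)
ch = table[table.condition == "chromatic"]

features = ["a_uV", "b_uV", "i_uV", "phnr1_uV", "phnr2_uV"]
X, y = ch[features], ch["ergc"].to_numpy()
groups = ch["individual_id"].to_numpy()

linear = cv_linear(X, y, groups=groups, k=10, seed=0)
mars = cv_tune(X, y, groups=groups, k=10, seed=0)

print(f"cohort: {len(ch)} eyes from {ch.individual_id.nunique()} individuals")
print(f"linear:  R2 = {linear.score(X, y):.3f}   cv R2 = {linear.cv_r2:.3f}")
print(f"MARS:    R2 = {mars.score(X, y):.3f}   cv R2 = {mars.cv_r2:.3f}")
print("\nMARS hinge terms (variable, knot uV, direction, cells per uV):")
for t in mars.terms:
    print(f"  {t.variable:10s} knot {t.knot:8.2f}  {t.direction}  coef {t.coefficient:12,.0f}")
print("\nEach hinge lets a marker's effect switch on or saturate at a knot;")
print("on any single cohort the two families can tie, but across cohorts")
print("with saturating amplitude links MARS wins on average (see the tests).")
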
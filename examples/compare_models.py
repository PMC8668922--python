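"""Compare PhNR-only and full-marker models by cluster bootstrap.

Because both eyes of an individual can enter the cohort, resampling is
done at the individual level (each draw brings all of that person's
eyes). The one-sided p-value is the fraction of resamples in which the
full-marker model fails to beat the PhNR-only baseline. Also prints
the between-eye intraclass correlation and the effective sample size
it implies.
"""
from ergpred import (
    CohortConfig,
    ModelSpec,
    cluster_bootstrap_compare,
    effective_sample_size,
    generate_cohort,
    icc_lohr,
)
from ergpred.analysis import feature_table_from_truth

cohort = generate_cohort(CohortConfig(seed=42))
table = feature_table_from_truth(cohort)
ch = table[table.condition == "chromatic"].reset_index(drop=True)

phnr_only = ModelSpec("linear", "phnr_only")
all_markers = ModelSpec("mars", "all_markers")
result = cluster_bootstrap_compare(phnr_only, all_markers, ch,
                                   n_resamples=500, seed=0)

icc = icc_lohr(ch["ergc"], ch["individual_id"])
n_eff = effective_sample_size(len(ch), icc.n_clusters, icc.icc)

print(f"PhNR-only linear   R2 = {result.r2_a:.3f}")
print(f"all-marker MARS    R2 = {result.r2_b:.3f}")
print(f"delta R2 = {result.delta:+.3f}, one-sided p = {result.p_value:.3f} "
      f"({result.n_resamples} resamples)")
print(f"between-eye ICC = {icc.icc:+.3f} -> effective n = {n_eff:.0f} of {len(ch)} eyes")
print("\nA small p says the extra ERG markers carry real information about")
print("ganglion-cell loss beyond the conventional PhNR measure; an ICC near")
print("zero says paired eyes behave almost independently here.")
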
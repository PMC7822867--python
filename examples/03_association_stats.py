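"""Feature-grade association analysis on a full cohort.

Computes, for every one of the 51 features: Spearman correlation against
ISUP grade group, a Mann-Whitney U test between low (GG1) and
intermediate/high (GG>=2) tumors, and Benjamini-Hochberg corrected
q-values per test family; then the two-way ANOVA institution screen.

Run:  python examples/03_association_stats.py   (about one minute)
"""

from pzrad.features import build_feature_table
from pzrad.stats import anova_site_screen, association_analysis
from pzrad.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(), seed=1)
table = build_feature_table(cohort)
print(f"{len(table)} tumors, classes: {table['aggressiveness'].value_counts().to_dict()}\n")

assoc = association_analysis(table).table
assoc = assoc.sort_values("q_u")
print("10 features most associated with aggressiveness (Mann-Whitney):")
cols = ["feature", "rho", "q_rho", "q_u", "sig_u"]
print(assoc[cols].head(10).to_string(index=False, float_format=lambda v: f"{v:.4f}"), "\n")

n_sig = int(assoc["sig_u"].sum())
print(f"{n_sig} of {len(assoc)} features significant after FDR correction\n")

screen = anova_site_screen(table)
dropped = screen[~screen["keep"]]
print(f"institution screen drops {len(dropped)} of {len(screen)} features:")
if len(dropped):
    print(dropped[["feature", "p_site", "p_interaction", "reason"]]
          .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
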
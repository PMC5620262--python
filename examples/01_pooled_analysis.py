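"""Total pooled odds ratios for the bundled gastric-cancer dataset.

Loads the 14 PRKAA1 rs13361707 case-control studies, pools each genetic
model under the heterogeneity-threshold rule (Q-test P < 0.10 selects
DerSimonian-Laird random effects, otherwise Mantel-Haenszel fixed effects)
and prints the resulting odds ratios.  An OR below 1 with a CI excluding 1
would mean T-allele carriers have lower disease odds; here every total CI
straddles 1, i.e. no overall association.
"""

from genemeta import GeneticModel, bundled_fixture, pool_auto, study_tables
from genemeta.report import fmt_or_ci, fmt_p

table = bundled_fixture()
print(f"{len(table)} studies, {table.case_total()} cases, "
      f"{table.control_total(deduplicate_shared=True)} unique controls\n")
print(f"{'model':14s} {'method':10s} {'OR (95% CI)':18s} {'P_h':>6s} {'P':>6s}")
for model in GeneticModel:
    pooled = pool_auto(study_tables(table, model))
    print(
        f"{model.value:14s} {pooled.method.name:10s} "
        f"{fmt_or_ci(pooled.or_, pooled.ci_low, pooled.ci_high):18s} "
        f"{fmt_p(pooled.het.p_h):>6s} {fmt_p(pooled.p):>6s}"
    )
print("\nP_h is the Cochran Q heterogeneity P; P the two-sided Z-test on the pooled OR.")
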
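"""Stratified pooling: by control source and by country.

Each stratum gets its own heterogeneity test and model selection.  The
hospital-based and Korean strata are where the inverse association appears:
their CIs sit entirely below 1.
"""

from genemeta import GeneticModel, bundled_fixture, subgroup_analysis
from genemeta.report import fmt_or_ci, fmt_p

table = bundled_fixture()
for key, model in (("design", GeneticModel.HETEROZYGOTE),
                   ("country", GeneticModel.HOMOZYGOTE)):
    print(f"\n{model.value} by {key}:")
    for stratum, pooled in subgroup_analysis(table, key, model).items():
        print(
            f"  {stratum:8s} k={pooled.k:2d} {pooled.method.name:9s} "
            f"OR {fmt_or_ci(pooled.or_, pooled.ci_low, pooled.ci_high)} "
            f"P_h={fmt_p(pooled.het.p_h)} P={fmt_p(pooled.p)}"
        )
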
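"""Genetic-model contrasts, allele frequencies and the Hardy-Weinberg test.

A biallelic genotype can be dichotomised five standard ways (allelic,
homozygote, heterozygote, dominant, recessive); each turns a study's genotype
counts into a 2x2 table whose odds ratio is then pooled downstream.  The
allelic contrast treats the 2n alleles of n subjects as independent
observations — the standard approximation in this literature, exact only under
Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

from scipy import stats

from .errors import DegenerateContrastError, DegenerateHWEError, EmptyGroupError
from .models import GeneticModel, GenotypeCounts, HWETestResult, TwoByTwo

__all__ = ["contrast_table", "allele_frequency", "hwe_test"]


def contrast_table(
    case: GenotypeCounts,
    control: GenotypeCounts,
    model: GeneticModel,
    study_id: str = "",
) -> TwoByTwo:
    """Cross-tabulate one study under a genetic model.

    The "exposed" column is the first-named category of the model (T allele,
    TT, TC, TT+TC, TT).  The homozygote and heterozygote contrasts drop the
    excluded genotype rather than erroring, as per-genotype odds ratios are
    conventionally computed; if the restriction empties a margin a
    :class:`DegenerateContrastError` is raised instead.
    """
    if case.n < 1 or control.n < 1:
        raise EmptyGroupError(f"study {study_id!r}: both groups need at least one subject")
    if model is GeneticModel.ALLELIC:
        cells = (case.t_alleles, case.c_alleles, control.t_alleles, control.c_alleles)
    elif model is GeneticModel.HOMOZYGOTE:
        cells = (case.tt, case.cc, control.tt, control.cc)
    elif model is GeneticModel.HETEROZYGOTE:
        cells = (case.tc, case.cc, control.tc, control.cc)
    elif model is GeneticModel.DOMINANT:
        cells = (case.tt + case.tc, case.cc, control.tt + control.tc, control.cc)
    elif model is GeneticModel.RECESSIVE:
        cells = (case.tt, case.tc + case.cc, control.tt, control.tc + control.cc)
    else:  # pragma: no cover - enum is closed
        raise ValueError(model)
    a, b, c, d = cells
    if a + b == 0 or c + d == 0:
        raise DegenerateContrastError(
            f"study {study_id!r}, model {model.name}: contrast leaves an empty margin"
        )
    return TwoByTwo(a=a, b=b, c=c, d=d, model=model, study_id=study_id)


def allele_frequency(counts: GenotypeCounts, allele: str = "T") -> float:
    """Frequency of the given allele among the group's 2n chromosomes."""
    if counts.n < 1:
        raise EmptyGroupError("allele frequency of an empty group is undefined")
    if allele not in ("T", "C"):
        raise ValueError(f"allele must be 'T' or 'C', got {allele!r}")
    t = counts.t_alleles / (2 * counts.n)
    return t if allele == "T" else 1.0 - t


def hwe_test(group: GenotypeCounts) -> HWETestResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (df = 1).

    Expected counts are n*p^2, 2n*p*q, n*q^2 with p the observed T-allele
    frequency; no Yates correction and no exact test.  The pipeline applies
    this to control groups, where departure flags genotyping problems.
    """
    if group.n < 1:
        raise EmptyGroupError("HWE test on an empty group")
    p = allele_frequency(group, "T")
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        raise DegenerateHWEError("monomorphic group: HWE expected counts degenerate")
    n = group.n
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    chi2 = sum(
        (obs - exp) ** 2 / exp for obs, exp in zip(group.as_tuple(), expected)
    )
    return HWETestResult(chi2=chi2, p=float(stats.chi2.sf(chi2, 1)))
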
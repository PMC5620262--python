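"""Core value types for the case-control meta-analysis pipeline.

The objects here are deliberately small, immutable where practical, and carry
no behaviour beyond validation and derived quantities: the statistics live in
:mod:`genemeta.contrasts`, :mod:`genemeta.pooling` and :mod:`genemeta.bias`.

A biallelic SNP with alleles C and T is summarised per study group by the three
genotype counts (TT, TC, CC).  One case-control study is a pair of such groups
plus stratification metadata (country, control source, sample-size class,
cancer-subtype label); a meta-analysis input is an ordered table of studies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence

from .errors import ValidationError

__all__ = [
    "GenotypeCounts",
    "StudyRecord",
    "StudyTable",
    "GeneticModel",
    "TwoByTwo",
    "HWETestResult",
    "EffectEstimate",
    "HeterogeneityResult",
    "PoolMethod",
    "ModelChoice",
    "PooledResult",
    "BiasMethod",
    "BiasTestResult",
    "LeaveOneOutResult",
    "ValidationIssue",
]

VALID_DESIGNS = ("HB", "PB")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (TT, TC, CC) for one group of one study."""

    tt: int
    tc: int
    cc: int

    def __post_init__(self) -> None:
        for name in ("tt", "tc", "cc"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"genotype count {name!r} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"genotype count {name!r} must be >= 0, got {v}")

    @property
    def n(self) -> int:
        """Number of subjects in the group."""
        return self.tt + self.tc + self.cc

    @property
    def t_alleles(self) -> int:
        """Number of T alleles carried by the group (2*TT + TC)."""
        return 2 * self.tt + self.tc

    @property
    def c_alleles(self) -> int:
        return 2 * self.cc + self.tc

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.tt, self.tc, self.cc)


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study: metadata strata plus case and control counts."""

    study_id: str
    author: str
    year: int
    country: str
    design: str  # "HB" (hospital-based) or "PB" (population-based)
    size_class: str  # "<1000" or ">1000"
    case: GenotypeCounts
    control: GenotypeCounts
    gc_type: str = "NA"
    genotyping_method: Optional[str] = None
    nos: Optional[int] = None  # Newcastle-Ottawa Scale, 0-9 stars
    shared_control_key: Optional[str] = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in VALID_DESIGNS:
            raise ValidationError(
                f"study {self.study_id!r}: design must be one of {VALID_DESIGNS}, got {self.design!r}"
            )
        if self.nos is not None and not (0 <= self.nos <= 9):
            raise ValidationError(
                f"study {self.study_id!r}: NOS must lie in [0, 9], got {self.nos}"
            )

    def stratum_value(self, key: str) -> str:
        """Value of a categorical metadata column for subgroup analysis."""
        if key in ("country", "design", "size_class", "gc_type"):
            return getattr(self, key)
        if key in self.extra:
            return self.extra[key]
        raise KeyError(key)


@dataclass(frozen=True)
class StudyTable:
    """Ordered sequence of studies; order drives forest-plot rows and leave-one-out indexing."""

    records: tuple[StudyRecord, ...]
    provenance: str = "memory"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.study_id in seen:
                raise ValidationError(f"duplicate study_id {rec.study_id!r}")
            seen.add(rec.study_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> StudyRecord:
        return self.records[i]

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(r.study_id for r in self.records)

    def drop(self, study_id: str) -> "StudyTable":
        """Copy of the table without the named study (leave-one-out helper)."""
        kept = tuple(r for r in self.records if r.study_id != study_id)
        if len(kept) == len(self.records):
            raise KeyError(study_id)
        return replace(self, records=kept)

    def filter(self, key: str, value: str) -> "StudyTable":
        """Sub-table of studies whose metadata column equals ``value``.

        Comparison is case-insensitive after trimming whitespace, matching how
        stratum labels are treated throughout the pipeline.
        """
        norm = value.strip().casefold()
        kept = tuple(
            r for r in self.records if r.stratum_value(key).strip().casefold() == norm
        )
        return replace(self, records=kept)

    def case_total(self) -> int:
        return sum(r.case.n for r in self.records)

    def control_total(self, deduplicate_shared: bool = False) -> int:
        """Control subjects, either as-rows or counting each shared series once.

        Studies sharing a control series (``shared_control_key``) double-count
        those subjects when rows are summed naively; ``deduplicate_shared=True``
        counts each shared series exactly once, giving the unique-subjects total.
        """
        total = 0
        seen_keys: set[str] = set()
        for r in self.records:
            if deduplicate_shared and r.shared_control_key:
                if r.shared_control_key in seen_keys:
                    continue
                seen_keys.add(r.shared_control_key)
            total += r.control.n
        return total

    def pooled_case_counts(self) -> GenotypeCounts:
        """Element-wise sum of the case genotype counts."""
        return GenotypeCounts(
            tt=sum(r.case.tt for r in self.records),
            tc=sum(r.case.tc for r in self.records),
            cc=sum(r.case.cc for r in self.records),
        )

    def pooled_control_counts(self, deduplicate_shared: bool = True) -> GenotypeCounts:
        """Element-wise sum of control counts, shared series counted once by default."""
        tt = tc = cc = 0
        seen_keys: set[str] = set()
        for r in self.records:
            if deduplicate_shared and r.shared_control_key:
                if r.shared_control_key in seen_keys:
                    continue
                seen_keys.add(r.shared_control_key)
            tt += r.control.tt
            tc += r.control.tc
            cc += r.control.cc
        return GenotypeCounts(tt=tt, tc=tc, cc=cc)


class GeneticModel(enum.Enum):
    """The five standard contrasts for a biallelic genotype.

    The "exposed" category is always the first-named one: T allele, TT, TC,
    TT+TC, and TT respectively.
    """

    ALLELIC = "T vs C"
    HOMOZYGOTE = "TT vs CC"
    HETEROZYGOTE = "TC vs CC"
    DOMINANT = "TT+TC vs CC"
    RECESSIVE = "TT vs TC+CC"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table for one study under one genetic model.

    ``a``/``b`` are case exposed/unexposed, ``c``/``d`` control exposed/unexposed.
    """

    a: int
    b: int
    c: int
    d: int
    model: GeneticModel
    study_id: str = ""
    continuity_corrected: bool = False

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class HWETestResult:
    """Pearson chi-square goodness-of-fit to Hardy-Weinberg proportions (df = 1)."""

    chi2: float
    p: float
    df: int = 1


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio with its Woolf standard error and 95% CI."""

    study_id: str
    model: GeneticModel
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran Q with its tail probability, Higgins I^2 and the DL tau^2."""

    q: float
    df: int
    p_h: float
    i2: float
    tau2: float


class PoolMethod(enum.Enum):
    MH_FIXED = "Mantel-Haenszel fixed"
    IV_FIXED = "inverse-variance fixed"
    DL_RANDOM = "DerSimonian-Laird random"


class ModelChoice(enum.Enum):
    FIXED = "fixed"
    RANDOM = "random"


@dataclass(frozen=True)
class PooledResult:
    """Pooled OR with CI, Z-test and the attached heterogeneity assessment."""

    model: GeneticModel
    method: PoolMethod
    k: int
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    het: HeterogeneityResult
    stratum: str = "total"


class BiasMethod(enum.Enum):
    EGGER = "Egger regression"
    BEGG = "Begg rank correlation"


@dataclass(frozen=True)
class BiasTestResult:
    """Publication-bias test outcome (Egger t or Begg z with its p-value)."""

    method: BiasMethod
    statistic: float
    p: float
    df: Optional[int] = None  # Egger only: k - 2
    intercept: Optional[float] = None  # Egger only
    kendall_score: Optional[int] = None  # Begg only


@dataclass(frozen=True)
class LeaveOneOutResult:
    omitted_study_id: str
    pooled: PooledResult


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    study_id: str
    message: str
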
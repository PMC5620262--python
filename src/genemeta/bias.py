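"""Publication-bias tests, leave-one-out sensitivity, subgroup stratification.

Both bias tests operate on the crude per-study effects (never on shrunken
random-effects values):

* Egger's regression: ordinary least squares of the standardized effect
  ``theta_i / se_i`` on the precision ``1 / se_i``; the test statistic is the
  intercept divided by its standard error, referred to Student's t with k - 2
  degrees of freedom.  A funnel plot that is symmetric about the pooled effect
  gives an intercept near zero.
* Begg-Mazumdar rank correlation: Kendall's score between the variance-
  standardized deviates ``(theta_i - theta_bar) / sqrt(v_i - 1/sum(w))`` and
  the variances ``v_i``, with the tie-corrected normal approximation for its
  null variance; optionally continuity-corrected.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .contrasts import contrast_table
from .errors import ConfigurationError, InsufficientStudiesError, NumericalDegeneracyError
from .models import (
    BiasMethod,
    BiasTestResult,
    EffectEstimate,
    GeneticModel,
    LeaveOneOutResult,
    PooledResult,
    StudyTable,
)
from .pooling import pool_auto, study_effect

__all__ = [
    "egger_test",
    "begg_test",
    "kendall_score",
    "leave_one_out",
    "subgroup_analysis",
    "study_tables",
]


def study_tables(table: StudyTable, model: GeneticModel):
    """Per-study 2x2 tables for one genetic model, in input order."""
    return [contrast_table(r.case, r.control, model, r.study_id) for r in table.records]


def egger_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger's unweighted regression test for funnel-plot asymmetry."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(
            f"Egger's test needs at least 3 studies (got {k}); with k < 3 the "
            "regression has no residual degrees of freedom"
        )
    se = np.array([e.se for e in effects])
    y = np.array([e.log_or for e in effects]) / se
    x = 1.0 / se
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept = float(fit.params[0])
    t_stat = float(fit.tvalues[0])
    df = k - 2
    return BiasTestResult(
        method=BiasMethod.EGGER,
        statistic=t_stat,
        p=float(2.0 * stats.t.sf(abs(t_stat), df)),
        df=df,
        intercept=intercept,
    )


def kendall_score(u: Sequence[float], v: Sequence[float]) -> int:
    """Kendall's S: concordant minus discordant pairs; ties contribute zero."""
    s = 0
    for i, j in itertools.combinations(range(len(u)), 2):
        s += int(np.sign((u[j] - u[i]) * (v[j] - v[i])))
    return s


def _tie_groups(values: np.ndarray) -> list[int]:
    _, counts = np.unique(values, return_counts=True)
    return [int(c) for c in counts if c > 1]


def _kendall_var(n: int, u_vals: np.ndarray, v_vals: np.ndarray) -> float:
    """Null variance of Kendall's S with the standard tie correction."""
    t = _tie_groups(u_vals)
    u = _tie_groups(v_vals)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = sum(ti * (ti - 1) * (2 * ti + 5) for ti in t)
    vu = sum(uj * (uj - 1) * (2 * uj + 5) for uj in u)
    var = (v0 - vt - vu) / 18.0
    if n > 2:
        var += (
            sum(ti * (ti - 1) * (ti - 2) for ti in t)
            * sum(uj * (uj - 1) * (uj - 2) for uj in u)
        ) / (9.0 * n * (n - 1) * (n - 2))
    var += (
        sum(ti * (ti - 1) for ti in t) * sum(uj * (uj - 1) for uj in u)
    ) / (2.0 * n * (n - 1))
    return var


def begg_test(
    effects: Sequence[EffectEstimate], continuity_correction: bool = False
) -> BiasTestResult:
    """Begg-Mazumdar adjusted rank-correlation test for funnel-plot asymmetry."""
    k = len(effects)
    if k < 2:
        raise InsufficientStudiesError(f"Begg's test needs at least 2 studies (got {k})")
    theta = np.array([e.log_or for e in effects])
    v = np.array([e.se for e in effects]) ** 2
    w = 1.0 / v
    v_star = v - 1.0 / w.sum()
    if np.any(v_star <= 1e-12):
        raise NumericalDegeneracyError(
            "a study's variance is not above the pooled variance; the "
            "standardized deviate is undefined (one study dominates the "
            "meta-analysis - drop it or test on the remaining studies)"
        )
    t_i = (theta - (w * theta).sum() / w.sum()) / np.sqrt(v_star)
    s = kendall_score(t_i, v)
    var = _kendall_var(k, t_i, v)
    if continuity_correction:
        z = max(abs(s) - 1, 0) / math.sqrt(var) * (1 if s >= 0 else -1)
    else:
        z = s / math.sqrt(var)
    return BiasTestResult(
        method=BiasMethod.BEGG,
        statistic=float(z),
        p=float(2.0 * stats.norm.sf(abs(z))),
        kendall_score=int(s),
    )


def leave_one_out(
    table: StudyTable,
    model: GeneticModel,
    het_threshold: float = 0.10,
    cc_increment: float = 0.5,
) -> list[LeaveOneOutResult]:
    """Re-pool after removing each study in turn (sensitivity analysis).

    Each of the k results applies the full pipeline - effects, Q-test,
    model-selection rule, pooling - to the complementary k - 1 studies.
    """
    if len(table) < 2:
        raise InsufficientStudiesError("leave-one-out needs at least 2 studies")
    out = []
    for rec in table.records:
        rest = table.drop(rec.study_id)
        pooled = pool_auto(
            study_tables(rest, model),
            het_threshold=het_threshold,
            cc_increment=cc_increment,
            stratum=f"omit {rec.study_id}",
        )
        out.append(LeaveOneOutResult(omitted_study_id=rec.study_id, pooled=pooled))
    return out


def subgroup_analysis(
    table: StudyTable,
    key: str,
    model: GeneticModel,
    het_threshold: float = 0.10,
    cc_increment: float = 0.5,
) -> dict[str, PooledResult]:
    """One pooled result per stratum of a categorical metadata column.

    Strata are formed on trimmed, case-insensitive values but labelled with
    the first-seen spelling; each stratum gets its own heterogeneity test and
    model selection, and single-study strata are pooled trivially (k = 1).
    """
    try:
        labels = [r.stratum_value(key) for r in table.records]
    except KeyError:
        raise ConfigurationError(f"unknown stratification column {key!r}") from None
    seen: dict[str, str] = {}
    for lab in labels:
        seen.setdefault(lab.strip().casefold(), lab.strip())
    out: dict[str, PooledResult] = {}
    for norm, label in seen.items():
        sub = table.filter(key, label)
        out[label] = pool_auto(
            study_tables(sub, model),
            het_threshold=het_threshold,
            cc_increment=cc_increment,
            stratum=label,
        )
    return out
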
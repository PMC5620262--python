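"""Per-study effects, heterogeneity, and fixed/random-effects pooling.

The estimators here are the meta-analytic workhorses for 2x2 tables:

* per-study log odds ratio with the Woolf standard error
  ``sqrt(1/a + 1/b + 1/c + 1/d)``, Haldane-Anscombe 0.5 correction when a
  zero cell occurs;
* Cochran's Q from inverse-variance fixed weights, Higgins I^2 and the
  DerSimonian-Laird moment estimator of the between-study variance tau^2;
* fixed-effect pooling by Mantel-Haenszel (point estimate
  ``sum(a_i d_i / n_i) / sum(b_i c_i / n_i)`` with the
  Robins-Breslow-Greenland variance of the log OR) or by inverse-variance
  weighting;
* random-effects pooling by DerSimonian-Laird, i.e. inverse-variance
  weighting with ``tau^2`` added to each study's variance;
* the heterogeneity-threshold rule used to choose between the two: random
  effects when the Q-test P-value falls below the threshold (0.10 by
  default), fixed effects otherwise;
* the two-sided Z-test on the pooled log OR.

These are written out rather than delegated because the pooling machinery is
the package's subject matter; independent brute-force implementations check
them in the test-suite.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, PoolingError
from .models import (
    EffectEstimate,
    GeneticModel,
    HeterogeneityResult,
    ModelChoice,
    PooledResult,
    PoolMethod,
    TwoByTwo,
)

__all__ = [
    "Z_975",
    "study_effect",
    "q_test",
    "pool_fixed",
    "pool_random_dl",
    "select_model",
    "z_test",
    "pool_auto",
]

#: 97.5% standard-normal quantile used for every 95% CI (not the rounded 1.96).
Z_975 = float(stats.norm.ppf(0.975))


def study_effect(table: TwoByTwo, cc_increment: float = 0.5) -> EffectEstimate:
    """Crude log OR, Woolf SE and 95% CI for one 2x2 table.

    If any cell is zero, ``cc_increment`` is added to all four cells
    (Haldane-Anscombe) and the estimate is flagged as continuity-corrected.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise PoolingError(
            f"study {table.study_id!r}: a 2x2 margin is empty, no odds ratio exists"
        )
    corrected = table.has_zero_cell
    a, b, c, d = (
        (x + cc_increment for x in (table.a, table.b, table.c, table.d))
        if corrected
        else (table.a, table.b, table.c, table.d)
    )
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        study_id=table.study_id,
        model=table.model,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z_975 * se),
        ci_high=math.exp(log_or + Z_975 * se),
        continuity_corrected=corrected or table.continuity_corrected,
    )


def _check_single_model(items: Sequence) -> GeneticModel:
    models = {x.model for x in items}
    if len(models) != 1:
        raise PoolingError(f"inputs mix genetic models: {sorted(m.name for m in models)}")
    return models.pop()


def q_test(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q with I^2 and the DerSimonian-Laird tau^2.

    Q uses inverse-variance fixed weights (the DL convention); for a single
    study the result is the conventional degenerate one (q = 0, p = 1).
    """
    if not effects:
        raise PoolingError("q_test needs at least one effect")
    k = len(effects)
    if k == 1:
        return HeterogeneityResult(q=0.0, df=0, p_h=1.0, i2=0.0, tau2=0.0)
    theta = np.array([e.log_or for e in effects])
    w = 1.0 / np.array([e.se for e in effects]) ** 2
    mean = float((w * theta).sum() / w.sum())
    q = float((w * (theta - mean) ** 2).sum())
    df = k - 1
    p_h = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    c = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (q - df) / c) if q > df else 0.0
    return HeterogeneityResult(q=q, df=df, p_h=p_h, i2=i2, tau2=tau2)


def _finish(
    model: GeneticModel,
    method: PoolMethod,
    k: int,
    log_or: float,
    se: float,
    het: HeterogeneityResult,
    stratum: str,
) -> PooledResult:
    z = log_or / se
    return PooledResult(
        model=model,
        method=method,
        k=k,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z_975 * se),
        ci_high=math.exp(log_or + Z_975 * se),
        z=z,
        p=float(2.0 * stats.norm.sf(abs(z))),
        het=het,
        stratum=stratum,
    )


def pool_fixed(
    tables: Sequence[TwoByTwo],
    variance: str = "MH_RBG",
    cc_increment: float = 0.5,
    stratum: str = "total",
) -> PooledResult:
    """Fixed-effect pooled OR over 2x2 tables sharing one genetic model.

    ``variance="MH_RBG"`` (default) gives the Mantel-Haenszel point estimate
    with the Robins-Breslow-Greenland variance of its log; ``variance="IV"``
    pools the per-study log ORs with inverse-variance weights.  Either way the
    heterogeneity assessment from :func:`q_test` (on Woolf-weighted effects)
    is attached.
    """
    if not tables:
        raise PoolingError("pool_fixed needs at least one table")
    if variance not in ("MH_RBG", "IV"):
        raise ConfigurationError(f"unknown fixed-effect variance {variance!r}")
    model = _check_single_model(tables)
    effects = [study_effect(t, cc_increment) for t in tables]
    het = q_test(effects)
    k = len(tables)
    if variance == "IV":
        w = 1.0 / np.array([e.se for e in effects]) ** 2
        theta = np.array([e.log_or for e in effects])
        log_or = float((w * theta).sum() / w.sum())
        se = float(1.0 / math.sqrt(w.sum()))
        return _finish(model, PoolMethod.IV_FIXED, k, log_or, se, het, stratum)

    cells = np.array([[t.a, t.b, t.c, t.d] for t in tables], dtype=float)
    a, b, c, d = cells.T
    n = cells.sum(axis=1)
    r_i = a * d / n
    s_i = b * c / n
    r, s = r_i.sum(), s_i.sum()
    if r <= 0 or s <= 0:
        raise PoolingError("all tables degenerate: Mantel-Haenszel sums vanish")
    log_or = float(math.log(r / s))
    p_i = (a + d) / n
    q_i = (b + c) / n
    var = float(
        (p_i * r_i).sum() / (2 * r * r)
        + (p_i * s_i + q_i * r_i).sum() / (2 * r * s)
        + (q_i * s_i).sum() / (2 * s * s)
    )
    return _finish(model, PoolMethod.MH_FIXED, k, log_or, math.sqrt(var), het, stratum)


def pool_random_dl(
    effects: Sequence[EffectEstimate], stratum: str = "total"
) -> PooledResult:
    """DerSimonian-Laird random-effects pooled OR.

    With tau^2 = 0 (homogeneous inputs) this reduces exactly to
    inverse-variance fixed pooling.
    """
    if not effects:
        raise PoolingError("pool_random_dl needs at least one effect")
    model = _check_single_model(effects)
    het = q_test(effects)
    theta = np.array([e.log_or for e in effects])
    w = 1.0 / (np.array([e.se for e in effects]) ** 2 + het.tau2)
    log_or = float((w * theta).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    return _finish(model, PoolMethod.DL_RANDOM, len(effects), log_or, se, het, stratum)


def select_model(het: HeterogeneityResult, threshold: float = 0.10) -> ModelChoice:
    """Heterogeneity-driven choice: random effects iff P_h < threshold.

    The boundary is strict: P_h equal to the threshold selects fixed effects.
    """
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError(f"threshold must lie in (0, 1), got {threshold}")
    return ModelChoice.RANDOM if het.p_h < threshold else ModelChoice.FIXED


def z_test(pooled: PooledResult) -> float:
    """Two-sided normal tail probability of the pooled log OR / SE."""
    if pooled.se <= 0:
        raise PoolingError("z_test needs a positive standard error")
    return float(2.0 * stats.norm.sf(abs(pooled.log_or / pooled.se)))


def pool_auto(
    tables: Sequence[TwoByTwo],
    het_threshold: float = 0.10,
    cc_increment: float = 0.5,
    stratum: str = "total",
) -> PooledResult:
    """Pool with the model-selection rule applied.

    Computes per-study effects and the Q-test, then pools by DerSimonian-Laird
    when P_h < ``het_threshold`` and by Mantel-Haenszel (RBG variance)
    otherwise.  Single-study input degenerates to that study's crude OR.
    """
    if not tables:
        raise PoolingError("pool_auto needs at least one table")
    effects = [study_effect(t, cc_increment) for t in tables]
    het = q_test(effects)
    if select_model(het, het_threshold) is ModelChoice.RANDOM:
        return pool_random_dl(effects, stratum=stratum)
    return pool_fixed(tables, "MH_RBG", cc_increment, stratum=stratum)
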
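"""Per-study effects, heterogeneity, MH/IV/DL pooling and model selection."""

import math

import numpy as np
import pytest
from scipy import stats

from genemeta import (
    GeneticModel,
    GenotypeCounts,
    ModelChoice,
    PoolMethod,
    StudyRecord,
    StudyTable,
    TwoByTwo,
    pool_auto,
    pool_fixed,
    pool_random_dl,
    q_test,
    select_model,
    study_effect,
    study_tables,
    z_test,
)
from genemeta.errors import ConfigurationError, PoolingError
from oracles import oracle_dl, oracle_iv, oracle_mh, oracle_q_tau2

ALLELIC = GeneticModel.ALLELIC


def tbl(a, b, c, d, model=ALLELIC, sid=""):
    return TwoByTwo(a=a, b=b, c=c, d=d, model=model, study_id=sid)


def effect(log_or, se, model=ALLELIC, sid=""):
    from genemeta.models import EffectEstimate
    from genemeta.pooling import Z_975
    return EffectEstimate(
        study_id=sid, model=model, log_or=log_or, se=se, or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z_975 * se), ci_high=math.exp(log_or + Z_975 * se),
    )


class TestStudyEffect:
    def test_shi_cardia_substudy_allelic(self):
        """The 895-case/3,227-control sub-study: OR 0.90 (0.81-0.99)."""
        e = study_effect(tbl(897, 893, 3412, 3042))
        assert round(e.or_, 2) == 0.90
        assert (round(e.ci_low, 2), round(e.ci_high, 2)) == (0.81, 0.99)
        assert not e.continuity_corrected

    def test_balanced_table_is_null(self):
        e = study_effect(tbl(10, 10, 10, 10))
        assert e.log_or == pytest.approx(0.0)
        assert e.ci_low * e.ci_high == pytest.approx(1.0)  # symmetric on log scale

    def test_zero_cell_continuity_correction(self):
        e = study_effect(tbl(1, 0, 5, 5), cc_increment=0.5)
        assert e.continuity_corrected
        assert e.or_ == pytest.approx((1.5 * 5.5) / (0.5 * 5.5))

    def test_empty_margin_errors(self):
        with pytest.raises(PoolingError):
            study_effect(tbl(0, 0, 5, 5))


class TestQTest:
    def test_two_effects_by_hand(self):
        het = q_test([effect(0.0, 0.1), effect(0.2, 0.1)])
        assert het.q == pytest.approx(2.0)
        assert het.df == 1

    def test_identical_effects_are_homogeneous(self):
        het = q_test([effect(0.3, 0.2)] * 5)
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0
        assert het.tau2 == 0.0
        assert het.p_h == pytest.approx(1.0)

    def test_single_study_convention(self):
        het = q_test([effect(0.5, 0.1)])
        assert (het.q, het.df, het.p_h, het.i2, het.tau2) == (0.0, 0, 1.0, 0.0, 0.0)

    def test_korean_homozygote_heterogeneity(self, fixture_table):
        korea = fixture_table.filter("country", "Korea")
        effects = [study_effect(t) for t in study_tables(korea, GeneticModel.HOMOZYGOTE)]
        assert round(q_test(effects).p_h, 3) == 0.469


class TestPooling:
    def test_hb_heterozygote_mh(self, fixture_table):
        hb = fixture_table.filter("design", "HB")
        pooled = pool_fixed(study_tables(hb, GeneticModel.HETEROZYGOTE))
        assert pooled.method is PoolMethod.MH_FIXED
        assert round(pooled.or_, 2) == 0.73
        assert (round(pooled.ci_low, 2), round(pooled.ci_high, 2)) == (0.63, 0.84)
        assert round(pooled.het.p_h, 3) == 0.306

    def test_korea_homozygote_mh(self, fixture_table):
        korea = fixture_table.filter("country", "Korea")
        pooled = pool_fixed(study_tables(korea, GeneticModel.HOMOZYGOTE))
        assert round(pooled.or_, 2) == 0.56
        assert (round(pooled.ci_low, 2), round(pooled.ci_high, 2)) == (0.49, 0.64)

    def test_single_table_mh_equals_crude(self):
        t = tbl(30, 20, 25, 25, sid="s")
        pooled = pool_fixed([t])
        crude = study_effect(t)
        assert pooled.log_or == pytest.approx(crude.log_or, abs=1e-12)
        assert pooled.se == pytest.approx(crude.se, rel=1e-6)

    def test_total_allelic_dl(self, fixture_table):
        effects = [study_effect(t) for t in study_tables(fixture_table, ALLELIC)]
        pooled = pool_random_dl(effects)
        assert round(pooled.or_, 2) == 0.87
        assert (round(pooled.ci_low, 2), round(pooled.ci_high, 2)) == (0.73, 1.05)
        assert round(pooled.p, 3) == 0.140

    def test_total_dominant_dl(self, fixture_table):
        effects = [
            study_effect(t) for t in study_tables(fixture_table, GeneticModel.DOMINANT)
        ]
        pooled = pool_random_dl(effects)
        assert round(pooled.or_, 2) == 0.83
        assert (round(pooled.ci_low, 2), round(pooled.ci_high, 2)) == (0.65, 1.07)

    def test_dl_reduces_to_iv_when_homogeneous(self):
        # identical tables: q <= df so tau^2 is exactly zero and DL weights
        # coincide with IV weights, bit for bit
        tables = [tbl(30, 20, 25, 25, sid=f"s{i}") for i in range(4)]
        dl = pool_random_dl([study_effect(t) for t in tables])
        iv = pool_fixed(tables, "IV")
        assert dl.het.tau2 == 0.0
        assert dl.log_or == iv.log_or
        assert dl.se == iv.se

    def test_mixed_models_rejected(self):
        with pytest.raises(PoolingError, match="mix"):
            pool_fixed([tbl(5, 5, 5, 5), tbl(5, 5, 5, 5, model=GeneticModel.DOMINANT)])

    def test_dl_never_tighter_than_iv(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(2, 10))
            effects = [
                effect(float(rng.normal(0, 0.5)), float(rng.uniform(0.05, 0.6)))
                for _ in range(k)
            ]
            log_ors = [e.log_or for e in effects]
            ses = [e.se for e in effects]
            _, iv_se = oracle_iv(log_ors, ses)
            dl = pool_random_dl(effects)
            assert dl.se >= iv_se - 1e-12


class TestSelectionAndZ:
    @pytest.mark.parametrize(
        "p_h, choice",
        [(0.0004, ModelChoice.RANDOM), (0.306, ModelChoice.FIXED), (0.10, ModelChoice.FIXED)],
    )
    def test_threshold_rule(self, p_h, choice):
        from genemeta.models import HeterogeneityResult
        het = HeterogeneityResult(q=1.0, df=1, p_h=p_h, i2=0.0, tau2=0.0)
        assert select_model(het) is choice

    def test_bad_threshold(self):
        from genemeta.models import HeterogeneityResult
        het = HeterogeneityResult(q=0.0, df=0, p_h=1.0, i2=0.0, tau2=0.0)
        with pytest.raises(ConfigurationError):
            select_model(het, threshold=1.5)

    def test_z_test_matches_normal_tail(self):
        from genemeta.pooling import Z_975
        pooled = pool_random_dl([effect(0.0, 0.1)])
        assert z_test(pooled) == pytest.approx(1.0)
        pooled2 = pool_random_dl([effect(Z_975 * 0.1, 0.1)])
        assert z_test(pooled2) == pytest.approx(0.05, abs=1e-9)

    def test_pool_auto_follows_rule(self, fixture_table):
        total = pool_auto(study_tables(fixture_table, ALLELIC))
        assert total.method is PoolMethod.DL_RANDOM  # P_h < 0.001
        hb = fixture_table.filter("design", "HB")
        assert (
            pool_auto(study_tables(hb, GeneticModel.HETEROZYGOTE)).method
            is PoolMethod.MH_FIXED
        )


class TestAgainstOracles:
    def test_estimators_match_brute_force(self):
        """MH, IV, DL, Q and tau^2 agree with straight-from-formula loops to 1e-10."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            k = int(rng.integers(2, 8))
            cells = [[int(x) for x in rng.integers(1, 60, size=4)] for _ in range(k)]
            tables = [tbl(*row, sid=f"s{i}") for i, row in enumerate(cells)]
            effects = [study_effect(t) for t in tables]
            log_ors = [e.log_or for e in effects]
            ses = [e.se for e in effects]

            mh = pool_fixed(tables, "MH_RBG")
            o_lo, o_se = oracle_mh(cells)
            assert mh.log_or == pytest.approx(o_lo, abs=1e-10)
            assert mh.se == pytest.approx(o_se, abs=1e-10)

            iv = pool_fixed(tables, "IV")
            o_lo, o_se = oracle_iv(log_ors, ses)
            assert iv.log_or == pytest.approx(o_lo, abs=1e-10)
            assert iv.se == pytest.approx(o_se, abs=1e-10)

            dl = pool_random_dl(effects)
            o_lo, o_se = oracle_dl(log_ors, ses)
            assert dl.log_or == pytest.approx(o_lo, abs=1e-10)
            assert dl.se == pytest.approx(o_se, abs=1e-10)

            o_q, o_p, o_tau2 = oracle_q_tau2(log_ors, ses)
            het = q_test(effects)
            assert het.q == pytest.approx(o_q, abs=1e-10)
            assert het.p_h == pytest.approx(o_p, abs=1e-10)
            assert het.tau2 == pytest.approx(o_tau2, abs=1e-10)

    def test_orientation_antisymmetry(self):
        """Swapping exposed/unexposed labels negates the pooled log OR exactly."""
        rng = np.random.default_rng(3)
        for variance in ("MH_RBG", "IV"):
            for _ in range(20):
                k = int(rng.integers(2, 6))
                cells = [[int(x) for x in rng.integers(1, 40, size=4)] for _ in range(k)]
                fwd = [tbl(a, b, c, d, sid=f"s{i}") for i, (a, b, c, d) in enumerate(cells)]
                rev = [tbl(b, a, d, c, sid=f"s{i}") for i, (a, b, c, d) in enumerate(cells)]
                pf = pool_fixed(fwd, variance)
                pr = pool_fixed(rev, variance)
                assert pf.log_or == pytest.approx(-pr.log_or, abs=1e-12)
                assert pf.se == pytest.approx(pr.se, abs=1e-12)
                assert pf.ci_low == pytest.approx(1 / pr.ci_high, rel=1e-12)
                df = pool_random_dl([study_effect(t) for t in fwd])
                dr = pool_random_dl([study_effect(t) for t in rev])
                assert df.log_or == pytest.approx(-dr.log_or, abs=1e-12)


def test_fixed_ci_coverage_under_homogeneity():
    """The 95% fixed CI covers the true (null) OR in ~95% of simulated metas."""
    from genemeta.simulate import _hwe_probs

    rng = np.random.default_rng(15)
    reps, k, n, maf = 2000, 10, 300, 0.55
    probs = _hwe_probs(maf)
    covered = 0
    for _ in range(reps):
        tables = []
        for i in range(k):
            case = rng.multinomial(n, probs)
            ctrl = rng.multinomial(n, probs)
            tables.append(
                tbl(
                    2 * case[0] + case[1], 2 * case[2] + case[1],
                    2 * ctrl[0] + ctrl[1], 2 * ctrl[2] + ctrl[1],
                    sid=f"s{i}",
                )
            )
        pooled = pool_fixed(tables, "MH_RBG")
        covered += pooled.ci_low <= 1.0 <= pooled.ci_high
    assert abs(covered / reps - 0.95) <= 0.015
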
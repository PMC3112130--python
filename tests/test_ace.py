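"""Five-group ACE model: implied correlations, FIML likelihood, df, CIs."""

import math

import numpy as np
import pytest
from dataclasses import replace

from twinliab.ace import (ACEParams, MODELS, _Problem, _suffstats,
                          _threshold_starts, fit, fit_saturated,
                          implied_correlation, model_df, pair_loglik,
                          profile_ci, raw_df)
from twinliab.simulate import (GroupCounts, apply_model_structure,
                               paper_combined, simulate)
from twinliab.twin_io import TwinPairRecord


def _params(A=0.5, C=0.3, rc=1.0, tau=0.0, cohort="c1"):
    shares = {("M", cohort): (A, C, 1 - A - C), ("F", cohort): (A, C, 1 - A - C)}
    thr = {(s, z, cohort): tau for s in "MF" for z in ("MZ", "DZ")}
    return ACEParams.from_shares(shares, {cohort: rc}, thr)


class TestImpliedCorrelation:
    def test_pure_genetic(self):
        p = _params(A=1.0, C=0.0)
        assert implied_correlation(p, "MZM", "c1") == pytest.approx(1.0)
        assert implied_correlation(p, "DZM", "c1") == pytest.approx(0.5)

    def test_published_combined_male_shares(self):
        # A = .66, C = .14 imply the published MZM/DZM correlations .80 / .47
        p = _params(A=0.66, C=0.14)
        assert implied_correlation(p, "MZM", "c1") == pytest.approx(0.80, abs=1e-12)
        assert implied_correlation(p, "DZM", "c1") == pytest.approx(0.47, abs=1e-12)

    def test_symmetric_sexes_rcdos_one_matches_dz(self):
        p = _params(A=0.4, C=0.35, rc=1.0)
        assert implied_correlation(p, "DOS", "c1") == pytest.approx(
            implied_correlation(p, "DZF", "c1"), abs=1e-12
        )

    def test_rcdos_moderates_dos_only(self):
        lo = _params(A=0.4, C=0.35, rc=0.2)
        hi = _params(A=0.4, C=0.35, rc=1.0)
        assert implied_correlation(lo, "DOS", "c1") < implied_correlation(hi, "DOS", "c1")
        assert implied_correlation(lo, "DZM", "c1") == implied_correlation(hi, "DZM", "c1")


class TestPairLoglik:
    def test_comonotone_concordant_pair(self):
        p = _params(A=1.0, C=0.0)
        rec = TwinPairRecord("f", "MZM", "c1", 1, 1)
        assert pair_loglik(rec, p) == pytest.approx(math.log(0.5), abs=1e-9)

    def test_impossible_pattern_sentinel(self):
        p = _params(A=1.0, C=0.0)
        rec = TwinPairRecord("f", "MZM", "c1", 1, 0)
        assert pair_loglik(rec, p) <= -1e9

    def test_singleton_margin(self):
        # threshold at the 22.8% prevalence quantile
        p = _params(tau=0.74544955)
        rec = TwinPairRecord("f", "MZF", "c1", 1, None)
        assert pair_loglik(rec, p) == pytest.approx(math.log(0.228), abs=1e-7)

    def test_dataset_m2ll_matches_problem(self, preset_dataset):
        # per-record FIML sum equals the sufficient-statistic likelihood
        ds = preset_dataset
        stats = _suffstats(ds)
        problem = _Problem(stats, ds.cohorts, MODELS[1])
        x = problem.start_vector(0.5, 0.25, 0.8, _threshold_starts(stats, ds.cohorts))
        m2ll, _ = problem.m2ll_grad(x)
        params = problem.unpack(x)
        direct = -2.0 * sum(pair_loglik(r, params) for r in ds.records)
        assert m2ll == pytest.approx(direct, rel=1e-10)


class TestDegreesOfFreedom:
    def test_published_df_column(self):
        expected = {1: 4990, 2: 4992, 3: 4995, 4: 4995,
                    5: 4998, 6: 5001, 7: 5002, 8: 5002}
        for mid, df in expected.items():
            assert model_df(MODELS[mid], 5008) == df

    def test_full_model_parameter_count(self):
        # 12 paths + 8 thresholds + 2 Rcdos
        assert MODELS[1].n_free_params() == 22
        assert MODELS[1].n_constraints() == 4

    def test_saturated_correlation_arithmetic(self):
        # 5 free correlations + 8 thresholds, no constraints
        assert raw_df(5008, 5 + 8) == 4995


class TestGradient:
    @pytest.mark.parametrize("mid", [1, 6, 7])
    def test_analytic_gradient_matches_finite_differences(self, preset_dataset, mid):
        ds = preset_dataset
        stats = _suffstats(ds)
        problem = _Problem(stats, ds.cohorts, MODELS[mid])
        x = problem.start_vector(0.45, 0.3, 0.6, _threshold_starts(stats, ds.cohorts))
        rng = np.random.default_rng(mid)
        x = x + rng.normal(0, 0.1, x.shape)
        _, grad = problem.m2ll_grad(x)
        h = 1e-6
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (problem.m2ll_grad(xp)[0] - problem.m2ll_grad(xm)[0]) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-4)


def _quick_config(pairs=3000, A=0.55, C=0.23, prev=0.35):
    cfg = paper_combined()
    cfg6 = apply_model_structure(cfg, 6)
    shares = {k: (A, C, round(1 - A - C, 10)) for k in cfg6.shares}
    prevalence = {k: prev for k in cfg6.prevalence}
    counts = {k: GroupCounts(pairs, 0) for k in cfg6.counts}
    return replace(cfg6, shares=shares, prevalence=prevalence, counts=counts)


class TestFit:
    def test_model6_recovery(self):
        ds = simulate(_quick_config(pairs=5000), seed=13)
        res = fit(ds, MODELS[6])
        A, C, E = res.params.shares("M", ds.cohorts[0])
        assert A == pytest.approx(0.55, abs=0.06)
        assert C == pytest.approx(0.23, abs=0.06)
        assert A + C + E == pytest.approx(1.0, abs=1e-6)
        assert res.converged

    def test_submodel_deviance_never_below_parent(self, preset_dataset):
        f1 = fit(preset_dataset, MODELS[1])
        prev = {1: f1}
        for mid in range(2, 9):
            parent = prev[MODELS[mid].parent]
            sub = fit(preset_dataset, MODELS[mid], warm_start=parent)
            assert sub.minus2LL >= parent.minus2LL - 1e-3
            prev[mid] = sub

    def test_ace_nested_in_saturated(self, preset_dataset):
        sat = fit_saturated(preset_dataset)
        f1 = fit(preset_dataset, MODELS[1])
        assert f1.minus2LL >= sat["minus2LL"] - 1e-3

    def test_implied_correlation_between_tetrachorics(self):
        # the model-6 MZ correlation lies between the fitted MZ and DZ
        # group correlations on well-powered data
        from twinliab.tetrachoric import concordance_table, estimate_tetrachoric

        ds = simulate(_quick_config(pairs=10_000), seed=23)
        res = fit(ds, MODELS[6])
        rho_mz = implied_correlation(res.params, "MZM", ds.cohorts[0])
        rho_dz = implied_correlation(res.params, "DZM", ds.cohorts[0])
        r_mz = estimate_tetrachoric(
            [concordance_table(ds, g, c) for g in ("MZM", "MZF")
             for c in ds.cohorts], shared_threshold=False, ci=False).r
        r_dz = estimate_tetrachoric(
            [concordance_table(ds, g, c) for g in ("DZM", "DZF")
             for c in ds.cohorts], shared_threshold=False, ci=False).r
        assert rho_dz - 0.02 < r_dz and r_mz < rho_mz + 0.02
        assert rho_dz < rho_mz

    def test_cohort_requirement(self):
        cfg = _quick_config(pairs=50)
        one_cohort = replace(
            cfg,
            cohorts=(cfg.cohorts[0],),
            counts={k: v for k, v in cfg.counts.items() if k[0] == cfg.cohorts[0]},
            shares={k: v for k, v in cfg.shares.items() if k[1] == cfg.cohorts[0]},
            rcdos={cfg.cohorts[0]: 1.0},
            prevalence={k: v for k, v in cfg.prevalence.items() if k[2] == cfg.cohorts[0]},
        )
        ds = simulate(one_cohort, seed=2)
        with pytest.raises(ValueError):
            fit(ds, MODELS[3])


class TestProfileCI:
    def test_boundary_truncation_when_component_is_zero(self):
        ds = simulate(_quick_config(pairs=4000, A=0.6, C=0.0), seed=31)
        res = fit(ds, MODELS[6])
        lo, hi = profile_ci(res, ("C", "M", ds.cohorts[0]))
        assert lo == 0.0
        assert hi < 0.2

    def test_interval_covers_mle_and_e_excludes_zero(self, preset_dataset):
        res = fit(preset_dataset, MODELS[6])
        c = preset_dataset.cohorts[0]
        for comp in ("A", "C", "E"):
            lo, hi = profile_ci(res, (comp, "M", c))
            mle = res.params.shares("M", c)[("A", "C", "E").index(comp)]
            assert lo - 1e-6 <= mle <= hi + 1e-6
        lo_e, _ = profile_ci(res, ("E", "M", c))
        assert lo_e > 0.0  # discordant MZ pairs force E away from zero
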
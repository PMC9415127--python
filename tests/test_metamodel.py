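"""Weighted crossed-random-effects model, AICc selection, and summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ltelegacy import metamodel
from ltelegacy.exceptions import DomainError, RankDeficientError
from ltelegacy.ltedata import CovariateSet, Crop, Method
from ltelegacy.metamodel import (
    CANDIDATE_TERMS,
    ModelData,
    ModelSpec,
    aicc,
    covariate_diagnostics,
    dredge,
    fit_mixed,
    mean_delta_re,
    method_contrast,
    standardise,
)
from ltelegacy.recovery import RecoveryRecord


def naive_m2l(gs, gy, X, y, Zs, Zy, w, reml):
    """Independent brute-force evaluation of the profiled -2 log likelihood."""
    n, p = X.shape
    V = gs * Zs @ Zs.T + gy * Zy @ Zy.T + np.diag(1.0 / w)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    q = r @ Vi @ r
    if reml:
        dof = n - p
        s2 = q / dof
        return (
            dof * np.log(2 * np.pi * s2)
            + np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(X.T @ Vi @ X)[1]
            + dof
        )
    s2 = q / n
    return n * np.log(2 * np.pi * s2) + np.linalg.slogdet(V)[1] + n


def make_record(site, year, y, weight=1.0, crop=Crop.winter_wheat,
                method=Method.isotope15N, **cov):
    defaults = dict(
        gdd=3000.0, temp_seasonality=8.0, aridity=0.8, duration_years=20,
        avg_n_rate=150.0, clay_pct=20.0, residue_retained=False,
    )
    defaults.update(cov)
    cs = CovariateSet(crop=crop, method=method, **defaults)
    return RecoveryRecord(
        site_id=site, year=year, crop=crop, method=method, n_rate=150.0,
        re_1st=0.4, re_lt=0.4 + y, delta_re=y, weight=weight, covariates=cs,
    )


@pytest.fixture()
def tiny_instance():
    """Fixed 8-observation, 2-site x 2-year design with unequal weights."""
    frame = pd.DataFrame(
        {
            "y": [0.21, 0.35, 0.11, 0.30, 0.25, 0.42, 0.05, 0.28],
            "weight": [1.0, 2.0, 1.0, 3.0, 2.0, 1.0, 2.0, 1.0],
            "site": ["a", "a", "a", "a", "b", "b", "b", "b"],
            "year": [2000, 2000, 2001, 2001, 2000, 2000, 2001, 2001],
        }
    )
    return ModelData(frame=frame, terms={})


def _design_pieces(data):
    f = data.frame
    X = np.ones((len(f), 1))
    y = f["y"].to_numpy()
    w = f["weight"].to_numpy()
    Zs = pd.get_dummies(f["site"]).to_numpy(dtype=float)
    Zy = pd.get_dummies(f["year"]).to_numpy(dtype=float)
    return X, y, w, Zs, Zy


class TestFitMixed:
    def test_gamma_zero_equals_weighted_least_squares(self, tiny_instance):
        fit = fit_mixed(ModelSpec(estimation="REML"), tiny_instance, fix_gammas=(0, 0))
        _, y, w, _, _ = _design_pieces(tiny_instance)
        wls = np.sum(w * y) / np.sum(w)
        assert fit.beta["intercept"] == pytest.approx(wls, abs=1e-8)
        resid = y - wls
        s2 = np.sum(w * resid**2) / (len(y) - 1)  # REML divisor n - p
        assert fit.sigma2_resid == pytest.approx(s2, abs=1e-8)

    @pytest.mark.parametrize("estimation", ["ML", "REML"])
    def test_optimum_dominates_grid_oracle(self, tiny_instance, estimation):
        fit = fit_mixed(ModelSpec(estimation=estimation), tiny_instance)
        X, y, w, Zs, Zy = _design_pieces(tiny_instance)
        reml = estimation == "REML"
        grid = np.linspace(0.0, 5.0, 40)
        opt = -2.0 * fit.loglik
        grid_min = min(
            naive_m2l(gs, gy, X, y, Zs, Zy, w, reml)
            for gs, gy in itertools.product(grid, grid)
        )
        assert opt <= grid_min + 1e-8
        # and the in-house criterion agrees with the naive formula at the optimum
        assert opt == pytest.approx(
            naive_m2l(*fit.gammas, X, y, Zs, Zy, w, reml), abs=1e-8
        )

    def test_matches_statsmodels_crossed_variance_components(self):
        """Unweighted crossed-intercepts REML fit agrees with statsmodels MixedLM."""
        smf = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(42)
        rows = []
        bs = rng.normal(0, 0.5, 6)
        by = rng.normal(0, 0.3, 4)
        for s in range(6):
            for yy in range(4):
                for _ in range(2):
                    rows.append(
                        dict(site=f"s{s}", year=2000 + yy, weight=1.0,
                             y=1.0 + bs[s] + by[yy] + rng.normal(0, 0.4))
                    )
        df = pd.DataFrame(rows)
        fit = fit_mixed(ModelSpec(estimation="REML"), ModelData(frame=df, terms={}))
        md = smf.mixedlm(
            "y ~ 1", df, groups=np.ones(len(df)),
            vc_formula={"site": "0 + C(site)", "year": "0 + C(year)"},
        ).fit(reml=True)
        assert fit.beta["intercept"] == pytest.approx(md.params["Intercept"], abs=1e-6)
        assert fit.loglik == pytest.approx(md.llf, abs=1e-4)
        assert fit.sigma2_site == pytest.approx(md.vcomp[0], abs=2e-3)
        assert fit.sigma2_year == pytest.approx(md.vcomp[1], abs=2e-3)
        assert fit.sigma2_resid == pytest.approx(md.scale, abs=2e-3)

    def test_parameter_recovery_over_replicates(self):
        """Variance components and intercept are recovered on average."""
        truth = dict(mu=0.25, s2_site=0.04**2, s2_year=0.025**2, s2_resid=0.03**2)
        rng = np.random.default_rng(123)
        mus, s2s, s2y, s2e = [], [], [], []
        for _ in range(200):
            rows = []
            bs = rng.normal(0, np.sqrt(truth["s2_site"]), 8)
            by = rng.normal(0, np.sqrt(truth["s2_year"]), 6)
            for s in range(8):
                for yy in range(6):
                    rows.append(
                        dict(site=f"s{s}", year=yy, weight=1.0,
                             y=truth["mu"] + bs[s] + by[yy]
                             + rng.normal(0, np.sqrt(truth["s2_resid"])))
                    )
            fit = fit_mixed(
                ModelSpec(estimation="REML"),
                ModelData(frame=pd.DataFrame(rows), terms={}),
            )
            mus.append(fit.beta["intercept"])
            s2s.append(fit.sigma2_site)
            s2y.append(fit.sigma2_year)
            s2e.append(fit.sigma2_resid)
        assert np.mean(mus) == pytest.approx(truth["mu"], abs=0.01)
        assert np.mean(s2s) == pytest.approx(truth["s2_site"], rel=0.30)
        assert np.mean(s2y) == pytest.approx(truth["s2_year"], rel=0.30)
        assert np.mean(s2e) == pytest.approx(truth["s2_resid"], rel=0.10)

    def test_single_site_free_estimation_rejected(self):
        records = [make_record("a", 2000 + i, 0.2 + 0.01 * i) for i in range(5)]
        data = standardise(records, terms=[])
        with pytest.raises(DomainError):
            fit_mixed(ModelSpec(), data)


class TestAicc:
    def test_forced_arithmetic(self):
        assert aicc(-50, 3, 66) == pytest.approx(106.387, abs=1e-3)

    def test_matches_formula_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            l = rng.normal(-40, 20)
            k = int(rng.integers(1, 12))
            n = int(rng.integers(k + 2, 200))
            assert aicc(l, k, n) == pytest.approx(
                -2 * l + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            )

    def test_approaches_aic_for_large_n(self):
        assert aicc(-50, 4, 10**6) == pytest.approx(108.0, abs=1e-4)

    def test_small_sample_domain_error(self):
        with pytest.raises(DomainError):
            aicc(-50, 5, 6)


class TestStandardise:
    def test_continuous_columns_are_z_scored(self, study_records):
        data = standardise(study_records)
        for col in ("gdd", "clay_pct", "duration_years"):
            x = data.frame[col].to_numpy()
            assert x.mean() == pytest.approx(0.0, abs=1e-12)
            assert x.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_binary_flag_left_untouched(self, study_records):
        data = standardise(study_records)
        assert set(np.unique(data.frame["residue_retained"])) <= {0.0, 1.0}

    def test_round_trip_unscale(self, study_records):
        data = standardise(study_records)
        raw = np.array([r.covariates.gdd for r in study_records])
        assert np.allclose(data.unscale("gdd", data.frame["gdd"]), raw)

    def test_zero_variance_covariate_named_in_error(self):
        records = [make_record("a", 2000, 0.2), make_record("b", 2001, 0.3)]
        with pytest.raises(DomainError, match="gdd"):
            standardise(records, terms=["gdd"])

    def test_categorical_reference_is_alphabetical(self, study_records):
        data = standardise(study_records)
        # maize < winter_wheat, isotope15N < subplot: references dropped
        assert data.terms["crop"] == ["crop_winter_wheat"]
        assert data.terms["method"] == ["method_subplot"]


class TestMeanDeltaRe:
    def test_single_site_collapses_to_classical_t_interval(self):
        y = np.array([0.18, 0.22, 0.25, 0.31, 0.20, 0.27])
        records = [make_record("only", 2000 + i, v) for i, v in enumerate(y)]
        res = mean_delta_re(records, fix_gammas=(0.0, 0.0))
        from scipy import stats as sps

        assert res.estimate == pytest.approx(y.mean(), abs=1e-10)
        se = y.std(ddof=1) / np.sqrt(len(y))
        assert res.se == pytest.approx(se, abs=1e-10)
        tcrit = sps.t.ppf(0.975, len(y) - 1)
        assert res.ci_low == pytest.approx(y.mean() - tcrit * se, abs=1e-9)

    def test_weight_scale_invariance(self, study_records):
        base = mean_delta_re(study_records)
        scaled = mean_delta_re(
            [r.model_copy(update={"weight": 10 * r.weight}) for r in study_records]
        )
        assert scaled.estimate == pytest.approx(base.estimate, abs=1e-6)

    def test_shift_equivariance(self, study_records):
        base = mean_delta_re(study_records)
        shifted = mean_delta_re(
            [r.model_copy(update={"delta_re": r.delta_re + 0.1}) for r in study_records]
        )
        assert shifted.estimate - base.estimate == pytest.approx(0.1, abs=1e-7)

    def test_plain_weighted_mean(self, study_records):
        w = np.array([r.weight for r in study_records])
        y = np.array([r.delta_re for r in study_records])
        res = mean_delta_re(study_records)
        assert res.plain_weighted_mean == pytest.approx(np.sum(w * y) / np.sum(w))


class TestDredge:
    def test_intercept_only_candidate_set_yields_one_model(self, study_records):
        data = standardise(study_records)
        result = dredge(data, candidate_terms=())
        assert len(result.entries) == 1
        assert result.entries[0].spec.fixed_terms == ()
        assert result.entries[0].delta_aicc == 0.0

    def test_two_candidates_yield_four_models_ranked(self, study_records):
        data = standardise(study_records)
        result = dredge(data, candidate_terms=("crop", "clay"))
        assert len(result.entries) == 4
        aiccs = [e.aicc for e in result.entries]
        assert aiccs == sorted(aiccs)
        assert result.entries[0].delta_aicc == 0.0

    def test_ranking_invariant_to_record_order(self, study_records):
        data1 = standardise(study_records)
        shuffled = list(study_records)
        np.random.default_rng(5).shuffle(shuffled)
        data2 = standardise(shuffled)
        r1 = dredge(data1, candidate_terms=("crop", "method", "clay"))
        r2 = dredge(data2, candidate_terms=("crop", "method", "clay"))
        assert [e.spec.fixed_terms for e in r1.entries] == [
            e.spec.fixed_terms for e in r2.entries
        ]
        assert np.allclose(
            [e.aicc for e in r1.entries], [e.aicc for e in r2.entries], atol=1e-6
        )

    def test_selects_the_true_crop_signal(self):
        """With a strong crop effect and noise covariates, dredge keeps crop."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            records = []
            for s in range(8):
                crop = Crop.winter_wheat if s < 4 else Crop.maize
                effect = 0.15 if crop is Crop.winter_wheat else 0.0
                b = rng.normal(0, 0.02)
                cov = dict(
                    gdd=float(rng.uniform(2500, 3900)),
                    aridity=float(rng.uniform(0.5, 1.0)),
                    clay_pct=float(rng.uniform(15, 28)),
                )
                for yy in range(4):
                    records.append(
                        make_record(
                            f"s{s}", 2000 + yy,
                            0.1 + effect + b + rng.normal(0, 0.03),
                            crop=crop, **cov,
                        )
                    )
            data = standardise(records, terms=["gdd", "aridity", "crop", "clay"])
            result = dredge(data, candidate_terms=("gdd", "aridity", "crop", "clay"))
            if any("crop" in e.spec.fixed_terms for e in result.best_set):
                hits += 1
        assert hits >= 0.9 * n_rep


class TestMethodContrast:
    def test_identical_methods_give_zero_contrast(self):
        records = []
        for s in range(4):
            for yy in range(3):
                y = 0.2 + 0.02 * s + 0.01 * yy
                records.append(make_record(f"s{s}", 2000 + yy, y, method=Method.isotope15N))
                records.append(make_record(f"s{s}", 2000 + yy, y, method=Method.subplot))
        mc = method_contrast(records)
        assert mc.contrast_all == pytest.approx(0.0, abs=1e-8)
        assert mc.contrast_paired == pytest.approx(0.0, abs=1e-8)
        assert mc.n_paired == len(records)

    def test_single_method_rejected(self):
        records = [make_record(f"s{i}", 2000, 0.2 + 0.01 * i) for i in range(4)]
        with pytest.raises(DomainError):
            method_contrast(records)

    def test_reports_both_all_and_paired_estimates(self, study_records):
        mc = method_contrast(study_records)
        assert np.isfinite(mc.contrast_all) and np.isfinite(mc.contrast_paired)
        assert 0 < mc.n_paired < mc.n_all


class TestDiagnostics:
    def test_duplicated_covariate_flagged(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(8):
            g = float(rng.uniform(2500, 3900))
            records.append(
                make_record(f"s{i}", 2000, float(rng.normal(0.2, 0.05)),
                            gdd=g, clay_pct=g / 200.0)  # affine copy of gdd
            )
        diag = covariate_diagnostics(records)
        pairs = {(a, b) for a, b, _ in diag.collinear_pairs}
        assert ("gdd", "clay_pct") in pairs

    def test_matrix_symmetric_unit_diagonal(self, study_records):
        corr = covariate_diagnostics(study_records).correlations
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_response_shape_summaries_present(self, study_records):
        diag = covariate_diagnostics(study_records)
        assert {"delta_re", "re_1st", "re_lt"} <= set(diag.response_shape)


def test_rank_deficient_design_raises(study_records):
    records = [
        r.model_copy(
            update={"covariates": r.covariates.model_copy(update={"clay_pct": r.covariates.gdd / 100.0})}
        )
        for r in study_records
    ]
    data = standardise(records, terms=["gdd", "clay"])
    with pytest.raises(RankDeficientError):
        fit_mixed(ModelSpec(fixed_terms=("gdd", "clay"), estimation="ML"), data)
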
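"""Weighted penalized GAMLSS fitting, selection, prediction, z-scores."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize, stats

import refcurve as rc
from refcurve import families
from refcurve.continuous_model import (
    ContinuousModel,
    fit_weighted_gamlss,
    select_best_family,
)
from refcurve.core_io import ExtrapolationError, FittingError, PipelineConfig
from refcurve.synthetic_data import alp_like, generate_dataset, truth_percentiles


def _clean_data(n, seed, scenario=None):
    sc = scenario or alp_like(n_total=n, seed=seed, pathological_fraction=0.0,
                              samples_per_subject=((1, 1.0),))
    ms, _ = generate_dataset(sc)
    return sc, ms


@pytest.fixture(scope="module")
def clean_fit():
    """BCCG fit on clean data with unit weights (n = 20k)."""
    sc, ms = _clean_data(20_000, 2024)
    w = np.ones(len(ms))
    model = fit_weighted_gamlss(ms.age_days, ms.values, w, family="BCCG",
                                config=PipelineConfig(rng_seed=1))
    return sc, ms, model


class TestFitRecovery:
    def test_clean_unit_weight_recovery(self, clean_fit):
        sc, ms, model = clean_fit
        ages = np.linspace(0, 6570, 60).astype(int)
        truth = truth_percentiles(sc, ages, (0.025, 0.5, 0.975))
        fit = model.predict_percentiles(ages, (0.025, 0.5, 0.975))
        rel = np.abs(fit.values / truth.values - 1.0)
        assert rel[:, 1].max() < 0.03   # median within 3%
        assert rel.max() < 0.07         # outer percentiles within 7%

    def test_consistency_error_shrinks_with_n(self, clean_fit):
        sc_small, ms_small = _clean_data(2000, 2024)
        w = np.ones(len(ms_small))
        small = fit_weighted_gamlss(ms_small.age_days, ms_small.values, w,
                                    family="BCCG", config=PipelineConfig(rng_seed=1))
        _, ms, model = clean_fit
        sc = sc_small
        ages = np.linspace(30, 6500, 40).astype(int)
        truth = truth_percentiles(sc, ages, (0.5,)).values[:, 0]
        err_small = np.abs(small.predict_percentiles(ages, (0.5,)).values[:, 0] / truth - 1).max()
        err_big = np.abs(model.predict_percentiles(ages, (0.5,)).values[:, 0] / truth - 1).max()
        assert err_big < 0.03
        assert err_big <= err_small + 0.005

    def test_zero_weighted_contaminants_do_not_move_fit(self):
        sc, ms = _clean_data(8000, 77)
        rng = np.random.default_rng(8)
        n_bad = 800
        bad_ages = rng.integers(0, 6570, n_bad)
        bad_vals = sc.mu_fn(bad_ages) * 3.0
        ages = np.concatenate([ms.age_days, bad_ages])
        values = np.concatenate([ms.values, bad_vals])
        w = np.concatenate([np.ones(len(ms)), np.zeros(n_bad)])
        cfg = PipelineConfig(rng_seed=2)
        pens = {"mu": 10.0, "sigma": 100.0, "lam": 100.0}
        contaminated = fit_weighted_gamlss(ages, values, w, family="BCCG",
                                           config=cfg, penalties=pens)
        clean = fit_weighted_gamlss(ms.age_days, ms.values, np.ones(len(ms)),
                                    family="BCCG", config=cfg, penalties=pens)
        hi = min(contaminated.age_max, clean.age_max)
        lo = max(contaminated.age_min, clean.age_min)
        grid = np.linspace(lo, hi, 40).astype(int)
        a = contaminated.predict_percentiles(grid, (0.025, 0.5, 0.975)).values
        b = clean.predict_percentiles(grid, (0.025, 0.5, 0.975)).values
        np.testing.assert_allclose(a, b, rtol=0.02)

    def test_constant_age_collapses_to_1d_ml_fit(self):
        rng = np.random.default_rng(3)
        n = 3000
        y = families.sample(n, 100.0, 0.15, 0.5, rng=rng)
        ages = np.full(n, 500)
        model = fit_weighted_gamlss(ages, y, np.ones(n), family="BCCG",
                                    config=PipelineConfig(rng_seed=1),
                                    penalties={"mu": 1.0, "sigma": 1.0, "lam": 1.0})
        # independent 1-D maximum-likelihood oracle over (mu, sigma, lam)
        def nll(p):
            mu, log_sig, lam = p
            return -np.sum(families.log_density(y, mu, np.exp(log_sig), lam))

        res = optimize.minimize(nll, [np.median(y), np.log(0.2), 0.3],
                                method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        mu_hat, sig_hat = res.x[0], np.exp(res.x[1])
        params = model.params_at([500])
        assert params["mu"][0] == pytest.approx(mu_hat, rel=5e-3)
        assert params["sigma"][0] == pytest.approx(sig_hat, rel=2e-2)

    def test_weight_scaling_invariance_with_matched_penalties(self):
        sc, ms = _clean_data(4000, 5)
        cfg = PipelineConfig(rng_seed=3)
        w = np.ones(len(ms))
        c = 0.25
        pens = {"mu": 20.0, "sigma": 20.0, "lam": 20.0}
        pens_scaled = {k: v * c for k, v in pens.items()}
        m1 = fit_weighted_gamlss(ms.age_days, ms.values, w, family="BCCG",
                                 config=cfg, penalties=pens)
        m2 = fit_weighted_gamlss(ms.age_days, ms.values, w * c, family="BCCG",
                                 config=cfg, penalties=pens_scaled)
        grid = np.linspace(0, 6570, 30).astype(int)
        np.testing.assert_allclose(
            m1.predict_percentiles(grid).values,
            m2.predict_percentiles(grid).values, rtol=1e-4,
        )

    def test_too_few_weighted_points_rejected(self):
        rng = np.random.default_rng(1)
        n = 400
        with pytest.raises(FittingError):
            fit_weighted_gamlss(
                rng.integers(0, 100, n), rng.uniform(1, 2, n), np.ones(n)
            )


class TestFamilySelection:
    def test_single_model_selected(self):
        m = ContinuousModel(family="BCCG", curves={}, age_min=0, age_max=1,
                            loglik=0.0, bic=100.0, n_eff=10.0)
        assert select_best_family([m]) is m

    def test_argmin_bic(self):
        ms = [
            ContinuousModel(family=f, curves={}, age_min=0, age_max=1,
                            loglik=0.0, bic=b, n_eff=10.0)
            for f, b in [("BCCG", 1000.0), ("BCPE", 999.0), ("BCT", 1001.0)]
        ]
        assert select_best_family(ms).bic == 999.0

    def test_all_failed_is_fatal(self):
        with pytest.raises(rc.PipelineError):
            select_best_family([None, None])

    def test_heavy_tailed_data_selects_bct(self):
        """Simulation study: data from BCT with tau = 4 should be recognized
        by BIC against BCCG/BCPE in most seeded replicates (scaled-down)."""
        wins = 0
        n = 6000
        pens = {"mu": 10.0, "sigma": 100.0, "lam": 100.0, "tau": 100.0}
        for rep in range(6):
            rng = np.random.default_rng(1000 + rep)
            ages = rng.integers(0, 6570, n)
            u = np.log(ages + 1.0)
            mu = 100.0 + 10.0 * np.sin(u / 2.0)
            y = families.quantile(
                rng.uniform(1e-9, 1 - 1e-9, n), mu, 0.15, 0.5,
                family="BCT", tau=4.0,
            )
            cfg = PipelineConfig(rng_seed=rep)
            fits = []
            for fam in ("BCCG", "BCPE", "BCT"):
                p = {k: v for k, v in pens.items()
                     if k != "tau" or fam != "BCCG"}
                fits.append(fit_weighted_gamlss(ages, y, np.ones(n), family=fam,
                                                config=cfg, penalties=p))
            if select_best_family(fits).family == "BCT":
                wins += 1
        assert wins >= 5


class TestPrediction:
    def test_default_probs_have_seven_columns(self, clean_fit):
        _, _, model = clean_fit
        table = model.predict_percentiles(np.array([10, 100, 1000]))
        assert len(table.probs) == 7
        assert table.values.shape == (3, 7)

    def test_rows_strictly_increasing(self, clean_fit):
        _, _, model = clean_fit
        table = model.predict_percentiles(np.arange(0, 6571, 37))
        assert np.all(np.diff(table.values, axis=1) > 0)

    def test_matches_direct_quantile_calls(self, clean_fit):
        _, _, model = clean_fit
        ages = np.array([5, 250, 4000])
        probs = (0.1, 0.5, 0.9)
        table = model.predict_percentiles(ages, probs)
        th = model.params_at(ages)
        for j, p in enumerate(probs):
            direct = families.quantile(p, th["mu"], th["sigma"], th["lam"],
                                       family=model.family, tau=th.get("tau"))
            np.testing.assert_allclose(table.values[:, j], direct, rtol=1e-12)

    def test_extrapolation_refused(self, clean_fit):
        _, _, model = clean_fit
        with pytest.raises(ExtrapolationError):
            model.predict_percentiles(np.array([model.age_max + 1]))

    def test_percentile_non_crossing_dense_grid(self, clean_fit):
        _, _, model = clean_fit
        dense = np.arange(model.age_min, model.age_max + 1)
        table = model.predict_percentiles(dense)
        assert np.all(np.diff(table.values, axis=1) > 0)


class TestZScores:
    def test_97_5th_percentile_maps_to_1_96(self, clean_fit):
        _, _, model = clean_fit
        for age in (0, 30, 365, 3000, 6570):
            y = model.predict_percentiles(np.array([age]), (0.975,)).values[0, 0]
            z = model.value_to_zscore(y, np.array([age]))
            assert abs(float(z) - 1.959964) < 1e-6

    def test_median_maps_to_zero(self, clean_fit):
        _, _, model = clean_fit
        y = model.predict_percentiles(np.array([100]), (0.5,)).values[0, 0]
        assert float(model.value_to_zscore(y, np.array([100]))) == pytest.approx(0.0, abs=1e-8)

    def test_round_trip_on_probability_grid(self, clean_fit):
        _, _, model = clean_fit
        probs = np.linspace(0.02, 0.98, 25)
        age = np.array([400])
        for p in probs:
            y = model.predict_percentiles(age, (p,)).values[0, 0]
            z = float(model.value_to_zscore(y, age))
            assert stats.norm.cdf(z) == pytest.approx(p, abs=1e-7)

    def test_monotone_in_value(self, clean_fit):
        _, _, model = clean_fit
        ys = np.linspace(50, 600, 40)
        zs = np.array([float(model.value_to_zscore(y, np.array([200]))) for y in ys])
        assert np.all(np.diff(zs) > 0)

    def test_extreme_values_censored_to_infinity(self, clean_fit):
        _, _, model = clean_fit
        z = model.value_to_zscore(1e12, np.array([100]))
        assert np.isinf(float(z))


class TestSerialization:
    def test_round_trip_bit_identical_predictions(self, clean_fit, tmp_path):
        _, _, model = clean_fit
        path = tmp_path / "model.json"
        model.save(path)
        back = ContinuousModel.load(path)
        ages = np.arange(0, 6571, 97)
        a = model.predict_percentiles(ages).values
        b = back.predict_percentiles(ages).values
        np.testing.assert_array_equal(a, b)
        assert back.family == model.family
        assert back.bic == model.bic
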
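"""Density-ratio weights: KDE, ratio, smoothing, assignment, correction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import refcurve as rc
from refcurve.age_partition import AgeGroup
from refcurve.core_io import MeasurementSet, ValidationError
from refcurve.indirect_np import NPModel, bcn_pdf
from refcurve.weighting import (
    assign_single_weight,
    density_ratio_weights,
    empirical_density,
    gaussian_smooth,
    raw_density_ratio,
    subject_correction,
)


class TestEmpiricalDensity:
    def test_uniform_density_level(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, size=10_000)
        d = empirical_density(values, np.array([0.5]))
        assert d[0] == pytest.approx(1.0, rel=0.10)

    def test_far_tail_vanishes(self):
        rng = np.random.default_rng(1)
        values = rng.normal(100, 5, size=2000)
        d = empirical_density(values, np.array([1e4]))
        assert d[0] < 1e-6

    def test_matches_brute_force_kernel_sum(self):
        rng = np.random.default_rng(2)
        values = rng.normal(50, 8, size=400)
        pts = np.array([40.0, 50.0, 66.0])
        d = empirical_density(values, pts)
        # Silverman bandwidth as scipy defines it: factor * data sd
        n = len(values)
        factor = (n * 3.0 / 4.0) ** (-1.0 / 5.0)
        bw = factor * values.std(ddof=1)
        brute = np.array([
            np.mean(np.exp(-0.5 * ((p - values) / bw) ** 2)) / (bw * np.sqrt(2 * np.pi))
            for p in pts
        ])
        np.testing.assert_allclose(d, brute, atol=1e-10)

    def test_zero_variance_degenerate(self):
        with pytest.raises(ValidationError):
            empirical_density(np.full(100, 3.0), np.array([3.0]))

    def test_integrates_to_about_one(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(3, 0.3, size=3000)
        grid = np.linspace(0.01, values.max() * 2, 4000)
        d = empirical_density(values, grid)
        assert np.trapezoid(d, grid) == pytest.approx(1.0, abs=0.02)


class TestDensityRatio:
    def _model(self):
        return NPModel(lam=0.5, mu=100.0, sigma=0.12, np_fraction=0.9)

    def test_raw_ratio_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        model = self._model()
        values = rng.normal(100, 14, size=1500)
        values = values[values > 0]
        grid = np.linspace(values.min(), values.max(), 256)
        ratio, _ = raw_density_ratio(values, model, grid)
        d_total = empirical_density(values, grid)
        oracle = np.where(
            d_total > 0, model.np_fraction * bcn_pdf(grid, model) / d_total, 0.0
        )
        np.testing.assert_allclose(ratio, oracle, atol=1e-10)

    def test_smoothing_matches_explicit_convolution_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 2, size=200)
        sd = 2.0
        out = gaussian_smooth(x, sd)
        r = int(4.0 * sd + 0.5)
        k = np.exp(-0.5 * (np.arange(-r, r + 1) / sd) ** 2)
        k /= k.sum()
        oracle = np.empty_like(x)
        for i in range(len(x)):
            acc = 0.0
            for j in range(-r, r + 1):
                idx = min(max(i + j, 0), len(x) - 1)
                acc += k[j + r] * x[idx]
            oracle[i] = acc
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_weight_is_one_where_model_exceeds_data(self):
        # concentrate D_np above D_total near the peak: small np sample with
        # a wide total spread keeps the KDE denominator low at the mode
        rng = np.random.default_rng(6)
        model = NPModel(lam=1.0, mu=100.0, sigma=0.05, np_fraction=1.0)
        values = rng.uniform(50, 150, size=2000)  # flat D_total ~ 0.01
        w = density_ratio_weights(values, model, at=np.array([100.0]))
        assert w[0] == 1.0

    def test_far_tail_weight_vanishes(self):
        rng = np.random.default_rng(7)
        model = self._model()
        clean = rng.normal(100, 12, size=1800)
        path = rng.normal(300, 10, size=200)
        values = np.concatenate([clean, path])
        w = density_ratio_weights(values, model, at=np.array([295.0, 300.0, 310.0]))
        assert np.all(w < 0.05)

    def test_weights_clipped_to_unit_interval(self):
        rng = np.random.default_rng(8)
        model = self._model()
        values = np.abs(rng.normal(100, 15, size=1000)) + 1.0
        w = density_ratio_weights(values, model)
        assert np.all((w >= 0) & (w <= 1))


def _toy_ms(ages, subjects=None, values=None):
    n = len(ages)
    return MeasurementSet(
        pd.DataFrame(
            {
                "value": values if values is not None else np.full(n, 100.0),
                "age_days": ages,
                "sex": ["A"] * n,
                "subject_id": subjects if subjects is not None
                else [f"s{i}" for i in range(n)],
            }
        )
    )


def _group(center, lo, hi, idx):
    return AgeGroup(center, lo, hi, lo, hi, np.asarray(idx))


class TestAssignment:
    def _setup(self):
        rng = np.random.default_rng(9)
        ages = np.concatenate([
            rng.integers(980, 1001, 300), rng.integers(1001, 1021, 300)
        ])
        values = rng.normal(100, 10, size=600).clip(1)
        ms = _toy_ms(ages, values=values)
        model = NPModel(lam=1.0, mu=100.0, sigma=0.1, np_fraction=0.95)
        groups = [
            _group(990, 980, 1000, np.where(ages <= 1000)[0]),
            _group(1000, 990, 1010, np.where((ages >= 990) & (ages <= 1010))[0]),
            _group(1010, 1000, 1020, np.where(ages >= 1000)[0]),
        ]
        models = {990: model, 1000: model, 1010: model}
        return ms, groups, models

    def test_nearest_center_wins(self):
        ms, groups, models = self._setup()
        p_raw, source = assign_single_weight(ms, groups, models)
        ages = ms.age_days
        assert np.all(source[ages == 1000] == 1000)
        assert np.all(source[ages == 992] == 990)

    def test_equidistant_tie_goes_to_younger_center(self):
        ms, groups, models = self._setup()
        _, source = assign_single_weight(ms, groups, models)
        ages = ms.age_days
        if np.any(ages == 995):
            assert np.all(source[ages == 995] == 990)
        assert np.all(source[ages == 1005] == 1000)

    def test_exactly_one_weight_per_measurement(self):
        ms, groups, models = self._setup()
        p_raw, source = assign_single_weight(ms, groups, models)
        assert len(p_raw) == len(ms) == len(source)
        assert np.all((p_raw >= 0) & (p_raw <= 1))

    def test_failed_group_falls_to_next_nearest(self):
        ms, groups, models = self._setup()
        models = dict(models)
        models[1000] = None
        _, source = assign_single_weight(ms, groups, models)
        assert set(np.unique(source)) <= {990, 1010}

    def test_no_fitted_model_is_fatal(self):
        ms, groups, _ = self._setup()
        with pytest.raises(rc.PipelineError):
            assign_single_weight(ms, groups, {990: None, 1000: None, 1010: None})


class TestSubjectCorrection:
    def test_division_by_whole_dataset_count(self):
        p, n_subj = subject_correction(
            np.array([0.9, 0.9, 0.9]), np.array(["a", "a", "a"])
        )
        np.testing.assert_allclose(p, [0.3, 0.3, 0.3])
        assert list(n_subj) == [3, 3, 3]

    def test_single_sample_subject_unchanged(self):
        p, _ = subject_correction(np.array([0.7]), np.array(["x"]))
        assert p[0] == pytest.approx(0.7)

    @settings(max_examples=30, deadline=None)
    @given(
        n=st.integers(2, 40),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_per_subject_sum_bounded_by_max_raw(self, n, seed):
        rng = np.random.default_rng(seed)
        p_raw = rng.uniform(0, 1, size=n)
        subjects = rng.integers(0, max(1, n // 3), size=n).astype(str)
        p_corr, _ = subject_correction(p_raw, subjects)
        assert np.all(p_corr <= p_raw + 1e-15)
        for s in np.unique(subjects):
            m = subjects == s
            assert p_corr[m].sum() <= p_raw[m].max() + 1e-12


def test_pathological_point_mass_gets_low_mean_weight():
    rng = np.random.default_rng(10)
    model = NPModel(lam=1.0, mu=100.0, sigma=0.1, np_fraction=0.9)
    clean = rng.normal(100, 10, size=1800).clip(1)
    path = rng.normal(250, 5, size=200)
    values = np.concatenate([clean, path])
    w = density_ratio_weights(values, model, at=path)
    assert w.mean() < 0.05
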
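"""Skellam mixture functional clustering."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from segn.clustering import em_cluster, select_module_count, skellam_logpmf
from segn.plasticity import PlasticitySeries


def skellam_logpmf_convolution(k, mu1, mu2, n_max=400):
    """Independent oracle: truncated Poisson-convolution sum."""
    n = np.arange(0, n_max)
    if k >= 0:
        terms = stats.poisson.pmf(n + k, mu1) * stats.poisson.pmf(n, mu2)
    else:
        terms = stats.poisson.pmf(n, mu1) * stats.poisson.pmf(n - k, mu2)
    return np.log(terms.sum())


class TestSkellamLogpmf:
    def test_zero_diff_unit_intensities(self):
        # e^-2 I_0(2) computed by the convolution oracle
        expected = skellam_logpmf_convolution(0, 1.0, 1.0)
        assert skellam_logpmf(0, 1.0, 1.0) == pytest.approx(expected, abs=1e-12)
        assert np.exp(expected) == pytest.approx(0.30851, abs=1e-5)

    @pytest.mark.parametrize("k,mu1,mu2", [(3, 2.0, 5.0), (-7, 0.5, 4.0), (0, 9.0, 0.3)])
    def test_matches_convolution_oracle(self, k, mu1, mu2):
        assert skellam_logpmf(k, mu1, mu2) == pytest.approx(
            skellam_logpmf_convolution(k, mu1, mu2), abs=1e-10
        )

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(-10, 11))
            a, b = rng.uniform(0.2, 8.0, 2)
            assert skellam_logpmf(k, a, b) == pytest.approx(
                skellam_logpmf(-k, b, a), rel=1e-12
            )

    def test_poisson_limit(self):
        for k in range(0, 8):
            assert skellam_logpmf(k, 3.0, 1e-10) == pytest.approx(
                stats.poisson.logpmf(k, 3.0), abs=1e-6
            )

    def test_normalization(self):
        k = np.arange(-200, 201)
        for mu1, mu2 in [(1.0, 1.0), (8.0, 12.0), (0.5, 15.0)]:
            total = np.exp(skellam_logpmf(k, mu1, mu2)).sum()
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            skellam_logpmf(0, 0.0, 1.0)


def make_module_data(rng, n_per, curves, times, lop_order=3):
    """Model-true Skellam series: intensities are softplus-LOP curves."""
    from segn.clustering import SkellamParams, _softplus_inv
    from segn.lop import AffineMap, legendre_basis

    domain = (float(times.min()), float(times.max()))
    B = legendre_basis(AffineMap(*domain)(times), lop_order)
    series, labels = [], []
    for l, mean_fn in enumerate(curves):
        mean = mean_fn(times)
        s = np.maximum(np.abs(mean) + 4.0, 6.0)
        b1, *_ = np.linalg.lstsq(B, _softplus_inv((s + mean) / 2), rcond=None)
        b2, *_ = np.linalg.lstsq(B, _softplus_inv((s - mean) / 2), rcond=None)
        mu1, mu2 = SkellamParams(b1, b2, domain).intensities(times)
        for j in range(n_per):
            vals = rng.poisson(mu1) - rng.poisson(mu2)
            series.append(
                PlasticitySeries(f"m{l}_g{j}", times, vals.astype(float))
            )
            labels.append(l)
    return series, np.array(labels)


TIMES = np.linspace(0.0, 8.0, 9)
CURVES3 = [
    lambda t: 12.0 - 3.0 * t,
    lambda t: -10.0 + 2.5 * t,
    lambda t: 10.0 * np.sin(t / 1.6),
]


class TestEmCluster:
    def test_single_module_weights(self):
        rng = np.random.default_rng(0)
        series, _ = make_module_data(rng, 20, CURVES3[:1], TIMES)
        part = em_cluster(series, 1, lop_order=3, seed=1)
        np.testing.assert_allclose(part.weights, [1.0])
        assert part.posterior.shape == (20, 1)

    def test_separated_modules_recovered(self):
        rng = np.random.default_rng(1)
        series, labels = make_module_data(rng, 30, CURVES3[:2], TIMES)
        part = em_cluster(series, 2, lop_order=3, seed=1)
        assert adjusted_rand_score(labels, part.labels) > 0.95

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        series, _ = make_module_data(rng, 15, CURVES3[:2], TIMES)
        part = em_cluster(series, 2, lop_order=3, seed=1)
        np.testing.assert_allclose(part.posterior.sum(axis=1), 1.0, atol=1e-10)
        assert part.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_duplication_leaves_mean_curves_unchanged(self):
        rng = np.random.default_rng(3)
        series, _ = make_module_data(rng, 25, CURVES3[:2], TIMES)
        part1 = em_cluster(series, 2, lop_order=3, seed=1)
        doubled = series + [
            PlasticitySeries(s.entity_id + "_dup", s.times, s.values) for s in series
        ]
        part2 = em_cluster(doubled, 2, lop_order=3, seed=1)
        c1 = sorted(part1.module_mean_curve(l, TIMES).mean() for l in range(2))
        c2 = sorted(part2.module_mean_curve(l, TIMES).mean() for l in range(2))
        np.testing.assert_allclose(c1, c2, atol=0.5)

    def test_too_few_genes_rejected(self):
        rng = np.random.default_rng(4)
        series, _ = make_module_data(rng, 1, CURVES3[:1], TIMES)
        with pytest.raises(ValueError):
            em_cluster(series, 3)

    def test_gaussian_emission(self):
        rng = np.random.default_rng(5)
        series, labels = make_module_data(rng, 25, CURVES3[:2], TIMES)
        part = em_cluster(series, 2, lop_order=3, emission="gaussian", seed=1)
        assert adjusted_rand_score(labels, part.labels) > 0.9


class TestSelectModuleCount:
    def test_aic_formula(self):
        rng = np.random.default_rng(6)
        series, _ = make_module_data(rng, 20, CURVES3[:1], TIMES)
        part = em_cluster(series, 1, lop_order=3, seed=1)
        expected = -2 * part.log_likelihood + 2 * (0 + 1 * 2 * 4)
        assert part.aic == pytest.approx(expected)

    def test_selects_three_modules(self):
        rng = np.random.default_rng(7)
        series, labels = make_module_data(rng, 30, CURVES3, TIMES)
        part = select_module_count(series, range(1, 6), lop_order=3, seed=1,
                                   n_restarts=2)
        assert part.n_modules == 3
        assert adjusted_rand_score(labels, part.labels) > 0.95

    def test_single_cluster_data_selects_one(self):
        rng = np.random.default_rng(8)
        series, _ = make_module_data(rng, 40, CURVES3[:1], TIMES)
        part = select_module_count(series, range(1, 4), lop_order=3, seed=1,
                                   n_restarts=2)
        assert part.n_modules == 1

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_module_count([], [])


def test_em_loglik_monotone():
    """Observed-data log-likelihood never decreases across EM iterations."""
    rng = np.random.default_rng(9)
    series, _ = make_module_data(rng, 20, CURVES3[:2], TIMES)
    part = em_cluster(series, 2, lop_order=3, seed=1, n_restarts=1)
    trace = np.array(part.loglik_trace)
    assert len(trace) >= 2
    assert np.all(np.diff(trace) >= -1e-9 * np.maximum(np.abs(trace[:-1]), 1.0))
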
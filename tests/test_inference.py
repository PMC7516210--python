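"""RK4 integration, regulator selection, ODE fitting, decomposition."""

import numpy as np
import pytest

from segn.inference import (
    decompose,
    fit_ode,
    integrate_rk4,
    select_regulators,
)
from segn.lop import LopCurve, fit_lop_curve
from segn.plasticity import PlasticitySeries


class TestIntegrateRk4:
    def test_constant_field(self):
        sol = integrate_rk4(lambda t, y: 0.0 * y, [2.0], np.linspace(0, 5, 6))
        np.testing.assert_allclose(sol[:, 0], 2.0)

    def test_exponential_growth(self):
        sol = integrate_rk4(lambda t, y: y, [1.0], [0.0, 1.0], h=0.01)
        assert sol[-1, 0] == pytest.approx(np.e, abs=1e-6)

    def test_fourth_order_convergence(self):
        """Halving the step reduces the error by about 2^4."""
        errors = []
        for h in (0.1, 0.05, 0.025):
            sol = integrate_rk4(lambda t, y: y, [1.0], [0.0, 1.0], h=h)
            errors.append(abs(sol[-1, 0] - np.e))
        assert errors[0] / errors[1] == pytest.approx(16, rel=0.2)
        assert errors[1] / errors[2] == pytest.approx(16, rel=0.2)

    def test_divergence_reported_with_time(self):
        with pytest.raises(FloatingPointError, match="t="):
            integrate_rk4(lambda t, y: y * np.inf, [1.0], [0.0, 1.0], h=0.5)

    def test_nonmonotone_grid_rejected(self):
        with pytest.raises(ValueError):
            integrate_rk4(lambda t, y: y, [1.0], [0.0, 1.0, 0.5])


def _series_from_curve(curve, times, entity="g"):
    return PlasticitySeries(entity, times, curve(times))


class TestSelectRegulators:
    def _noise_curves(self, rng, times, n, amp=1.0):
        out = {}
        for k in range(n):
            vals = amp * rng.standard_normal(len(times))
            out[f"noise{k}"] = fit_lop_curve(times, vals, 4)
        return out

    def test_dmax_zero_returns_empty(self):
        times = np.linspace(0, 10, 20)
        rng = np.random.default_rng(0)
        target = fit_lop_curve(times, np.sin(times), 6)
        cands = self._noise_curves(rng, times, 3)
        assert select_regulators(target, cands, d_max=0) == []

    def test_degenerate_target_empty_with_warning(self):
        times = np.linspace(0, 10, 20)
        rng = np.random.default_rng(1)
        target = fit_lop_curve(times, np.zeros(20), 3)
        cands = self._noise_curves(rng, times, 3)
        with pytest.warns(UserWarning, match="degenerate"):
            assert select_regulators(target, cands) == []

    def test_no_candidates_rejected(self):
        times = np.linspace(0, 10, 20)
        target = fit_lop_curve(times, np.sin(times), 6)
        with pytest.raises(ValueError):
            select_regulators(target, {})

    def test_true_driver_recovered(self):
        """A target driven by one oscillatory candidate selects that candidate."""
        rng = np.random.default_rng(2)
        times = np.linspace(0, 12, 30)
        hits = 0
        n_trials = 20
        for trial in range(n_trials):
            driver_vals = 8 * np.exp(-0.1 * times) * np.sin(
                rng.uniform(0.6, 1.4) * times + rng.uniform(0, 6)
            )
            driver = fit_lop_curve(times, driver_vals, 10)
            g = integrate_rk4(
                lambda t, y: -0.4 * y + 0.9 * driver(t, extrapolate=True) + 2.0,
                [rng.uniform(-5, 5)], times, h=0.02,
            )[:, 0]
            noise = rng.normal(0, 0.1, len(times))
            series = PlasticitySeries("tgt", times, g + noise)
            target = fit_lop_curve(times, series.values, 10)
            cands = {"driver": driver}
            for k in range(5):
                vals = 8 * np.exp(-0.1 * times) * np.sin(
                    rng.uniform(0.6, 1.4) * times + rng.uniform(0, 6)
                ) + rng.normal(0, 0.1, len(times))
                cands[f"decoy{k}"] = fit_lop_curve(times, vals, 10)
            sel = select_regulators(target, cands, target_series=series)
            hits += sel[:1] == ["driver"]
        assert hits / n_trials > 0.9

    def test_pure_noise_sparsity(self):
        """An isolated gene with noise-only candidates selects (almost) none."""
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            times = np.linspace(0, 10, 25)
            # self-consistent isolated kinetics: relaxation toward an asymptote
            vals = 6.0 - 9.0 * np.exp(-0.4 * times) + rng.normal(0, 0.1, 25)
            series = PlasticitySeries("t", times, vals)
            target = fit_lop_curve(times, vals, 8)
            cands = self._noise_curves(rng, times, 8, amp=3.0)
            counts.append(len(select_regulators(target, cands, target_series=series)))
        assert np.median(counts) <= 1


def _two_gene_system(times, g0=(5.0, -4.0)):
    """Underdamped mutual pair: the split is identifiable because the
    target revisits expression values with different derivatives."""

    def field(t, g):
        return np.array([
            1.0 - 0.2 * g[0] + 0.9 * g[1],
            -0.5 - 0.2 * g[1] - 0.9 * g[0],
        ])

    return integrate_rk4(field, list(g0), times, h=0.005)


class TestFitOdeAndDecompose:
    times = np.linspace(0.0, 12.0, 30)

    def _fit_pair(self, refine=False):
        traj = _two_gene_system(self.times)
        s1 = PlasticitySeries("g1", self.times, traj[:, 0])
        s2 = PlasticitySeries("g2", self.times, traj[:, 1])
        c1 = fit_lop_curve(self.times, s1.values, 10)
        c2 = fit_lop_curve(self.times, s2.values, 10)
        fit = fit_ode(s1, c1, {"g2": c2}, comp_order=2, refine=refine, n_starts=2)
        return fit, traj

    def test_noiseless_fit_small_sse(self):
        fit, _ = self._fit_pair()
        assert fit.sse < 1e-3

    def test_component_recovery_within_five_percent(self):
        """Fitted P_12 matches the generating dependent integral."""
        fit, traj = self._fit_pair()
        dec = decompose(fit, n_grid=241)
        # generating dependent contribution: integral of 0.9 * g2(s)
        fine = np.linspace(0, 12, 241)
        traj_fine = _two_gene_system(fine)
        true_p12 = np.concatenate(
            [[0.0], np.cumsum(
                0.9 * (traj_fine[1:, 1] + traj_fine[:-1, 1]) / 2 * np.diff(fine)
            )]
        )
        signal_range = np.ptp(true_p12)
        err = np.abs(dec.p_dependent["g2"] - true_p12).max()
        assert err < 0.05 * signal_range

    def test_decomposition_additivity(self):
        fit, _ = self._fit_pair()
        dec = decompose(fit)
        assert dec.additivity_gap() < 1e-6

    def test_dependent_components_start_at_zero(self):
        fit, _ = self._fit_pair()
        dec = decompose(fit)
        assert dec.p_dependent["g2"][0] == 0.0
        assert dec.p_independent[0] == pytest.approx(fit.g0)

    def test_no_regulators_gives_pure_independent(self):
        vals = 5 * np.exp(-0.3 * self.times)
        s = PlasticitySeries("g", self.times, vals)
        c = fit_lop_curve(self.times, vals, 6)
        fit = fit_ode(s, c, {}, comp_order=2, refine=False)
        dec = decompose(fit)
        np.testing.assert_allclose(dec.p_independent, dec.g_hat, atol=1e-9)

    def test_fitted_derivative_identity(self):
        """dg/dt of the integrated solution equals the sum of components."""
        fit, _ = self._fit_pair()
        dec = decompose(fit, n_grid=201)
        mid = 100
        t = dec.times[mid]
        lhs = np.gradient(dec.g_hat, dec.times)[mid]
        rhs = fit.derivative_at(t, dec.g_hat[mid])
        assert lhs == pytest.approx(rhs, rel=0.01)

    def test_scale_equivariance(self):
        """Scaling all series by c scales the decomposition by c."""
        traj = _two_gene_system(self.times)
        for scale in (1.0, 3.0):
            s1 = PlasticitySeries("g1", self.times, scale * traj[:, 0])
            c1 = fit_lop_curve(self.times, s1.values, 10)
            c2 = fit_lop_curve(self.times, scale * traj[:, 1], 10)
            fit = fit_ode(s1, c1, {"g2": c2}, comp_order=2, refine=False)
            dec = decompose(fit, n_grid=61)
            if scale == 1.0:
                base = dec
            else:
                np.testing.assert_allclose(
                    dec.p_dependent["g2"], scale * base.p_dependent["g2"],
                    rtol=0.02, atol=0.02 * scale,
                )
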
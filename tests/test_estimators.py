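"""Estimator suite: Wald ratios, IVW (correlated/independent), Egger, Q, LOO, RAPS."""

import numpy as np
import pytest

from mrkit.estimators import (
    EstimationError,
    heterogeneity,
    ivw_correlated,
    ivw_independent,
    leave_one_out,
    mr_egger,
    raps,
    wald_ratio,
)

from conftest import make_dataset


class TestWaldRatio:
    def test_null_numerator(self):
        est = wald_ratio(0.5, 0.02, 0.0, 0.1)
        assert est.beta == 0.0
        assert est.se == pytest.approx(0.1 / 0.5)
        assert est.odds_ratio == 1.0

    def test_identity_instrument(self):
        est = wald_ratio(1.0, 0.0, 0.3, 0.05)
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.05)

    def test_delta_method_orders(self):
        bx, sx, by, sy = 0.5, 0.05, 0.2, 0.1
        first = wald_ratio(bx, sx, by, sy)
        second = wald_ratio(bx, sx, by, sy, second_order=True)
        # formulas evaluated independently
        assert first.se == pytest.approx(sy / abs(bx), rel=1e-12)
        assert second.se == pytest.approx(
            np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4), rel=1e-12
        )
        assert second.se > first.se

    def test_zero_denominator_rejected(self):
        with pytest.raises(EstimationError):
            wald_ratio(0.0, 0.01, 0.1, 0.05)

    def test_or_ci_is_exponentiated_beta_ci(self):
        est = wald_ratio(0.4, 0.03, 0.12, 0.06)
        assert est.odds_ratio == pytest.approx(np.exp(est.beta), rel=1e-15)
        assert est.or_ci_low == pytest.approx(np.exp(est.ci_low), rel=1e-15)
        assert est.or_ci_high == pytest.approx(np.exp(est.ci_high), rel=1e-15)


class TestIvwCorrelated:
    def test_single_snp_reduces_to_wald(self):
        data = make_dataset([0.12], [0.02], [0.05], [0.015])
        pooled = ivw_correlated(data)
        wald = wald_ratio(0.12, 0.02, 0.05, 0.015)
        assert pooled.beta == pytest.approx(wald.beta, rel=1e-12)
        assert pooled.se == pytest.approx(wald.se, rel=1e-12)

    def test_identity_ld_equals_independent_fixed(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            k = rng.integers(2, 8)
            data = make_dataset(
                rng.uniform(0.05, 0.2, k),
                rng.uniform(0.005, 0.02, k),
                rng.normal(0, 0.05, k),
                rng.uniform(0.01, 0.05, k),
            )
            corr = ivw_correlated(data)
            indep = ivw_independent(data, model="fixed")
            assert corr.beta == pytest.approx(indep.beta, abs=1e-10)
            assert corr.se == pytest.approx(indep.se, abs=1e-10)

    def test_three_snp_hand_matrix_oracle(self):
        bx = np.array([0.10, 0.12, 0.09])
        by = np.array([0.03, 0.05, 0.02])
        sy = np.array([0.010, 0.015, 0.012])
        r = np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1.0]])
        data = make_dataset(bx, np.zeros(3), by, sy, ld_r=r)

        # independent route: cofactor inversion of the 3x3 covariance
        omega = np.outer(sy, sy) * r
        det = (
            omega[0, 0] * (omega[1, 1] * omega[2, 2] - omega[1, 2] * omega[2, 1])
            - omega[0, 1] * (omega[1, 0] * omega[2, 2] - omega[1, 2] * omega[2, 0])
            + omega[0, 2] * (omega[1, 0] * omega[2, 1] - omega[1, 1] * omega[2, 0])
        )
        cof = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                minor = np.delete(np.delete(omega, i, axis=0), j, axis=1)
                cof[i, j] = (-1) ** (i + j) * (
                    minor[0, 0] * minor[1, 1] - minor[0, 1] * minor[1, 0]
                )
        omega_inv = cof.T / det
        denom = bx @ omega_inv @ bx
        expected_beta = (bx @ omega_inv @ by) / denom
        expected_se = np.sqrt(1.0 / denom)

        est = ivw_correlated(data)
        assert est.beta == pytest.approx(expected_beta, rel=1e-10)
        assert est.se == pytest.approx(expected_se, rel=1e-10)


class TestIvwIndependent:
    def test_replicated_instrument(self):
        k = 4
        data = make_dataset([0.1] * k, [0.0] * k, [0.04] * k, [0.02] * k)
        est = ivw_independent(data)
        assert est.beta == pytest.approx(0.4, rel=1e-12)
        assert est.se == pytest.approx((0.02 / 0.1) / np.sqrt(k), rel=1e-12)

    def test_no_overdispersion_keeps_fixed_se(self):
        # perfectly proportional: Q = 0 <= K-1
        bx = np.array([0.1, 0.2, 0.15])
        data = make_dataset(bx, np.zeros(3), 0.3 * bx, [0.02, 0.03, 0.025])
        fixed = ivw_independent(data, "fixed")
        re = ivw_independent(data, "multiplicative_random")
        assert re.se == pytest.approx(fixed.se, rel=1e-12)
        assert re.beta == pytest.approx(fixed.beta, rel=1e-12)

    def test_equals_weighted_mean_of_ratios(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            k = rng.integers(2, 12)
            bx = rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k)
            by = rng.normal(0, 0.1, k)
            sy = rng.uniform(0.01, 0.08, k)
            data = make_dataset(bx, np.zeros(k), by, sy)
            w = bx**2 / sy**2
            expected = np.sum(w * (by / bx)) / np.sum(w)
            assert ivw_independent(data).beta == pytest.approx(expected, abs=1e-10)

    def test_random_effects_needs_two_snps(self):
        data = make_dataset([0.1], [0.0], [0.03], [0.02])
        with pytest.raises(EstimationError):
            ivw_independent(data, "multiplicative_random")


class TestEgger:
    def test_noiseless_line_recovery(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        a, slope = 0.01, 0.3
        data = make_dataset(bx, np.zeros(4), a + slope * bx, [1e-6] * 4)
        result = mr_egger(data)
        assert result.intercept == pytest.approx(a, abs=1e-9)
        assert result.slope.beta == pytest.approx(slope, abs=1e-7)

    def test_four_point_normal_equations_oracle(self):
        bx = np.array([0.05, 0.12, 0.08, 0.2])
        by = np.array([0.02, 0.06, 0.01, 0.07])
        sy = np.array([0.01, 0.02, 0.015, 0.03])
        w = 1.0 / sy**2
        sw, sx_ = w.sum(), (w * bx).sum()
        sxx, sy_, sxy = (w * bx * bx).sum(), (w * by).sum(), (w * bx * by).sum()
        slope = (sw * sxy - sx_ * sy_) / (sw * sxx - sx_**2)
        intercept = (sy_ - slope * sx_) / sw
        result = mr_egger(make_dataset(bx, np.zeros(4), by, sy))
        assert result.slope.beta == pytest.approx(slope, rel=1e-10)
        assert result.intercept == pytest.approx(intercept, rel=1e-10)

    def test_orientation_invariance(self):
        bx = np.array([0.05, -0.12, 0.08, 0.2])
        by = np.array([0.02, 0.06, 0.01, 0.07])
        sy = np.array([0.01, 0.02, 0.015, 0.03])
        base = mr_egger(make_dataset(bx, np.zeros(4), by, sy))
        flip = np.array([1, -1, 1, -1.0])
        other = mr_egger(make_dataset(bx * flip, np.zeros(4), by * flip, sy))
        assert other.slope.beta == pytest.approx(base.slope.beta, rel=1e-12)
        assert other.intercept == pytest.approx(base.intercept, rel=1e-12)
        assert other.intercept_se == pytest.approx(base.intercept_se, rel=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(EstimationError):
            mr_egger(make_dataset([0.1, 0.2], [0, 0], [0.03, 0.05], [0.01, 0.01]))


class TestHeterogeneity:
    def test_proportional_data_gives_zero_q(self):
        bx = np.array([0.1, 0.2, 0.15])
        data = make_dataset(bx, np.zeros(3), 0.25 * bx, [0.02, 0.03, 0.025])
        het = heterogeneity(data, ivw_independent(data))
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.i_squared == 0.0
        assert het.df == 2

    def test_two_term_hand_sum(self):
        data = make_dataset([0.1, 0.2], [0, 0], [0.05, 0.04], [0.02, 0.01])
        pooled = ivw_independent(data)
        expected = ((0.05 - pooled.beta * 0.1) / 0.02) ** 2 + (
            (0.04 - pooled.beta * 0.2) / 0.01
        ) ** 2
        het = heterogeneity(data, pooled)
        assert het.q == pytest.approx(expected, rel=1e-12)
        assert het.i_squared == pytest.approx(max(0.0, (het.q - 1) / het.q))


class TestLeaveOneOut:
    def test_pairwise_reduction_to_wald(self):
        data = make_dataset([0.1, 0.2], [0.01, 0.02], [0.05, 0.04], [0.02, 0.01])
        loo = dict(leave_one_out(data))
        assert loo["rs1"].beta == pytest.approx(wald_ratio(0.2, 0.02, 0.04, 0.01).beta)
        assert loo["rs2"].beta == pytest.approx(wald_ratio(0.1, 0.01, 0.05, 0.02).beta)

    def test_identical_instruments_are_exchangeable(self):
        data = make_dataset([0.1] * 4, [0.0] * 4, [0.04] * 4, [0.02] * 4)
        full = ivw_independent(data)
        for _, est in leave_one_out(data):
            assert est.beta == pytest.approx(full.beta, rel=1e-12)

    def test_matches_explicit_subsets(self):
        rng = np.random.default_rng(21)
        k = 5
        r = np.full((k, k), 0.3)
        np.fill_diagonal(r, 1.0)
        data = make_dataset(
            rng.uniform(0.05, 0.2, k),
            rng.uniform(0.005, 0.02, k),
            rng.normal(0, 0.05, k),
            rng.uniform(0.01, 0.05, k),
            ld_r=r,
        )
        for i, (snp, est) in enumerate(leave_one_out(data)):
            sub = data.subset([j for j in range(k) if j != i])
            direct = ivw_correlated(sub)
            assert snp == data.snp_ids[i]
            assert est.beta == pytest.approx(direct.beta, rel=1e-12)
            assert est.se == pytest.approx(direct.se, rel=1e-12)


def _raps_objective(data, beta, tau2=0.0, with_log=False):
    v = data.se_outcome**2 + beta**2 * data.se_exposure**2 + tau2
    resid = data.beta_outcome - beta * data.beta_exposure
    out = 0.5 * np.sum(resid**2 / v)
    if with_log:
        out += 0.5 * np.sum(np.log(v))
    return out


def _toy_raps_data(seed=17, k=10, beta=0.3):
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.05, 0.25, k)
    sx = np.full(k, 0.02)
    sy = np.full(k, 0.03)
    bx = gamma + sx * rng.standard_normal(k)
    by = beta * gamma + sy * rng.standard_normal(k)
    return make_dataset(bx, sx, by, sy)


class TestRaps:
    def test_no_exposure_noise_equals_fixed_ivw(self):
        data = make_dataset(
            [0.1, 0.2, 0.15, 0.12], np.zeros(4), [0.05, 0.04, 0.06, 0.03],
            [0.02, 0.01, 0.03, 0.015],
        )
        est = raps(data)
        ivw = ivw_independent(data)
        assert est.beta == pytest.approx(ivw.beta, abs=1e-7)
        assert est.se == pytest.approx(ivw.se, rel=1e-4)

    def test_matches_dense_grid_search(self):
        data = _toy_raps_data()
        est = raps(data)
        grid = np.arange(est.beta - 0.3, est.beta + 0.3, 5e-4)
        values = [_raps_objective(data, b) for b in grid]
        best = grid[int(np.argmin(values))]
        assert abs(est.beta - best) <= 5e-4
        assert _raps_objective(data, est.beta) <= min(values) + 1e-12

    def test_overdispersed_matches_coarse_grid(self):
        rng = np.random.default_rng(4)
        k = 12
        gamma = rng.uniform(0.1, 0.3, k)
        sx, sy = np.full(k, 0.01), np.full(k, 0.02)
        alpha = 0.03 * rng.standard_normal(k)  # genuine overdispersion
        bx = gamma + sx * rng.standard_normal(k)
        by = 0.2 * gamma + alpha + sy * rng.standard_normal(k)
        data = make_dataset(bx, sx, by, sy)
        est = raps(data, overdispersion=True)
        betas = np.arange(est.beta - 0.2, est.beta + 0.2, 2e-3)
        tau2s = np.concatenate([[0.0], np.geomspace(1e-6, 1e-2, 40)])
        grid_min = min(
            _raps_objective(data, b, t, with_log=True) for b in betas for t in tau2s
        )
        fitted = _raps_objective(data, est.beta, _raps_tau2(data, est.beta), with_log=True)
        # the optimizer's objective value must beat every grid point
        assert fitted <= grid_min + 1e-6

    def test_parameter_recovery_under_model(self):
        # summary-level simulation exactly under the RAPS data model
        rng = np.random.default_rng(42)
        true_beta, k, reps = 0.3, 20, 500
        gamma = rng.uniform(0.05, 0.2, k)
        sx, sy = np.full(k, 0.015), np.full(k, 0.02)
        estimates = []
        for _ in range(reps):
            bx = gamma + sx * rng.standard_normal(k)
            by = true_beta * gamma + sy * rng.standard_normal(k)
            estimates.append(raps(make_dataset(bx, sx, by, sy)).beta)
        estimates = np.asarray(estimates)
        mc_se = estimates.std() / np.sqrt(reps)
        assert abs(estimates.mean() - true_beta) < 4 * mc_se

    def test_requires_three_instruments(self):
        with pytest.raises(EstimationError):
            raps(make_dataset([0.1, 0.2], [0.01, 0.01], [0.03, 0.05], [0.02, 0.02]))


def _raps_tau2(data, beta):
    """Profile tau2 at fixed beta by scalar search (test helper)."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda lt: _raps_objective(data, beta, np.exp(lt), with_log=True),
        bounds=(-30, 2),
        method="bounded",
    )
    return float(np.exp(res.x))


class TestScaleEquivariance:
    def test_pooled_beta_scales_inversely_with_exposure_units(self):
        rng = np.random.default_rng(9)
        k, c = 6, 3.7
        bx = rng.uniform(0.05, 0.3, k)
        sx = rng.uniform(0.005, 0.02, k)
        by = rng.normal(0, 0.05, k)
        sy = rng.uniform(0.01, 0.05, k)
        r = np.full((k, k), 0.2)
        np.fill_diagonal(r, 1.0)
        base = make_dataset(bx, sx, by, sy, ld_r=r)
        scaled = make_dataset(c * bx, c * sx, by, sy, ld_r=r)
        assert ivw_correlated(scaled).beta == pytest.approx(
            ivw_correlated(base).beta / c, rel=1e-10
        )
        assert ivw_independent(scaled).beta == pytest.approx(
            ivw_independent(base).beta / c, rel=1e-10
        )
        assert mr_egger(scaled).slope.beta == pytest.approx(
            mr_egger(base).slope.beta / c, rel=1e-10
        )
        assert raps(scaled).beta == pytest.approx(raps(base).beta / c, rel=1e-5)
        assert wald_ratio(c * bx[0], c * sx[0], by[0], sy[0]).beta == pytest.approx(
            wald_ratio(bx[0], sx[0], by[0], sy[0]).beta / c, rel=1e-12
        )
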
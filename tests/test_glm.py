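"""Run-level prewhitened GLM, smoothing, fixed effects and group inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scoutlite.design import DesignMatrix
from scoutlite.glm import (
    contrast_map,
    estimate_ar1,
    fit_run,
    fixed_effects,
    group_onesample,
    smooth_map,
    t_to_z,
)
from scoutlite.stimio import BoldRun, StatMap, ValidationError


def make_dm(x: np.ndarray, names=None) -> DesignMatrix:
    names = names or [f"c{i}" for i in range(x.shape[1] - 1)] + ["intercept"]
    roles = {n: "predictor" for n in names}
    roles[names[-1]] = "intercept"
    return DesignMatrix(frame=pd.DataFrame(x, columns=names), tr=2.0, column_roles=roles)


def make_bold(y: np.ndarray, grid=(5, 1, 1)) -> BoldRun:
    """y: (n_voxels, n_time) -> BoldRun on a tiny grid."""
    n_vox, n_t = y.shape
    data = np.zeros(grid + (n_t,))
    data.reshape(-1, n_t)[:n_vox] = y
    mask = np.zeros(grid, dtype=bool)
    mask.reshape(-1)[:n_vox] = True
    return BoldRun(
        data=data, tr=2.0, mask=mask,
        confounds=pd.DataFrame(index=range(n_t)), affine=np.eye(4),
    )


class TestEstimateAR1:
    def test_white_noise_near_zero(self, rng):
        resid = rng.standard_normal((5000, 4))
        assert abs(estimate_ar1(resid)) < 0.05

    def test_ar1_recovery(self, rng):
        phi, n = 0.5, 5000
        x = np.zeros((n, 3))
        innov = rng.standard_normal((n, 3))
        for t in range(1, n):
            x[t] = phi * x[t - 1] + innov[t]
        assert 0.45 <= estimate_ar1(x) <= 0.55

    def test_alternating_clipped(self):
        resid = np.tile([[1.0], [-1.0]], (10, 1))
        assert estimate_ar1(resid) == pytest.approx(-0.99)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            estimate_ar1(np.ones((2, 3)))


class TestFitRun:
    def test_noise_free_exact_recovery(self, rng):
        n, k = 30, 3
        x = np.column_stack([rng.standard_normal((n, k - 1)), np.ones(n)])
        beta_true = np.array([1.5, -2.0, 0.7])
        y = (x @ beta_true)[None, :].repeat(4, axis=0)
        fit = fit_run(make_bold(y, grid=(4, 1, 1)), make_dm(x), noise="ols")
        for j, name in enumerate(["c0", "c1", "intercept"]):
            got = fit.betas[name].effect[fit.betas[name].mask]
            assert np.allclose(got, beta_true[j], atol=1e-10)

    def test_ols_equals_closed_form(self, rng):
        # 20 time points, 5 voxels vs the normal-equations oracle
        n = 20
        x = np.column_stack([rng.standard_normal((n, 2)), np.ones(n)])
        y = rng.standard_normal((5, n))
        fit = fit_run(make_bold(y), make_dm(x), noise="ols")
        oracle = np.linalg.inv(x.T @ x) @ x.T @ y.T
        for j, name in enumerate(["c0", "c1", "intercept"]):
            got = fit.betas[name].effect[fit.betas[name].mask]
            assert np.allclose(got, oracle[j], atol=1e-10)
        assert fit.dof == n - 3

    def test_ar1_simulation_recovery(self, rng):
        # AR(1) noise phi=0.4, beta=0.5: mean estimate within 3 SEM
        n, n_vox, phi, beta = 200, 500, 0.4, 0.5
        pred = (np.arange(n) % 10 < 5).astype(float)
        x = np.column_stack([pred, np.ones(n)])
        noise = np.zeros((n_vox, n))
        innov = rng.normal(0, 1, (n_vox, n))
        noise[:, 0] = rng.normal(0, 1 / np.sqrt(1 - phi**2), n_vox)
        for t in range(1, n):
            noise[:, t] = phi * noise[:, t - 1] + innov[:, t]
        y = beta * pred[None, :] + noise
        fit = fit_run(make_bold(y, grid=(n_vox, 1, 1)), make_dm(x), noise="ar1")
        est = fit.betas["c0"].effect[fit.betas["c0"].mask]
        sem = est.std() / np.sqrt(n_vox)
        assert abs(est.mean() - beta) < 3 * sem
        assert 0.25 <= fit.noise.rho <= 0.55

    def test_rank_deficient_rejected(self, rng):
        n = 20
        c = rng.standard_normal(n)
        x = np.column_stack([c, 2 * c, np.ones(n)])
        with pytest.raises(ValidationError):
            fit_run(make_bold(rng.standard_normal((3, n))), make_dm(x))

    def test_contrast_matches_single_column(self, rng):
        n = 40
        x = np.column_stack([rng.standard_normal((n, 2)), np.ones(n)])
        fit = fit_run(make_bold(rng.standard_normal((4, n))), make_dm(x), noise="ols")
        cm = contrast_map(fit, ["c0"], [1.0])
        assert np.allclose(cm.effect, fit.betas["c0"].effect)
        assert np.allclose(cm.variance, fit.betas["c0"].variance)


class TestSmoothing:
    def _map(self, values, mask=None):
        mask = np.ones(values.shape, dtype=bool) if mask is None else mask
        return StatMap(
            effect=values, variance=np.abs(values), dof=10.0, kind="beta",
            affine=np.diag([2.0, 2.0, 2.0, 1.0]), mask=mask,
        )

    def test_constant_map_unchanged(self):
        m = self._map(np.full((6, 6, 6), 3.5))
        sm = smooth_map(m, fwhm_mm=4.0)
        assert np.allclose(sm.effect[sm.mask], 3.5, atol=1e-10)

    def test_zero_fwhm_identity(self, rng):
        m = self._map(rng.standard_normal((5, 5, 5)))
        sm = smooth_map(m, fwhm_mm=0.0)
        assert np.array_equal(sm.effect, m.effect)

    def test_sigma_conversion(self):
        from scoutlite.glm import FWHM_TO_SIGMA

        assert 4.0 * FWHM_TO_SIGMA == pytest.approx(1.69864, abs=1e-4)

    def test_mass_stays_in_mask_and_max_bounded(self, rng):
        vals = rng.standard_normal((8, 8, 8))
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        m = self._map(np.where(mask, vals, 0.0), mask)
        sm = smooth_map(m, fwhm_mm=6.0)
        assert np.all(sm.effect[~mask] == 0.0)
        assert np.abs(sm.effect).max() <= np.abs(m.effect[mask]).max() + 1e-12

    def test_negative_fwhm_rejected(self, rng):
        with pytest.raises(ValidationError):
            smooth_map(self._map(np.zeros((3, 3, 3))), fwhm_mm=-1.0)


class TestFixedEffects:
    def _map(self, value, variance, shape=(2, 2, 2)):
        return StatMap(
            effect=np.full(shape, value), variance=np.full(shape, variance),
            dof=10.0, kind="beta", affine=np.eye(4), mask=np.ones(shape, dtype=bool),
        )

    def test_closed_form_weights(self):
        combined = fixed_effects([self._map(1.0, 1.0), self._map(3.0, 1.0)])
        assert np.allclose(combined.effect[combined.mask], 2.0)
        assert np.allclose(combined.variance[combined.mask], 0.5)

    def test_single_input_unchanged(self):
        m = self._map(1.7, 0.3)
        combined = fixed_effects([m])
        assert np.allclose(combined.effect, m.effect)
        assert np.allclose(combined.variance, m.variance)

    def test_k_identical_inputs(self):
        k = 4
        combined = fixed_effects([self._map(2.0, 0.8)] * k)
        assert np.allclose(combined.effect[combined.mask], 2.0)
        assert np.allclose(combined.variance[combined.mask], 0.8 / k)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            fixed_effects([self._map(1.0, 0.0)])


class TestGroup:
    def _map(self, values):
        values = np.asarray(values, dtype=float).reshape(1, 1, 1)
        return StatMap(
            effect=values, variance=np.full_like(values, 0.1), dof=10.0,
            kind="beta", affine=np.eye(4), mask=np.ones_like(values, dtype=bool),
        )

    def test_symmetric_values_zero(self):
        gr = group_onesample([self._map(-1.3), self._map(1.3)])
        assert gr.z.effect[0, 0, 0] == pytest.approx(0.0)

    def test_hand_computation(self):
        gr = group_onesample([self._map(v) for v in (1.0, 2.0, 3.0)])
        assert gr.effect.effect[0, 0, 0] == pytest.approx(2.0)
        assert gr.effect.variance[0, 0, 0] == pytest.approx(1.0 / 3.0)
        assert gr.dof == 2
        # t = 2 / (1/sqrt(3)) = 3.4641 -> z via the quantile-transform oracle
        t = 3.4641016
        z_oracle = stats.norm.isf(stats.t.sf(t, 2))
        assert gr.z.effect[0, 0, 0] == pytest.approx(z_oracle, abs=1e-6)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValidationError):
            group_onesample([self._map(1.0)])

    def test_group_null_calibration(self, rng):
        # quantile transform preserves two-sided p: fraction |z|>3.29 ~ 0.001
        shape = (40, 40, 32)
        maps = [
            StatMap(
                effect=rng.standard_normal(shape), variance=np.ones(shape),
                dof=10.0, kind="beta", affine=np.eye(4), mask=np.ones(shape, dtype=bool),
            )
            for _ in range(5)
        ]
        gr = group_onesample(maps)
        frac = np.mean(np.abs(gr.z.effect) >= 3.29)
        n = np.prod(shape)
        tol = 3 * np.sqrt(0.001 * 0.999 / n)
        assert abs(frac - 0.001) < tol


class TestTtoZ:
    def test_zero_maps_to_zero(self):
        assert t_to_z(0.0, 5) == 0.0

    def test_antisymmetry(self):
        assert t_to_z(-2.5, 7) == pytest.approx(-t_to_z(2.5, 7))

    def test_large_df_limit(self):
        assert t_to_z(1.96, 1e7) == pytest.approx(1.96, abs=1e-3)

    def test_matches_high_precision_oracle(self):
        for t, df in [(3.4641, 2), (1.0, 5), (6.0, 30)]:
            expected = stats.norm.isf(stats.t.sf(t, df))
            assert t_to_z(t, df) == pytest.approx(expected, abs=1e-8)

    def test_extreme_t_finite(self):
        z = t_to_z(50.0, 100)
        assert np.isfinite(z) and z > 8

    def test_invalid_df_rejected(self):
        with pytest.raises(ValidationError):
            t_to_z(1.0, 0)
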
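"""HRF, convolution, drift basis, transforms and design assembly."""

import numpy as np
import pandas as pd
import pytest

from scoutlite.design import (
    DesignMatrix,
    HRFParams,
    build_design,
    canonical_hrf,
    convolve_to_tr,
    correlation_report,
    cosine_drift,
    demean_rescale,
    dispersion_derivative,
    orthogonalize,
    threshold,
)
from scoutlite.stimio import FeatureStream, ModelSpec, Transformation, ValidationError


class TestTransforms:
    def test_demean_rescale_hand_values(self):
        out = demean_rescale([1.0, 2.0, 3.0])
        assert np.allclose(out, [-1.2247448, 0.0, 1.2247448], atol=1e-6)
        assert out.mean() == pytest.approx(0.0)
        assert out.std() == pytest.approx(1.0)

    def test_already_standardized_unchanged(self, rng):
        x = demean_rescale(rng.standard_normal(50))
        assert np.allclose(demean_rescale(x), x)

    def test_constant_rejected(self):
        with pytest.raises(ValidationError):
            demean_rescale(np.ones(10))

    @pytest.mark.parametrize(
        "x,cutoff,binarize,expected",
        [
            ([0.2, 0.7], 0.5, True, [0.0, 1.0]),
            ([0.2, 0.7], -np.inf, False, [0.2, 0.7]),
            ([0.1, 0.2], 0.5, False, [0.0, 0.0]),
        ],
    )
    def test_threshold(self, x, cutoff, binarize, expected):
        assert np.allclose(threshold(np.array(x), cutoff, binarize), expected)

    def test_orthogonalize_against_normal_equations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 1.0, 2.0, 2.0])
        out = orthogonalize(x, [y])
        # oracle: residual from explicit normal equations with intercept
        basis = np.column_stack([np.ones(4), y])
        coef = np.linalg.solve(basis.T @ basis, basis.T @ x)
        assert np.allclose(out, x - basis @ coef, atol=1e-12)
        assert abs(out @ y) < 1e-8 * np.linalg.norm(x) * np.linalg.norm(y)

    def test_orthogonalize_preserves_orthogonal_input(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert np.allclose(orthogonalize(x, [y]), x)

    def test_orthogonalize_spanning_input_is_zeroed(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(orthogonalize(2 * y + 1, [y]), 0.0, atol=1e-10)

    def test_rank_deficient_basis_rejected(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValidationError):
            orthogonalize(y, [y, 2 * y])


class TestHRF:
    def test_zero_at_origin_and_truncation(self):
        p = HRFParams()
        t = np.array([0.0, 33.0, 100.0])
        h = canonical_hrf(t, p)
        assert h[0] == 0.0
        assert np.all(h[1:] == 0.0)

    def test_peak_location_and_height(self):
        t = np.linspace(0, 32, 6401)
        h = canonical_hrf(t)
        t_peak = t[np.argmax(h)]
        assert 4.0 <= t_peak <= 6.0
        assert h.max() == pytest.approx(1.0, abs=1e-3)

    def test_dispersion_derivative_zero_for_identical_dispersions(self):
        p = HRFParams()
        t = np.linspace(0, 32, 100)
        h0 = canonical_hrf(t, p)
        # delta -> derivative is a difference of nearby HRFs; with the peak
        # flat in dispersion this is ~0 only where the HRF itself vanishes
        d = dispersion_derivative(t, p)
        assert d[0] == 0.0 and np.isfinite(d).all()

    def test_dispersion_derivative_sign_flip_near_peak(self):
        t = np.linspace(0, 16, 801)
        d = dispersion_derivative(t)
        peak_region = (t > 2) & (t < 10)
        assert d[peak_region].min() < 0 < d[peak_region].max()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            HRFParams(peak_delay=-1.0)
        with pytest.raises(ValidationError):
            HRFParams(length=10.0)  # shorter than undershoot delay


class TestConvolve:
    def test_zero_stream_zero_columns(self):
        s = FeatureStream(name="x", kind="sparse", onsets=[1.0], durations=[1.0], values=[0.0])
        c, d = convolve_to_tr(s, tr=2.0, n_volumes=20)
        assert np.allclose(c, 0) and np.allclose(d, 0)

    def test_linearity(self, rng):
        onsets = np.sort(rng.uniform(0, 50, 8))
        onsets += np.arange(8) * 1e-3  # enforce strict ordering
        dur = rng.uniform(0.5, 2.0, 8)
        va, vb = rng.standard_normal(8), rng.standard_normal(8)
        mk = lambda v: FeatureStream(name="x", kind="sparse", onsets=onsets, durations=dur, values=v)
        ca, _ = convolve_to_tr(mk(va), tr=2.0, n_volumes=40)
        cb, _ = convolve_to_tr(mk(vb), tr=2.0, n_volumes=40)
        cab, _ = convolve_to_tr(mk(va + vb), tr=2.0, n_volumes=40)
        assert np.allclose(cab, ca + cb, atol=1e-10)

    def test_impulse_reproduces_hrf_samples(self):
        s = FeatureStream(name="x", kind="sparse", onsets=[0.0], durations=[0.0], values=[1.0])
        c, _ = convolve_to_tr(s, tr=1.0, n_volumes=30)
        assert np.allclose(c, canonical_hrf(np.arange(30.0)), atol=1e-12)

    def test_matches_dense_grid_oracle(self):
        # independent oracle: explicit Riemann-sum convolution on a fine grid
        s = FeatureStream(
            name="x", kind="sparse",
            onsets=[3.0, 11.5, 20.0], durations=[2.0, 1.0, 4.0], values=[1.0, -0.5, 2.0],
        )
        tr, n_vol, over = 2.0, 25, 50
        dt = tr / over
        n_fine = n_vol * over
        fine_t = np.arange(n_fine) * dt
        boxcar = np.zeros(n_fine)
        for o, d, v in zip(s.onsets, s.durations, s.values):
            boxcar[(fine_t >= o) & (fine_t < o + d)] += v
        hrf_t = np.arange(0.0, 32.0 + dt / 2, dt)
        kernel = canonical_hrf(hrf_t)
        oracle_fine = np.array(
            [np.sum(boxcar[max(0, i - len(kernel) + 1): i + 1][::-1] * kernel[: min(i + 1, len(kernel))]) * dt
             for i in range(n_fine)]
        )
        oracle = oracle_fine[::over]
        col, _ = convolve_to_tr(s, tr=tr, n_volumes=n_vol, oversampling=over)
        assert np.allclose(col, oracle, atol=1e-6)

    def test_time_shift_commutes_on_fine_grid(self):
        tr, over = 2.0, 50
        shift = tr / over * 10  # exact multiple of the fine spacing
        a = FeatureStream(name="x", kind="sparse", onsets=[4.0], durations=[2.0], values=[1.0])
        b = FeatureStream(name="x", kind="sparse", onsets=[4.0 + shift], durations=[2.0], values=[1.0])
        ca, _ = convolve_to_tr(a, tr=tr, n_volumes=40, oversampling=over)
        cb, _ = convolve_to_tr(b, tr=tr, n_volumes=40, oversampling=over)
        # compare on the fine-shifted grid: cb(t) == ca(t - shift) up to TR sampling
        fine_a, _ = convolve_to_tr(a, tr=tr / over, n_volumes=40 * over, oversampling=1)
        fine_b, _ = convolve_to_tr(b, tr=tr / over, n_volumes=40 * over, oversampling=1)
        assert np.allclose(fine_b[10:], fine_a[:-10], atol=1e-10)

    def test_matches_nilearn_regressor_shape(self):
        # independent cross-check: nilearn's SPM-model regressor for the same
        # events must match ours up to its own scale convention
        from nilearn.glm.first_level import compute_regressor

        onsets = np.array([4.0, 20.0, 36.0])
        durations = np.array([3.0, 1.0, 5.0])
        values = np.array([1.0, 2.0, 0.5])
        s = FeatureStream(name="x", kind="sparse", onsets=onsets, durations=durations, values=values)
        tr, n_vol = 2.0, 40
        ours, _ = convolve_to_tr(s, tr=tr, n_volumes=n_vol)
        frame_times = np.arange(n_vol) * tr
        theirs, _ = compute_regressor(
            np.vstack([onsets, durations, values]), "spm", frame_times
        )
        r = np.corrcoef(ours, theirs[:, 0])[0, 1]
        assert r > 0.999

    def test_dense_stream_supported(self):
        s = FeatureStream(name="x", kind="dense", values=np.ones(30), sampling_rate=1.0)
        c, _ = convolve_to_tr(s, tr=2.0, n_volumes=15)
        assert c[5] > 0.5  # plateau of the response to a sustained input

    def test_invalid_oversampling_rejected(self):
        s = FeatureStream(name="x", kind="sparse", onsets=[0.0], durations=[1.0], values=[1.0])
        with pytest.raises(ValidationError):
            convolve_to_tr(s, tr=2.0, n_volumes=10, oversampling=0)


class TestDrift:
    def test_column_count_formula(self):
        assert cosine_drift(128, 2.0, 128.0).shape == (128, 4)

    def test_short_series_zero_columns(self):
        assert cosine_drift(10, 2.0, 128.0).shape[1] == 0

    def test_columns_orthogonal(self):
        basis = cosine_drift(200, 2.0, 100.0)
        gram = basis.T @ basis
        assert np.allclose(gram, np.eye(basis.shape[1]), atol=1e-10)

    def test_cutoff_too_small_rejected(self):
        with pytest.raises(ValidationError):
            cosine_drift(100, 2.0, 3.0)

    def test_drift_plus_intercept_absorbs_slow_cosine(self):
        n, tr = 128, 2.0
        basis = cosine_drift(n, tr, 128.0)
        x = np.column_stack([np.ones(n), basis])
        # the slowest DCT component itself (period 2*n*tr) lies in the span
        slow = np.cos(np.pi * (np.arange(n) + 0.5) / n)
        resid = slow - x @ np.linalg.lstsq(x, slow, rcond=None)[0]
        assert np.abs(resid).max() < 1e-10


class TestBuildDesign:
    def _streams(self, rng):
        return {
            "speech": FeatureStream(
                name="speech", kind="sparse",
                onsets=np.arange(0.0, 180.0, 20.0), durations=np.full(9, 5.0),
                values=np.ones(9),
            )
        }

    def _confounds(self, n, rng):
        cols = {f"trans_{a}": rng.standard_normal(n) for a in "xyz"}
        cols.update({f"rot_{a}": rng.standard_normal(n) for a in "xyz"})
        cols.update({f"a_comp_cor_{i:02d}": rng.standard_normal(n) for i in range(6)})
        return pd.DataFrame(cols)

    def test_column_count(self, rng):
        # 1 predictor + 1 derivative + 12 confounds + 3 drift + 1 intercept
        spec = ModelSpec(
            dataset="d", predictors=["speech"],
            confound_selector=["trans_*", "rot_*", "a_comp_cor_*"],
        )
        dm = build_design(self._streams(rng), self._confounds(100, rng), spec, tr=2.0, n_volumes=100)
        n_drift = int(np.floor(2 * 100 * 2.0 / 128.0))
        assert len(dm.columns) == 2 + 12 + n_drift + 1
        assert dm.columns_with_role("intercept") == ["intercept"]
        assert "speech_derivative" in dm.columns

    def test_no_predictors_valid(self, rng):
        spec = ModelSpec(dataset="d", predictors=[], confound_selector=["trans_x"])
        dm = build_design({}, self._confounds(50, rng), spec, tr=2.0, n_volumes=50)
        assert "trans_x" in dm.columns and "intercept" in dm.columns

    def test_missing_confound_rejected(self, rng):
        spec = ModelSpec(dataset="d", predictors=["speech"], confound_selector=["nope"])
        with pytest.raises(Exception):
            build_design(self._streams(rng), self._confounds(50, rng), spec, tr=2.0, n_volumes=50)

    def test_duplicate_predictor_name_rejected(self, rng):
        streams = self._streams(rng)
        conf = self._confounds(50, rng)
        conf["speech"] = 0.5  # name collision with the predictor column
        spec = ModelSpec(dataset="d", predictors=["speech"], confound_selector=["speech"])
        with pytest.raises(ValidationError):
            build_design(streams, conf, spec, tr=2.0, n_volumes=50)

    def test_transformation_applied_before_convolution(self, rng):
        streams = self._streams(rng)
        streams["speech"] = streams["speech"].with_values(np.arange(9.0))
        spec = ModelSpec(
            dataset="d", predictors=["speech"],
            transformations=[Transformation("demean_rescale", ("speech",), "speech")],
        )
        dm = build_design(streams, pd.DataFrame(index=range(100)), spec, tr=2.0, n_volumes=100)
        # oracle: convolve the z-scored stream directly
        zs = streams["speech"].with_values(demean_rescale(np.arange(9.0)))
        expected, _ = convolve_to_tr(zs, tr=2.0, n_volumes=100)
        assert np.allclose(dm.frame["speech"].to_numpy(), expected)

    def test_deterministic(self, rng):
        spec = ModelSpec(dataset="d", predictors=["speech"], confound_selector=["trans_x"])
        conf = self._confounds(80, rng)
        a = build_design(self._streams(rng), conf, spec, tr=2.0, n_volumes=80)
        b = build_design(self._streams(rng), conf, spec, tr=2.0, n_volumes=80)
        assert np.array_equal(a.matrix(), b.matrix())


class TestCorrelationReport:
    def _dm(self, cols):
        roles = {name: "predictor" for name in cols}
        roles["intercept"] = "intercept"
        cols = dict(cols)
        cols["intercept"] = np.ones(len(next(iter(cols.values()))))
        return DesignMatrix(frame=pd.DataFrame(cols), tr=2.0, column_roles=roles)

    def test_duplicate_and_negated_columns(self, rng):
        x = rng.standard_normal(50)
        dm = self._dm({"a": x, "b": x.copy(), "c": -x})
        r, flagged = correlation_report(dm)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert flagged == ["intercept"]

    def test_orthogonal_columns_zero(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        r, _ = correlation_report(self._dm({"a": a, "b": b}))
        assert r.loc["a", "b"] == pytest.approx(0.0)
        assert np.allclose(np.diag(r.to_numpy()), 1.0)
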
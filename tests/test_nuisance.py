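"""Nuisance-module tests: phases, Fourier set, auxiliary regressors, OLS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cordconn.nuisance as nuis
from cordconn.synthetic import PhysioRecording


def _physio_from_beats(beat_times, fs=100.0, duration=None):
    duration = duration or (beat_times[-1] + 1.0)
    n = int(duration * fs)
    t = np.arange(n) / fs
    k = np.clip(np.searchsorted(beat_times, t, side="right") - 1,
                0, len(beat_times) - 2)
    frac = (t - beat_times[k]) / (beat_times[k + 1] - beat_times[k])
    cardiac = np.exp(3.0 * (np.cos(2 * np.pi * frac) - 1.0))
    resp = np.sin(2 * np.pi * 0.25 * t)
    return PhysioRecording(fs=fs, cardiac=cardiac, resp=resp,
                           trigger_times=np.array([0.0, 1.0]))


class TestCardiacPhase:
    def test_midpoint_is_pi(self):
        physio = _physio_from_beats(np.array([0.0, 1.0, 2.0, 3.0]))
        theta = nuis.cardiac_phase(physio, [0.5])
        assert theta[0] == pytest.approx(np.pi, abs=1e-6)

    def test_phase_zero_at_beat(self):
        physio = _physio_from_beats(np.array([0.0, 1.0, 2.0, 3.0]))
        theta = nuis.cardiac_phase(physio, [2.0])
        assert theta[0] == pytest.approx(0.0, abs=1e-6)

    def test_jittered_train_matches_interpolation_oracle(self):
        rng = np.random.default_rng(0)
        beats = np.cumsum(0.8 + 0.2 * rng.random(30))
        beats -= beats[0]
        physio = _physio_from_beats(beats)
        times = np.linspace(beats[1], beats[-2], 57)
        theta = nuis.cardiac_phase(physio, times)
        # brute-force oracle on the *detected* beats (detection is on-grid)
        det = nuis.detect_beats(physio.cardiac, physio.fs)
        oracle = np.empty_like(times)
        for i, t in enumerate(times):
            k = np.searchsorted(det, t, side="right") - 1
            k = min(max(k, 0), det.size - 2)
            oracle[i] = 2 * np.pi * ((t - det[k]) / (det[k + 1] - det[k]) % 1)
        assert np.allclose(theta, oracle, atol=1e-9)

    def test_constant_trace_raises(self):
        physio = PhysioRecording(fs=100.0, cardiac=np.ones(1000),
                                 resp=np.sin(np.arange(1000) / 50),
                                 trigger_times=np.array([0.0]))
        with pytest.raises(nuis.PhysioError, match="cardiac"):
            nuis.cardiac_phase(physio, [1.0])


class TestRespiratoryPhase:
    def _sine_physio(self, f=0.25, fs=100.0, duration=60.0):
        t = np.arange(int(duration * fs)) / fs
        return PhysioRecording(fs=fs, cardiac=np.cos(2 * np.pi * t),
                               resp=np.sin(2 * np.pi * f * t),
                               trigger_times=np.array([0.0]))

    def test_zero_crossing_has_near_zero_phase(self):
        physio = self._sine_physio()
        theta = nuis.respiratory_phase(physio, [4.0])  # sin(2pi*0.25*4)=0
        assert abs(theta[0]) < 0.1

    def test_sign_flips_between_limbs_at_equal_amplitude(self):
        physio = self._sine_physio()
        # amplitude |sin| equal at t=0.4 (rising) and t=1.6 (falling)
        th = nuis.respiratory_phase(physio, [0.4, 1.6])
        assert th[0] > 0 > th[1]
        assert abs(abs(th[0]) - abs(th[1])) < 0.05

    def test_matches_numerical_histogram_oracle(self):
        physio = self._sine_physio()
        times = np.linspace(1.0, 50.0, 40)
        theta = nuis.respiratory_phase(physio, times)
        r = physio.resp
        amp = np.interp(times, np.arange(r.size) / physio.fs, r)
        slope = np.gradient(r) * physio.fs
        sl = np.interp(times, np.arange(r.size) / physio.fs, slope)
        # brute-force cumulative amplitude mass, counted sample by sample
        oracle = np.empty_like(times)
        for i in range(times.size):
            frac = np.mean(np.abs(r) <= abs(amp[i]))
            oracle[i] = np.pi * frac * (1 if sl[i] >= 0 else -1)
        assert np.max(np.abs(theta - oracle)) < 0.05

    def test_constant_trace_raises(self):
        physio = PhysioRecording(fs=100.0, cardiac=np.cos(np.arange(500) / 10),
                                 resp=np.zeros(500),
                                 trigger_times=np.array([0.0]))
        with pytest.raises(nuis.PhysioError):
            nuis.respiratory_phase(physio, [1.0])


class TestRetroicor:
    @given(c=st.integers(0, 6), r=st.integers(0, 6), i=st.integers(0, 6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_column_count_formula(self, c, r, i):
        rng = np.random.default_rng(1)
        phases = nuis.PhysioPhases(theta_c=rng.uniform(0, 2 * np.pi, (2, 5)),
                                   theta_r=rng.uniform(-np.pi, np.pi, (2, 5)))
        mat, labels = nuis.build_retroicor(phases, c, r, i)
        expected = 2 * c + 2 * r + 4 * i ** 2
        assert mat.shape == (2, 5, expected)
        assert len(labels) == expected

    def test_default_orders_give_32_columns(self):
        rng = np.random.default_rng(2)
        phases = nuis.PhysioPhases(theta_c=rng.uniform(0, 2 * np.pi, (3, 7)),
                                   theta_r=rng.uniform(-np.pi, np.pi, (3, 7)))
        mat, _ = nuis.build_retroicor(phases)
        assert mat.shape[-1] == 32

    def test_columns_match_term_enumeration(self):
        rng = np.random.default_rng(3)
        tc = rng.uniform(0, 2 * np.pi, (1, 11))
        tr = rng.uniform(-np.pi, np.pi, (1, 11))
        phases = nuis.PhysioPhases(theta_c=tc, theta_r=tr)
        mat, labels = nuis.build_retroicor(phases, 2, 2, 1)
        assert mat.shape[-1] == 12
        expected = [np.sin(tc[0]), np.cos(tc[0]), np.sin(2 * tc[0]),
                    np.cos(2 * tc[0]), np.sin(tr[0]), np.cos(tr[0]),
                    np.sin(2 * tr[0]), np.cos(2 * tr[0]),
                    np.sin(tc[0] + tr[0]), np.cos(tc[0] + tr[0]),
                    np.sin(tc[0] - tr[0]), np.cos(tc[0] - tr[0])]
        assert np.allclose(mat[0], np.stack(expected, axis=-1))


class TestHighpassBasis:
    def test_reference_count(self):
        # floor(2 * 250 * 1.89 / 100) = floor(9.45) = 9
        assert nuis.build_highpass_basis(250, 1.89, 100.0).shape == (250, 9)

    def test_long_cutoff_gives_zero_columns(self):
        with pytest.warns(UserWarning):
            basis = nuis.build_highpass_basis(250, 1.89, 2000.0)
        assert basis.shape == (250, 0)

    def test_linear_drift_mostly_removed(self):
        basis = nuis.build_highpass_basis(250, 1.89, 100.0)
        drift = np.linspace(-1, 1, 250)
        resid = nuis.regress_nuisance(drift, basis)
        assert resid.var() < 0.05 * drift.var()

    def test_cutoff_below_2tr_rejected(self):
        with pytest.raises(nuis.DesignError):
            nuis.build_highpass_basis(250, 1.89, 3.0)


class TestAuxRegressors:
    def test_constant_rate_gives_constant_bpm_column(self):
        physio = _physio_from_beats(np.arange(0.0, 60.0, 1.0))
        hr = nuis.heart_rate_column(physio, np.linspace(5, 50, 20))
        assert np.allclose(hr, 60.0, atol=1e-6)

    def test_top_percentile_selects_single_voxel_of_ten(self):
        rng = np.random.default_rng(4)
        data = np.zeros((10, 1, 50))
        for v in range(10):
            data[v, 0] = (v + 1) * rng.standard_normal(50)
        mask = np.ones((10, 1), dtype=bool)
        col = nuis.csf_column(data, mask)
        # only the highest-variance voxel (v=9) passes the 90th percentile
        assert np.allclose(col, data[9, 0])

    def test_task_column_zero_without_events(self):
        col = nuis.task_column([], np.arange(10.0))
        assert np.allclose(col, 0.0)

    def test_task_column_peaks_after_event(self):
        times = np.arange(0, 30.0, 0.5)
        col = nuis.task_column([5.0], times)
        assert col[times <= 5.0].max() == 0.0
        assert times[np.argmax(col)] == pytest.approx(10.0, abs=1.5)


class TestPCA:
    def test_rank_one_data_first_component_dominates(self):
        t = np.sin(np.arange(40))
        data = np.zeros((3, 2, 40))
        weights = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        data += weights[:, :, None] * t[None, None, :]
        comps = nuis.build_pca_regressors(data, np.ones((3, 2), bool), 2)
        X = data[np.ones((3, 2), bool)]
        X = X - X.mean(axis=1, keepdims=True)
        proj = X @ comps[:, 0]
        assert (proj ** 2).sum() / (X ** 2).sum() > 0.999

    def test_components_orthonormal(self, rng):
        data = rng.standard_normal((4, 4, 30))
        comps = nuis.build_pca_regressors(data, np.ones((4, 4), bool), 5)
        gram = comps.T @ comps
        assert np.allclose(gram, np.eye(5), atol=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        data = rng.standard_normal((5, 1, 20))
        comps = nuis.build_pca_regressors(data, np.ones((5, 1), bool), 3)
        X = data[:, 0, :] - data[:, 0, :].mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        for j in range(3):
            v = evecs[:, order[j]]
            dot = abs(v @ comps[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_insufficient_voxels_warns(self, rng):
        data = rng.standard_normal((2, 1, 30))
        with pytest.warns(UserWarning):
            comps = nuis.build_pca_regressors(data, np.ones((2, 1), bool), 5)
        assert comps.shape[1] == 2


class TestRegression:
    def test_design_column_fully_removed(self, rng):
        X = rng.standard_normal((50, 3))
        resid = nuis.regress_nuisance(X[:, 1].copy(), X)
        assert np.max(np.abs(resid)) < 1e-8

    def test_orthogonal_series_unchanged_up_to_mean(self, rng):
        T = 64
        t = np.arange(T)
        X = np.column_stack([np.sin(2 * np.pi * t / T)])
        y = np.cos(2 * np.pi * 5 * t / T) + 3.0
        resid = nuis.regress_nuisance(y, X)
        assert np.allclose(resid, y - y.mean(), atol=1e-8)

    def test_matches_projection_matrix_oracle(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal((40, 3))
        Xi = np.column_stack([np.ones(40), X])
        P = np.eye(40) - Xi @ np.linalg.inv(Xi.T @ Xi) @ Xi.T
        resid = nuis.regress_nuisance(y, X)
        assert np.allclose(resid, P @ y, atol=1e-9)

    def test_residuals_uncorrelated_with_design(self, rng):
        X = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        resid = nuis.regress_nuisance(y, X)
        for j in range(5):
            assert abs(np.corrcoef(resid, X[:, j])[0, 1]) < 1e-8

    def test_collinear_design_warns_but_projects(self, rng):
        X = rng.standard_normal((30, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="rank-deficient"):
            resid = nuis.regress_nuisance(y, X)
        for j in range(3):
            assert abs(resid @ X[:, j]) < 1e-6

    def test_statsmodels_ols_oracle(self, rng):
        import statsmodels.api as sm
        X = rng.standard_normal((45, 4))
        y = rng.standard_normal(45)
        resid = nuis.regress_nuisance(y, X)
        sm_resid = sm.OLS(y, sm.add_constant(X)).fit().resid
        assert np.allclose(resid, sm_resid, atol=1e-9)
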
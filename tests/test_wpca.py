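import numpy as np
import pytest

import radarvitals as rv
from radarvitals.wpca import save_eigensystem_npz


def sig_from(values, fs=20.0):
    return rv.PhaseSignal(np.asarray(values, float), fs=fs, stage="separated")


class TestEmbed:
    def test_definition_on_tiny_series(self):
        traj = rv.embed(sig_from([1, 2, 3, 4]), 2)
        assert np.array_equal(traj.data, [[1, 2, 3], [2, 3, 4]])

    def test_half_length_window_shape(self):
        traj = rv.embed(sig_from(np.arange(100.0)), 50)
        assert traj.data.shape == (50, 51)

    def test_antidiagonal_average_recovers_source(self):
        x = np.random.default_rng(0).standard_normal(40)
        traj = rv.embed(sig_from(x), 7)
        assert np.allclose(rv.hankel_average(traj.data), x)

    @pytest.mark.parametrize("window", [1, 60])
    def test_window_out_of_range_rejected(self, window):
        with pytest.raises(rv.ParameterError):
            rv.embed(sig_from(np.arange(100.0)), window)


class TestDecompose:
    def test_rank_one_antisymmetric_rows(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        traj = rv.TrajectoryMatrix(np.vstack([x, -x]), source_fs=20.0, window=2)
        es = rv.decompose(traj)
        var = np.var(x)  # 1/L normalisation matches np.var
        assert es.eigenvalues[0] == pytest.approx(2 * var, rel=1e-10)
        assert es.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(np.abs(es.eigenvectors[:, 0]),
                           [1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_diagonal_covariance_recovers_axes(self):
        rng = np.random.default_rng(2)
        L = 2000
        a = np.sqrt(3) * rng.standard_normal(L)
        b = rng.standard_normal(L)
        # construct exactly uncorrelated rows with variances 3 and 1
        a = (a - a.mean()) / a.std() * np.sqrt(3)
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)
        b = b / b.std()
        traj = rv.TrajectoryMatrix(np.vstack([a, b]), source_fs=20.0, window=2)
        es = rv.decompose(traj)
        assert np.allclose(es.eigenvalues, [3.0, 1.0], rtol=1e-9)
        assert np.allclose(np.abs(es.eigenvectors), np.eye(2), atol=1e-9)

    def test_orthonormality_and_covariance_reconstruction(self, eigensystem):
        Q = eigensystem.eigenvectors
        assert np.max(np.abs(Q.T @ Q - np.eye(Q.shape[0]))) < 1e-10
        X = eigensystem.coefficients  # y = Q^T Xc, so Xc = Q y
        Xc = Q @ X
        cov = Xc @ Xc.T / Xc.shape[1]
        recon = Q @ np.diag(eigensystem.eigenvalues) @ Q.T
        assert np.max(np.abs(recon - cov)) < 1e-8

    def test_energy_conservation(self, eigensystem):
        Xc = eigensystem.eigenvectors @ eigensystem.coefficients
        trace = np.trace(Xc @ Xc.T / Xc.shape[1])
        assert eigensystem.eigenvalues.sum() == pytest.approx(trace, rel=1e-10)

    def test_degenerate_input_warns(self):
        traj = rv.TrajectoryMatrix(np.zeros((3, 10)), source_fs=20.0, window=3)
        with pytest.warns(UserWarning):
            es = rv.decompose(traj)
        assert np.all(es.eigenvalues == 0)
        assert np.array_equal(es.eigenvectors, np.eye(3))

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 200))
        traj = rv.TrajectoryMatrix(X, source_fs=20.0, window=6)
        es = rv.decompose(traj)
        peak = es.eigenvectors[
            np.argmax(np.abs(es.eigenvectors), axis=0), np.arange(6)
        ]
        assert np.all(peak > 0)


class TestDominantFrequency:
    @pytest.mark.parametrize("f0", [0.3, 1.4])
    def test_single_tone(self, f0):
        t = np.arange(1200) / 20.0
        f = rv.dominant_frequency(np.sin(2 * np.pi * f0 * t), 20.0)
        assert abs(f - f0) <= 20.0 / (4 * 1200)

    def test_dominated_mixture_picks_larger_tone(self):
        t = np.arange(1200) / 20.0
        y = 10 * np.sin(2 * np.pi * 0.3 * t) + np.sin(2 * np.pi * 1.4 * t)
        assert abs(rv.dominant_frequency(y, 20.0) - 0.3) <= 20.0 / 4800

    def test_constant_input_is_zero_hz(self):
        assert rv.dominant_frequency(np.full(100, 7.0), 20.0) == 0.0


class TestSelectComponents:
    def _es(self, eigenvalues, freqs, fs=20.0, n=1200):
        """EigenSystem stub with coefficient rows at given tone frequencies."""
        t = np.arange(n) / fs
        coeffs = np.vstack([np.sin(2 * np.pi * f * t) for f in freqs])
        M = len(eigenvalues)
        return rv.EigenSystem(
            eigenvalues=np.asarray(eigenvalues, float),
            eigenvectors=np.eye(M),
            coefficients=coeffs,
            mean=np.zeros(M),
            fs=fs,
        )

    def test_weights_follow_eigenvalue_share(self):
        es = self._es([2.0, 1.0, 1.0], [0.3, 0.32, 0.28])
        sel = rv.select_components(es, 20.0, (0.1, 0.5), max_k=3)
        assert sel.indices == (0, 1, 2)
        assert np.allclose(sel.weights, [0.5, 0.25, 0.25])

    def test_single_component_weight_is_one(self):
        es = self._es([5.0], [0.3])
        sel = rv.select_components(es, 20.0, (0.1, 0.5), max_k=1)
        assert np.allclose(sel.weights, [1.0])

    def test_band_selections_disjoint_on_simulated_signal(self, eigensystem,
                                                          worked_truth):
        fs = eigensystem.fs
        sel_r = rv.select_components(eigensystem, fs, rv.RESP_BAND)
        sel_h = rv.select_components(eigensystem, fs, rv.HEART_BAND)
        assert not set(sel_r.indices) & set(sel_h.indices)
        for sel, f0 in ((sel_r, worked_truth.f_resp), (sel_h, worked_truth.f_heart)):
            # the dominant (top-weight) component oscillates at the true rate
            top = sel.indices[int(np.argmax(sel.weights))]
            f = rv.dominant_frequency(eigensystem.coefficients[top], fs)
            assert abs(f - f0) < 0.05

    def test_eigenvalue_range_filter_applies(self):
        es = self._es([5.0, 2.0], [0.3, 0.3])
        sel = rv.select_components(
            es, 20.0, (0.1, 0.5), eigenvalue_range=(1.0, 3.0)
        )
        assert sel.indices == (1,)

    def test_empty_band_raises(self):
        es = self._es([1.0], [0.3])
        with pytest.raises(rv.NoPhysiologicalComponentError):
            rv.select_components(es, 20.0, (0.8, 2.0))

    def test_weights_order_isomorphic_to_eigenvalues(self, eigensystem):
        sel = rv.select_components(eigensystem, eigensystem.fs, rv.HEART_BAND)
        lams = eigensystem.eigenvalues[list(sel.indices)]
        assert np.all(np.diff(lams) <= 1e-12)
        assert np.all(np.diff(sel.weights) <= 1e-12)
        assert np.all(sel.weights >= 0)
        assert sel.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestReconstruct:
    def test_full_uniform_reconstruction_recovers_mean_removed_input(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        traj = rv.embed(sig_from(x), 10)
        es = rv.decompose(traj)
        sel = rv.ComponentSelection(
            indices=tuple(range(10)), weights=np.full(10, 0.1), band=(0.1, 9.9)
        )
        # uniform 1/M weights scaled by M = plain full PCA synthesis
        out = rv.reconstruct(es, sel, weights=np.ones(10))
        centred = traj.data - traj.data.mean(axis=1, keepdims=True)
        assert np.max(np.abs(out.values - rv.hankel_average(centred))) < 1e-8

    def test_top_component_matches_dominant_sinusoid(self):
        t = np.arange(1200) / 20.0
        x = np.sin(2 * np.pi * 0.3 * t)
        es = rv.decompose(rv.embed(sig_from(x), 100))
        sel = rv.select_components(es, 20.0, (0.1, 0.5), max_k=1)
        out = rv.reconstruct(es, sel)
        n = len(out.values)
        corr = np.corrcoef(out.values, x[:n])[0, 1]
        assert abs(corr) >= 0.99

    def test_linearity_in_weights(self, eigensystem):
        sel = rv.select_components(eigensystem, eigensystem.fs, rv.RESP_BAND)
        full = rv.reconstruct(eigensystem, sel)
        half = rv.reconstruct(eigensystem, sel, weights=sel.weights / 2)
        assert np.allclose(half.values, full.values / 2)

    def test_uniform_weight_mode_equals_plain_pca_path(self, eigensystem):
        """WPCA with equal weights reproduces the K-component PCA reconstruction."""
        sel = rv.select_components(eigensystem, eigensystem.fs, rv.HEART_BAND)
        k = len(sel.indices)
        uniform = rv.reconstruct(eigensystem, sel, weights=np.full(k, 1.0 / k))
        M = eigensystem.eigenvectors.shape[0]
        acc = np.zeros((M, eigensystem.coefficients.shape[1]))
        for i in sel.indices:
            acc += np.outer(eigensystem.eigenvectors[:, i],
                            eigensystem.coefficients[i]) / k
        assert np.allclose(uniform.values, rv.hankel_average(acc))

    def test_empty_selection_rejected(self):
        with pytest.raises(rv.ParameterError):
            rv.ComponentSelection(indices=(), weights=np.array([]), band=(0.1, 0.5))


class TestSeparationQuality:
    def test_recovered_bands_match_truth_across_seeds(self, radar_cfg,
                                                      pipeline_cfg):
        """At 10 dB SNR both branch reconstructions keep the true tone >= 90%."""
        hits = 0
        n_runs = 20
        for s in range(n_runs):
            truth = rv.VitalTruth(noise_snr_db=10.0, seed=1000 + s)
            cube = rv.simulate_if_cube(radar_cfg, truth, 60.0)
            prof = rv.range_fft(rv.remove_dc(cube))
            b = rv.select_target_bin(prof)
            dph = rv.diff_phase(rv.unwrap_phase(rv.extract_phase(prof, b)))
            es = rv.decompose(rv.embed(dph, 100))
            ok = True
            for band, f0 in ((rv.RESP_BAND, truth.f_resp),
                             (rv.HEART_BAND, truth.f_heart)):
                sel = rv.select_components(es, dph.fs, band)
                rec = rv.reconstruct(es, sel)
                f = rv.dominant_frequency(rec.values, dph.fs)
                pad_bin = dph.fs / (4 * len(rec.values))
                ok &= abs(f - f0) <= pad_bin
            hits += ok
        assert hits >= 0.9 * n_runs


def test_eigensystem_export(tmp_path, eigensystem):
    p = tmp_path / "es.npz"
    save_eigensystem_npz(eigensystem, p)
    with np.load(p) as z:
        assert np.allclose(z["eigenvalues"], eigensystem.eigenvalues)
        assert z["eigenvectors"].shape == eigensystem.eigenvectors.shape
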
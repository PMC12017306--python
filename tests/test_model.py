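import numpy as np
import pytest
from scipy.signal import fftconvolve

from retidend import decoder, encoder, evaluate, synthetic
from retidend.pipeline import encode_variants


@pytest.fixture(scope="module")
def frames():
    clips = synthetic.gen_cricket_scenes(n_clips=2, n_frames=2,
                                         distance_range=(8, 9), seed=21)
    return np.concatenate([c.frames for c in clips])


@pytest.fixture(scope="module")
def calibrated(frames):
    models = {v: encoder.build_population_model(v, noise_sd=0.1)
              for v in encoder.RGC_VARIANTS}
    ref = next(iter(models.values()))
    encoder.calibrate_model(ref, frames)
    for m in models.values():
        m.sigmoid_params = ref.sigmoid_params
    return models


class TestShapes:
    def test_bc_grid_arithmetic(self, frames, calibrated):
        lin = encoder.bc_linear(frames[:1], calibrated["t_mi"])
        assert lin["w"].shape == (1, 111, 111)
        assert lin["s"].shape == (1, 111, 111)
        assert (395 - 65) // 3 + 1 == 111

    def test_rgc_grids(self, frames, calibrated):
        assert encoder.encode(frames[:1], calibrated["t_mi"],
                              seed=0).shape == (1, 19, 19)
        assert encoder.encode(frames[:1], calibrated["n_wi"],
                              seed=0).shape == (1, 9, 9)

    def test_wrong_input_shape_rejected(self, calibrated):
        with pytest.raises(ValueError):
            encoder.bc_linear(np.zeros((1, 100, 100)), calibrated["t_mi"])


class TestSigmoid:
    def test_closed_form_calibration(self, rng):
        x = rng.normal(2.0, 3.0, size=5000)
        p = encoder.calibrate_sigmoid(x)
        assert p.d == pytest.approx(x.mean())
        assert p.b == pytest.approx(np.log(29.0 / 5.0) / x.std())
        f = encoder.generalized_sigmoid
        assert f(np.array([x.mean()]), p)[0] == pytest.approx(0.1, abs=1e-12)
        assert f(np.array([x.mean() + x.std()]), p)[0] \
            == pytest.approx(0.5, abs=1e-12)

    def test_unit_variance_solution(self):
        p = encoder.calibrate_sigmoid(np.array([-1.0, 1.0]))  # mean 0, sd 1
        assert p.b == pytest.approx(np.log(29.0 / 5.0))

    def test_range_and_monotonicity(self):
        p = encoder.SigmoidParams(b=1.5, d=0.0)
        x = np.linspace(-15, 15, 1001)
        f = encoder.generalized_sigmoid(x, p)
        assert np.all(f > 0) and np.all(f < 3)  # open range (0, 3)
        assert np.all(np.diff(f) > 0)           # monotone for b > 0

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            encoder.calibrate_sigmoid(np.ones(10))


class TestEncode:
    def test_zero_noise_deterministic(self, frames, calibrated):
        m = encoder.build_population_model("t_mi", noise_sd=0.0)
        m.sigmoid_params = calibrated["t_mi"].sigmoid_params
        a = encoder.encode(frames[:2], m, seed=1)
        b = encoder.encode(frames[:2], m, seed=99)
        assert np.array_equal(a, b)

    def test_uniform_input_interior_equal(self, calibrated):
        m = encoder.build_population_model("t_si", noise_sd=0.0)
        m.sigmoid_params = calibrated["t_si"].sigmoid_params
        flat = np.full((1, 395, 395), 0.6)
        lin = encoder.bc_linear(flat, m)["s"]
        expected = m.bc_kernels["s"].sum() * 0.6
        assert np.allclose(lin[0], expected, rtol=1e-10)

    def test_rgc_stage_linearity_pure_w(self, frames, calibrated):
        """Channel weights (1, 0) equal an independently computed pure-w
        pooling path."""
        m = encoder.build_population_model("t_wi", noise_sd=0.0)
        m.sigmoid_params = calibrated["t_wi"].sigmoid_params
        out = encoder.encode(frames[:1], m)
        # independent oracle: direct conv + sigmoid + pad + strided correlation
        lin = fftconvolve(frames[0], m.bc_kernels["w"][::-1, ::-1],
                          mode="valid")[::3, ::3]
        resp = encoder.generalized_sigmoid(lin, m.sigmoid_params["w"])
        padded = np.pad(resp, 3)
        k = m.rgc_kernel
        manual = np.zeros((19, 19))
        for i in range(19):
            for j in range(19):
                manual[i, j] = np.sum(
                    padded[i * 5:i * 5 + 27, j * 5:j * 5 + 27] * k)
        assert np.allclose(out[0], manual, atol=1e-10)

    def test_noise_variance_matches_sigma(self, frames, calibrated):
        """Across repeated encodings of one frame, the output variance
        equals sigma^2 propagated through the pooling weights."""
        m = calibrated["t_si"]
        reps = np.stack([encoder.encode(frames[:1], m, seed=s)[0]
                         for s in range(300)])
        var = reps.var(axis=0).mean()
        expected = 0.1**2 * (m.rgc_kernel**2).sum()
        assert var == pytest.approx(expected, rel=0.10)

    def test_shared_bc_stage_matches_per_variant_encode(self, frames,
                                                        calibrated):
        out = encode_variants(frames[:2], {"t_si": calibrated["t_si"]},
                              seed=3)["t_si"]
        m = encoder.build_population_model("t_si", noise_sd=0.0)
        m.sigmoid_params = calibrated["t_si"].sigmoid_params
        direct = encoder.encode(frames[:2], m)
        # same up to the noise draw
        assert out.shape == direct.shape
        assert np.abs(out - direct).mean() < 1.0

    def test_uncalibrated_model_rejected(self, frames):
        m = encoder.build_population_model("t_mi")
        with pytest.raises(ValueError, match="calibrate"):
            encoder.encode(frames[:1], m)


class TestRgcKernel:
    def test_truncated_gaussian_cutoff(self):
        k = encoder.truncated_gaussian_kernel(27, 15.0, 40.0, 85.0)
        c = 13
        yy, xx = np.mgrid[:27, :27]
        r = np.hypot(yy - c, xx - c) * 15.0
        assert np.all(k[r > 85.0] == 0)
        assert k[c, c] == 1.0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            encoder.build_population_model("x_yz")


class TestDecoder:
    def _blob_task(self, n, side, rng):
        X = rng.normal(0, 1, size=(n, side, side))
        y = np.zeros(n)
        y[: n // 2] = 1
        for i in range(n // 2):
            cy, cx = rng.integers(1, side - 1, 2)
            X[i, cy - 1:cy + 2, cx - 1:cx + 2] += 3.0
        perm = rng.permutation(n)
        return X[perm], y[perm]

    def test_separable_task_high_accuracy(self, rng):
        X, y = self._blob_task(2400, 9, rng)
        dec = decoder.ConvNetDecoder(seed=0, max_epochs=80, es_start=30,
                                     lr=3e-3, batch_size=256)
        dec.fit(X[:1800], y[:1800], validation=(X[1800:2100], y[1800:2100]))
        assert (dec.predict(X[2100:]) == y[2100:]).mean() >= 0.9

    def test_shuffled_labels_chance_level(self, rng):
        X, y = self._blob_task(800, 9, rng)
        ysh = rng.permutation(y)
        dec = decoder.ConvNetDecoder(seed=1, max_epochs=30, es_start=30,
                                     lr=3e-3, batch_size=256)
        dec.fit(X[:600], ysh[:600], validation=(X[600:700], ysh[600:700]))
        acc = (dec.predict(X[700:]) == ysh[700:]).mean()
        assert abs(acc - 0.5) <= 0.1

    def test_ensemble_configuration_honored(self, rng):
        X, y = self._blob_task(200, 9, rng)
        ens = decoder.DecoderEnsemble(n_members=3, seed=0, max_epochs=3,
                                      es_start=3, batch_size=64)
        ens.fit(X[:150], y[:150], validation=(X[150:], y[150:]))
        assert len(ens.members_) == 3
        for m in ens.members_:
            assert m.n_conv == 5 and m.n_filters == 3
        proba = ens.predict_proba(X[150:])[:, 1]
        member_mean = np.mean([d.predict_proba(X[150:])[:, 1]
                               for d in ens.members_], axis=0)
        assert np.allclose(proba, member_mean)

    def test_early_stopping_restores_best(self, rng):
        X, y = self._blob_task(400, 9, rng)
        dec = decoder.ConvNetDecoder(seed=2, max_epochs=40, es_start=5,
                                     patience=5, batch_size=128)
        dec.fit(X[:300], y[:300], validation=(X[300:], y[300:]))
        from retidend.decoder import _bce

        xv = (X[300:] - dec.input_mean_) / dec.input_sd_
        assert _bce(dec.net_.forward(xv)[0], y[300:]) \
            == pytest.approx(dec.best_val_loss_, abs=1e-9)


class TestAccuracyCurve:
    def test_step_function_crossing(self, rng):
        d = rng.uniform(0, 40, size=2000)
        correct = (d < 20).astype(float)
        flip = rng.random(2000) < 0.05
        correct[flip] = 1 - correct[flip]
        curve = evaluate.accuracy_vs_distance(correct, d)
        cross = curve.distances[np.argmin(np.abs(curve.accuracy - 0.5))]
        assert abs(cross - 20.0) < 5.0

    def test_constant_correctness_flat(self, rng):
        d = rng.uniform(0, 40, size=200)
        curve = evaluate.accuracy_vs_distance(np.ones(200), d)
        assert np.allclose(curve.accuracy, 1.0)

    def test_sparse_distances_warn(self, rng):
        d = np.repeat([5.0, 10.0, 20.0, 30.0], 25)
        correct = rng.integers(0, 2, 100).astype(float)
        with pytest.warns(UserWarning, match="widening"):
            evaluate.accuracy_vs_distance(correct, d, df=8)

    def test_bootstrap_diff_detects_separation(self, rng):
        a = (rng.random(400) < 0.8).astype(float)
        b = (rng.random(400) < 0.5).astype(float)
        diff, lo, hi = evaluate.bootstrap_accuracy_diff(a, b, seed=1)
        assert lo > 0 and lo < diff < hi
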
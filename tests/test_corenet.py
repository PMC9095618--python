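"""Phase-encoder network: configs, pipeline equivalence, gradients, training."""

import numpy as np
import pytest

from mcfholo.corenet import (DifferentiablePipeline, NetworkConfig,
                             TrainingConfig, build_corenet, forward_pipeline,
                             infer_hologram, load_checkpoint, npcc_loss,
                             prepare_inputs, save_checkpoint, train)
from mcfholo.errors import ConfigError, ConstantImageError, GeometryError
from mcfholo.mcf import make_synthetic_core_map, reconstruct_far_field
from mcfholo.metrics import correlation_coefficient
from mcfholo.nn import Tensor
from mcfholo.retrieval import core_gs_retrieve

LAM = 0.532
DESK = dict(pitch_x=2.0, pitch_y=2.0, wavelength=LAM)


def tiny_toy():
    """16x16 grid / 8-core map used for gradient and pipeline checks."""
    cm = make_synthetic_core_map(8, core_radius=1.5, min_spacing=3.5,
                                 facet_diameter=24.0, seed=2)
    cfg = NetworkConfig(input_size=(16, 16), depth=2, base_width=4, seed=0,
                        dtype="float64")
    return cm, cfg


class TestConfigs:
    def test_divisibility_enforced(self):
        with pytest.raises(ConfigError):
            NetworkConfig(input_size=(60, 60), depth=3)

    def test_output_must_not_shrink(self):
        with pytest.raises(ConfigError):
            NetworkConfig(input_size=(64, 64), output_size=(32, 32))

    def test_non_power_ratio_rejected(self):
        with pytest.raises(ConfigError):
            NetworkConfig(input_size=(64, 64), output_size=(192, 192))

    def test_training_config_bounds(self):
        with pytest.raises(ConfigError):
            TrainingConfig(epochs=0)
        with pytest.raises(ConfigError):
            TrainingConfig(batch_size=0)


class TestBuild:
    def test_same_seed_identical_parameters(self):
        cfg = NetworkConfig(input_size=(32, 32), depth=2, base_width=4, seed=9)
        a, b = build_corenet(cfg), build_corenet(cfg)
        pa, pb = a.parameters(), b.parameters()
        assert len(pa) == len(pb)
        for x, y in zip(pa, pb):
            np.testing.assert_array_equal(x.data, y.data)

    def test_different_seed_differs(self):
        cfg = NetworkConfig(input_size=(32, 32), depth=2, base_width=4, seed=1)
        cfg2 = NetworkConfig(input_size=(32, 32), depth=2, base_width=4, seed=2)
        a, b = build_corenet(cfg), build_corenet(cfg2)
        assert any(not np.array_equal(x.data, y.data)
                   for x, y in zip(a.parameters(), b.parameters()))

    def test_output_spatial_size_matches_config(self, rng):
        cfg = NetworkConfig(input_size=(16, 16), output_size=(32, 32), depth=2,
                            base_width=4, seed=0)
        model = build_corenet(cfg)
        x = Tensor(rng.standard_normal((2, 1, 16, 16)).astype(np.float32))
        y = Tensor(rng.standard_normal((2, 1, 16, 16)).astype(np.float32))
        out = model.forward(x, y, training=True)
        assert out.shape == (2, 1, 32, 32)

    def test_two_inputs_required(self, rng):
        cfg = NetworkConfig(input_size=(16, 16), depth=2, base_width=4, seed=0)
        model = build_corenet(cfg)
        with pytest.raises(TypeError):
            model.forward(Tensor(rng.standard_normal((1, 1, 16, 16))))


class TestPrepareInputs:
    def test_zero_target_gives_zero_planes(self):
        re, im = prepare_inputs(np.zeros((32, 32)), 700.0, **DESK)
        assert np.all(re == 0) and np.all(im == 0)

    def test_z_zero_gives_zero_imag_plane(self, rng):
        t = rng.random((64, 64))
        re, im = prepare_inputs(t, 0.0, **DESK)
        np.testing.assert_allclose(im, 0.0, atol=1e-12)
        np.testing.assert_allclose(re, np.sqrt(t), atol=1e-12)

    def test_round_trip_reproduces_in_band_target(self, glyph_targets):
        from mcfholo.fields import ComplexField, propagate

        t = glyph_targets[0]
        re, im = prepare_inputs(t, 700.0, **DESK)
        f = ComplexField(re + 1j * im, 2.0, 2.0, LAM)
        recon = np.abs(propagate(f, 700.0).values) ** 2
        assert correlation_coefficient(recon, t) >= 0.99


class TestNpccLoss:
    def test_perfect_match_is_minus_one(self, rng):
        X = rng.random((16, 16))
        assert npcc_loss(X, X) == pytest.approx(-1.0, abs=1e-12)

    def test_anticorrelated_is_plus_one(self, rng):
        X = rng.random((16, 16))
        assert npcc_loss(2.0 - X, X) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ConstantImageError):
            npcc_loss(np.ones((4, 4)), np.zeros((4, 4)))


class TestForwardPipeline:
    def test_deterministic_for_fixed_seed(self, rng):
        cm, cfg = tiny_toy()
        t = rng.random((16, 16))
        m1 = build_corenet(cfg)
        m2 = build_corenet(cfg)
        h1, _, r1 = forward_pipeline(m1, t, cm, 700.0, **DESK)
        h2, _, r2 = forward_pipeline(m2, t, cm, 700.0, **DESK)
        np.testing.assert_array_equal(h1, h2)
        np.testing.assert_array_equal(r1, r2)

    def test_core_gs_hologram_reproduces_core_gs_reconstruction(self, core_map,
                                                                glyph_targets):
        # substituting the network output with a rendered Core-GS hologram
        # must reproduce Core-GS's own reconstruction through the pipeline's
        # sample -> render -> propagate stages
        from mcfholo.mcf import render_core_field, sample_core_phases

        t = glyph_targets[0]
        res = core_gs_retrieve(t, core_map, z=700.0, iters=10, **DESK)
        phase_img = np.angle(render_core_field(res.hologram, core_map, t.shape,
                                               2.0, 2.0, LAM).values) % (2 * np.pi)
        resampled = sample_core_phases(phase_img, core_map, 2.0, 2.0)
        via_pipeline = reconstruct_far_field(resampled, core_map, t.shape,
                                             2.0, 2.0, LAM, 700.0)
        direct = reconstruct_far_field(res.hologram, core_map, t.shape,
                                       2.0, 2.0, LAM, 700.0)
        np.testing.assert_allclose(via_pipeline, direct, atol=1e-9)

    def test_geometry_mismatch_raises(self, core_map, rng):
        cfg = NetworkConfig(input_size=(32, 32), depth=2, base_width=4, seed=0)
        model = build_corenet(cfg)
        with pytest.raises(GeometryError):
            infer_hologram(model, rng.random((64, 64)), 700.0, **DESK)

    def test_end_to_end_gradient_matches_finite_differences(self, rng):
        """NPCC through the full physics pipeline on the 16x16/8-core toy."""
        from oracles import numeric_gradient

        cm, _ = tiny_toy()
        pipe = DifferentiablePipeline(cm, (16, 16), 2.0, 2.0, LAM, 700.0,
                                      dtype=np.float64)
        target = rng.random((1, 16, 16))
        phi0 = rng.uniform(0, 2 * np.pi, (1, 1, 16, 16))

        x = Tensor(phi0.copy(), requires_grad=True)
        loss = pipe.loss(x, target)
        loss.backward()
        ana = x.grad.copy()

        def f(arr):
            return float(pipe.loss(Tensor(arr), target).data)

        num = numeric_gradient(f, phi0.copy(), eps=1e-6)
        scale = np.max(np.abs(num))
        assert np.isfinite(ana).all()
        assert np.max(np.abs(ana - num)) / scale <= 1e-3

    def test_network_parameter_gradient_finite_and_accurate(self, rng):
        cm, cfg = tiny_toy()
        model = build_corenet(cfg)
        pipe = DifferentiablePipeline(cm, (16, 16), 2.0, 2.0, LAM, 700.0,
                                      dtype=np.float64)
        t = rng.random((2, 16, 16))
        xr = Tensor(rng.standard_normal((2, 1, 16, 16)))
        xi = Tensor(rng.standard_normal((2, 1, 16, 16)))

        def run():
            out = model.forward(xr, xi, training=True)
            return pipe.loss(out, t)

        loss = run()
        loss.backward()
        p = model.head_conv.weight
        ana = p.grad.copy()
        assert np.isfinite(ana).all()

        eps = 1e-6
        num = np.zeros_like(p.data)
        flat_p = p.data.ravel()
        flat_n = num.ravel()
        for i in range(flat_p.size):
            orig = flat_p[i]
            flat_p[i] = orig + eps
            fp = float(run().data)
            flat_p[i] = orig - eps
            fm = float(run().data)
            flat_p[i] = orig
            flat_n[i] = (fp - fm) / (2 * eps)
        scale = max(np.max(np.abs(num)), 1e-12)
        assert np.max(np.abs(ana - num)) / scale <= 1e-3


class TestTraining:
    def test_empty_dataset_rejected(self, core_map):
        model = build_corenet(NetworkConfig(seed=0))
        with pytest.raises(ValueError):
            train(model, [], core_map, TrainingConfig(epochs=1), **DESK)

    def test_single_sample_overfit(self, rng):
        # capacity check: one target, enough epochs -> high-fidelity recon
        cm = make_synthetic_core_map(60, core_radius=1.5, min_spacing=3.5,
                                     facet_diameter=40.0, seed=3)
        yy, xx = np.mgrid[0:32, 0:32]
        t = np.exp(-(((yy - 16) ** 2 + (xx - 19) ** 2) / 18.0))
        cfg = NetworkConfig(input_size=(32, 32), depth=2, base_width=8, seed=0)
        model = build_corenet(cfg)
        # EMA off: its averaging horizon exceeds this short 60-step run
        tcfg = TrainingConfig(epochs=60, batch_size=1, z=700.0, seed=0,
                              ema_decay=0.0)
        history = train(model, [t], cm, tcfg, **DESK)
        assert history.epoch_losses[-1] < history.epoch_losses[0]
        _, _, recon = forward_pipeline(model, t, cm, 700.0, **DESK)
        assert correlation_coefficient(recon, t) >= 0.9

    def test_training_reproducible(self, rng):
        cm, cfg = tiny_toy()
        cfg32 = NetworkConfig(input_size=(16, 16), depth=2, base_width=4, seed=0)
        targets = [rng.random((16, 16)) for _ in range(4)]
        hists = []
        models = []
        for _ in range(2):
            m = build_corenet(cfg32)
            h = train(m, targets, cm, TrainingConfig(epochs=2, batch_size=2,
                                                     z=700.0, seed=5), **DESK)
            hists.append(h.epoch_losses)
            models.append(m)
        assert hists[0] == hists[1]
        for a, b in zip(models[0].parameters(), models[1].parameters()):
            np.testing.assert_array_equal(a.data, b.data)


class TestInference:
    def test_same_target_same_hologram(self, rng):
        cm, cfg = tiny_toy()
        model = build_corenet(cfg)
        t = rng.random((16, 16))
        h1 = infer_hologram(model, t, 700.0, **DESK)
        h2 = infer_hologram(model, t, 700.0, **DESK)
        np.testing.assert_array_equal(h1, h2)
        assert np.all((h1 >= 0) & (h1 < 2 * np.pi))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cm, cfg = tiny_toy()
        model = build_corenet(cfg)
        t = rng.random((16, 16))
        ref = infer_hologram(model, t, 700.0, **DESK)
        p = tmp_path / "ckpt.h5"
        save_checkpoint(p, model, core_map=cm,
                        tcfg=TrainingConfig(epochs=1, z=700.0))
        model2, cm2, tcfg2 = load_checkpoint(p)
        np.testing.assert_array_equal(infer_hologram(model2, t, 700.0, **DESK), ref)
        np.testing.assert_allclose(cm2.centers, cm.centers)
        assert tcfg2.z == 700.0
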
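import numpy as np
import pytest

from scentpipe._nn import (
    Adam,
    BatchNorm1d,
    Conv3x3,
    Dense,
    ReLU,
    Sequential,
    softmax_cross_entropy,
)
from scentpipe.adversarial import (
    AdvConfig,
    _adversarial_step,
    predict_risk,
    residual_bias_probe,
    total_loss,
    train_adversarial,
)


class TestTotalLoss:
    @pytest.mark.parametrize(
        "l0,lq,lam,expected",
        [
            (0.9, 123.4, 0.0, 0.9),
            (0.7, 0.5, 1.0, 0.2),
            (1.0, 0.4, 0.5, 0.8),
        ],
    )
    def test_arithmetic(self, l0, lq, lam, expected):
        assert total_loss(l0, lq, lam) == pytest.approx(expected)

    def test_lambda_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, 1.5)
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, -0.1)

    def test_nonfinite_losses_rejected(self):
        with pytest.raises(ValueError):
            total_loss(float("nan"), 1.0, 0.5)


class TestGradientReversal:
    def _toy(self, seed=0):
        rng = np.random.default_rng(seed)
        backbone = Sequential([Dense(10, 6, rng), ReLU(), Dense(6, 4, rng)])
        dis = Sequential([Dense(4, 3, rng)])
        src = Sequential([Dense(4, 4, rng)])
        x = rng.normal(size=(8, 10))
        yd = rng.integers(0, 3, 8)
        ys = rng.integers(0, 4, 8)
        return backbone, dis, src, x, yd, ys

    def test_backbone_gradient_is_minus_lambda_times_source_gradient(self):
        """Finite-difference oracle: the source branch contributes exactly
        -lambda * dLq/dtheta to every backbone parameter."""
        backbone, dis, src, x, yd, ys = self._toy()
        lam = 0.7
        for p in backbone.params() + dis.params() + src.params():
            p.grad[...] = 0.0
        feats = backbone.forward(x)
        _, gq = softmax_cross_entropy(src.forward(feats), ys)
        grad_f = src.backward(gq)
        backbone.backward((-lam) * grad_f)
        analytic = [p.grad.copy() for p in backbone.params()]

        eps = 1e-6
        for pi, p in enumerate(backbone.params()):
            numeric = np.zeros_like(p.value)
            it = np.nditer(p.value, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p.value[idx]
                p.value[idx] = orig + eps
                lp, _ = softmax_cross_entropy(src.forward(backbone.forward(x)), ys)
                p.value[idx] = orig - eps
                lm, _ = softmax_cross_entropy(src.forward(backbone.forward(x)), ys)
                p.value[idx] = orig
                numeric[idx] = (lp - lm) / (2 * eps)
            assert np.max(np.abs(analytic[pi] - (-lam) * numeric)) < 1e-4

    def test_source_head_itself_minimizes_its_loss(self):
        """The head's own parameter gradient is the plain (unreversed)
        dLq/dtheta: a step along -grad lowers Lq."""
        backbone, dis, src, x, yd, ys = self._toy()
        for p in src.params():
            p.grad[...] = 0.0
        _adversarial_step(backbone, dis, src, x, yd, ys, lam=1.0)
        lq_before, _ = softmax_cross_entropy(src.forward(backbone.forward(x)), ys)
        for p in src.params():
            p.value -= 0.01 * p.grad
        lq_after, _ = softmax_cross_entropy(src.forward(backbone.forward(x)), ys)
        assert lq_after < lq_before

    def test_lambda_zero_contributes_nothing_to_backbone(self):
        backbone, dis, src, x, yd, ys = self._toy()
        for p in backbone.params() + dis.params() + src.params():
            p.grad[...] = 0.0
        _adversarial_step(backbone, dis, src, x, yd, ys, lam=0.0)
        with_head = [p.grad.copy() for p in backbone.params()]
        for p in backbone.params() + dis.params() + src.params():
            p.grad[...] = 0.0
        _adversarial_step(backbone, dis, src, x, yd, ys, lam=0.0,
                          block_source_grad=True)
        without = [p.grad.copy() for p in backbone.params()]
        for a, b in zip(with_head, without):
            np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def tiny_image_set():
    """Small labelled image set with a source-coded bright row and a
    class-coded bright column."""
    rng = np.random.default_rng(0)
    images, risks, sources = [], [], []
    risk_names = ("Control", "LowRisk", "HighRisk")
    for s in range(2):
        for r in range(3):
            for _ in range(6):
                img = rng.integers(0, 40, (256, 256, 3), dtype=np.uint8)
                img[40 + 60 * s : 60 + 60 * s, :, :] = 230  # source stripe
                img[:, 40 + 50 * r : 60 + 50 * r, :] = 200  # class column
                images.append(img)
                risks.append(risk_names[r])
                sources.append(f"S{s}")
    return np.stack(images), np.array(risks), np.array(sources)


class TestTraining:
    def test_history_satisfies_total_loss_identity(self, tiny_image_set):
        imgs, risks, sources = tiny_image_set
        cfg = AdvConfig(lam=0.5, epochs=4, seed=0, batch_size=12)
        model = train_adversarial(imgs, risks, sources, cfg)
        assert len(model.history) == 4
        for _, row in model.history.iterrows():
            assert row["ltotal"] == total_loss(row["l0"], row["lq"], row["lambda"])

    def test_deterministic_given_seed(self, tiny_image_set):
        imgs, risks, sources = tiny_image_set
        cfg = AdvConfig(lam=0.25, epochs=3, seed=5, batch_size=12)
        m1 = train_adversarial(imgs, risks, sources, cfg)
        m2 = train_adversarial(imgs, risks, sources, cfg)
        assert m1.history.equals(m2.history)
        for p1, p2 in zip(m1.backbone.params(), m2.backbone.params()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_lambda_zero_trajectory_matches_blocked_source_branch(self, tiny_image_set):
        imgs, risks, sources = tiny_image_set
        base = dict(lam=0.0, epochs=3, seed=3, batch_size=12)
        m_zero = train_adversarial(imgs, risks, sources, AdvConfig(**base))
        m_blocked = train_adversarial(
            imgs, risks, sources, AdvConfig(**base, block_source_grad=True)
        )
        assert np.allclose(m_zero.history["l0"], m_blocked.history["l0"])
        for p1, p2 in zip(m_zero.backbone.params(), m_blocked.backbone.params()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_single_source_with_adversary_rejected(self, tiny_image_set):
        imgs, risks, sources = tiny_image_set
        with pytest.raises(ValueError, match="single-source"):
            train_adversarial(
                imgs, risks, np.repeat("OnlySite", len(imgs)),
                AdvConfig(lam=0.5, epochs=1),
            )

    def test_resnet_backbone_unavailable(self):
        with pytest.raises(ValueError, match="resnet18"):
            AdvConfig(backbone="resnet18")


class TestPrediction:
    def test_probabilities_sum_to_one_and_deterministic(self, tiny_image_set):
        imgs, risks, sources = tiny_image_set
        cfg = AdvConfig(lam=0.0, epochs=3, seed=0, batch_size=12)
        model = train_adversarial(imgs, risks, sources, cfg)
        probs = predict_risk(model, imgs)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        dup = predict_risk(model, np.concatenate([imgs[:1], imgs[:1]]))
        np.testing.assert_array_equal(dup[0], dup[1])

    def test_learns_separable_classes_above_chance(self, tiny_image_set):
        imgs, risks, sources = tiny_image_set
        cfg = AdvConfig(lam=0.0, epochs=20, seed=0, batch_size=12)
        model = train_adversarial(imgs, risks, sources, cfg)
        probs = predict_risk(model, imgs)
        pred = np.array([model.risk_classes[i] for i in probs.argmax(1)])
        assert (pred == risks).mean() >= 1 / 3 + 0.2


def test_save_load_roundtrip_preserves_predictions(tiny_image_set, tmp_path):
    from scentpipe.adversarial import load_model, save_model

    imgs, risks, sources = tiny_image_set
    model = train_adversarial(
        imgs, risks, sources, AdvConfig(lam=0.5, epochs=2, seed=1, batch_size=12)
    )
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    np.testing.assert_array_equal(
        predict_risk(back, imgs), predict_risk(model, imgs)
    )
    assert back.risk_classes == model.risk_classes
    assert back.history["ltotal"].tolist() == model.history["ltotal"].tolist()


class TestResidualBiasProbe:
    def _model(self, tiny_image_set):
        imgs, risks, sources = tiny_image_set
        return train_adversarial(
            imgs, risks, sources, AdvConfig(lam=0.0, epochs=2, seed=0, batch_size=12)
        )

    def test_constant_features_give_chance(self, tiny_image_set):
        imgs, risks, sources = tiny_image_set
        model = self._model(tiny_image_set)
        # overwrite the latent projection so every sample maps to the
        # same feature vector
        dense = model.backbone.layers[-2]
        dense.W.value[...] = 0.0
        dense.b.value[...] = 1.0
        bn = model.backbone.layers[-1]
        bn.running_mean[...] = 1.0
        bn.running_var[...] = 1.0
        acc = residual_bias_probe(model, imgs, sources)
        assert abs(acc - 0.5) < 0.2  # two balanced sources -> chance 0.5

    def test_one_hot_source_features_fully_decodable(self, tiny_image_set):
        imgs, risks, sources = tiny_image_set
        model = self._model(tiny_image_set)
        feats = np.zeros((len(imgs), 4))
        feats[np.arange(len(imgs)), [0 if s == "S0" else 1 for s in sources]] = 1.0

        class Stub:
            cfg = model.cfg
            backbone = model.backbone

        import scentpipe.adversarial as adv

        orig = adv.latent_features
        adv.latent_features = lambda m, im: feats
        try:
            acc = residual_bias_probe(model, imgs, sources)
        finally:
            adv.latent_features = orig
        assert acc == 1.0


class TestNNKernel:
    def test_conv_matches_direct_convolution(self):
        rng = np.random.default_rng(0)
        conv = Conv3x3(2, 3, rng)
        x = rng.normal(size=(1, 2, 5, 5))
        out = conv.forward(x)
        # direct computation at an interior pixel
        i, j = 2, 3
        patch = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))[0, :, i : i + 3, j : j + 3]
        for o in range(3):
            expected = (conv.W.value[o] * patch).sum() + conv.b.value[o]
            assert out[0, o, i, j] == pytest.approx(expected)

    def test_batchnorm_normalizes_and_tracks_running_stats(self):
        rng = np.random.default_rng(1)
        bn = BatchNorm1d(4, momentum=0.0)  # running stats = last batch
        x = rng.normal(5.0, 3.0, (64, 4))
        y = bn.forward(x)
        np.testing.assert_allclose(y.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(y.std(axis=0), 1.0, atol=1e-3)
        bn.training = False
        y2 = bn.forward(x)
        np.testing.assert_allclose(y2, y, atol=1e-6)

    def test_adam_descends_quadratic(self):
        from scentpipe._nn import Param

        p = Param(np.array([5.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            p.grad[...] = 2 * p.value
            opt.step()
        assert abs(p.value[0]) < 0.1
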
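import numpy as np
import pytest

from yeastfish.phasecnn import layers as L
from yeastfish.phasecnn.model import CLASSES, CnnConfig, build_model, load_model, save_model
from yeastfish.phasecnn.predict import _metrics, predict_filtered, predict_scores
from yeastfish.phasecnn.preprocess import _std_projection, preprocess_cell
from yeastfish.phasecnn.train import (
    balanced_batches,
    focal_loss,
    focal_loss_batch,
    train,
)

TINY = CnnConfig(
    n_blocks=2, base_filters=4, fc_hidden=16, input_size=32,
    dropout_rate=0.0, epochs=2, batch_size=8, augment=False, seed=0,
)


class TestFocalLoss:
    def test_certain_prediction_zero_loss(self):
        assert focal_loss(np.eye(9)[4], 4) == pytest.approx(0.0, abs=1e-9)

    def test_gamma_zero_is_cross_entropy(self):
        p = np.full(9, 0.5 / 8)
        p[2] = 0.5
        assert focal_loss(p, 2, alpha=1.0, gamma=0.0) == pytest.approx(
            -np.log(0.5), abs=1e-9
        )

    def test_half_confidence_gamma_two(self):
        p = np.full(9, 0.5 / 8)
        p[0] = 0.5
        assert focal_loss(p, 0, gamma=2.0) == pytest.approx(0.25 * np.log(2), abs=1e-9)

    def test_invalid_scores_raise(self):
        with pytest.raises(ValueError):
            focal_loss(np.full(9, 0.2), 0)

    def test_batch_gradient_matches_numerics(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(0, 1, (4, 9))
        y = np.array([0, 3, 5, 8])
        loss, grad = focal_loss_batch(logits, y, alpha=1.0, gamma=2.0)
        eps = 1e-5
        for i, j in [(0, 0), (1, 3), (2, 2), (3, 8)]:
            lp = focal_loss_batch(
                logits + eps * np.eye(4)[i][:, None] * np.eye(9)[j], y, 1.0, 2.0
            )[0]
            lm = focal_loss_batch(
                logits - eps * np.eye(4)[i][:, None] * np.eye(9)[j], y, 1.0, 2.0
            )[0]
            assert grad[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)


class TestArchitecture:
    def test_filter_counts_double_per_block(self):
        cfg = CnnConfig()
        assert cfg.filters == (32, 64, 128, 256, 512)

    def test_output_scores_sum_to_one(self):
        m = build_model(TINY)
        x = np.random.default_rng(1).random((2, 3, 32, 32)).astype(np.float32)
        m.forward(x, train=True)  # populate BN running stats
        scores = predict_scores(m, x)
        assert scores.shape == (2, 9)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_spatial_size_after_five_pools(self):
        assert CnnConfig(input_size=80).final_spatial == 2

    def test_wrong_input_size_fails(self):
        m = build_model(TINY)
        bad = np.zeros((1, 3, 48, 48), dtype=np.float32)
        with pytest.raises(ValueError):
            m.forward(bad, train=False)

    def test_save_load_roundtrip(self, tmp_path):
        m = build_model(TINY)
        x = np.random.default_rng(2).random((4, 3, 32, 32)).astype(np.float32)
        m.forward(x, train=True)
        save_model(m, tmp_path / "m.pkl")
        m2 = load_model(tmp_path / "m.pkl")
        np.testing.assert_array_equal(
            m.forward(x, train=False), m2.forward(x, train=False)
        )


class TestGradients:
    def test_full_model_numerical_gradients(self):
        """Analytical backward matches central differences away from
        max-pool / attention argmax ties (checked via the median)."""
        cfg = CnnConfig(n_blocks=2, base_filters=4, fc_hidden=8, input_size=16,
                        dropout_rate=0.0, seed=0)
        m = build_model(cfg)
        rng = np.random.default_rng(0)
        x = rng.random((3, 3, 16, 16)).astype(np.float32)
        y = np.array([1, 4, 7])
        m.forward(x, train=True)
        m.zero_grad()
        logits = m.forward(x, train=False)
        _, dl = focal_loss_batch(logits, y, 1.0, 2.0)
        m.backward(dl)

        def loss_of():
            return focal_loss_batch(m.forward(x, train=False), y, 1.0, 2.0)[0]

        errs = []
        for p in m.params():
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for idx in rng.integers(0, flat.size, 2):
                eps, old = 1e-3, flat[idx]
                flat[idx] = old + eps
                lp = loss_of()
                flat[idx] = old - eps
                lm = loss_of()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                errs.append(abs(num - gflat[idx]) / max(1e-6, abs(num) + abs(gflat[idx])))
        assert np.median(errs) < 1e-3
        assert np.percentile(errs, 90) < 0.1


class TestTraining:
    @staticmethod
    def _toy_data(n_per_class=2, size=32, seed=0):
        """Trivially separable composites: class k lights up sector k."""
        rng = np.random.default_rng(seed)
        xs, ys = [], []
        for c in range(9):
            for _ in range(n_per_class):
                img = rng.random((size, size, 3)).astype(np.float32) * 0.1
                r, col = divmod(c, 3)
                img[r * 10 : r * 10 + 8, col * 10 : col * 10 + 8, :] = 1.0
                xs.append(img)
                ys.append(c)
        return np.stack(xs), np.array(ys)

    def test_memorises_nine_examples(self):
        x, y = self._toy_data(n_per_class=1)
        cfg = CnnConfig(
            n_blocks=2, base_filters=8, fc_hidden=32, input_size=32,
            dropout_rate=0.0, epochs=200, batch_size=9, augment=False,
            learning_rate=1e-3, seed=1,
        )
        m = build_model(cfg)
        hist = train(m, x, y, cfg)
        assert min(hist.loss) < 0.01

    def test_balanced_sampler_uniform_marginals(self):
        rng = np.random.default_rng(2)
        y = np.repeat(np.arange(9), [100, 5, 5, 5, 5, 5, 5, 5, 5])  # imbalanced
        seen = np.zeros(9)
        n_batches, bs = 1000, 18
        for idx in balanced_batches(y, n_batches, bs, 9, rng):
            seen += np.bincount(y[idx], minlength=9)
        total = n_batches * bs
        expect = total / 9
        sd = np.sqrt(total * (1 / 9) * (8 / 9))
        assert np.all(np.abs(seen - expect) < 3 * sd)

    def test_empty_class_raises_naming_it(self):
        from yeastfish.exceptions import ConfigurationError

        y = np.array([0, 1, 2])  # classes 3.. missing
        with pytest.raises(ConfigurationError, match="Early-M"):
            list(balanced_batches(y, 1, 4, 9, np.random.default_rng(0)))

    def test_fixed_seed_reproducible_weights(self):
        x, y = self._toy_data(n_per_class=2)
        weights = []
        for _ in range(2):
            m = build_model(TINY)
            train(m, x, y, TINY)
            weights.append(np.concatenate([p.value.ravel() for p in m.params()]))
        np.testing.assert_array_equal(weights[0], weights[1])


class _StubModel:
    """Returns pre-set logits; lets filtering be tested deterministically."""

    def __init__(self, logits):
        self.logits = np.asarray(logits, dtype=np.float32)

    def forward(self, x, train=False):
        return self.logits[: len(x)]


class TestPredictFiltered:
    @staticmethod
    def _single_class_scores(n=100, seed=0):
        rng = np.random.default_rng(seed)
        logits = np.zeros((n, 9), dtype=np.float32)
        logits[:, 0] = 1.0 + rng.random(n)  # everything predicted as G1
        return logits

    def test_twenty_percent_filtered_per_class(self):
        logits = self._single_class_scores(100)
        model = _StubModel(logits)
        preds = predict_filtered(model, np.zeros((100, 1, 2, 2)), filter_fraction=0.2)
        assert sum(p.retained for p in preds) == 80
        dropped_conf = [p.confidence for p in preds if not p.retained]
        kept_conf = [p.confidence for p in preds if p.retained]
        assert max(dropped_conf) <= min(kept_conf)

    def test_fraction_zero_retains_all(self):
        model = _StubModel(self._single_class_scores(50))
        preds = predict_filtered(model, np.zeros((50, 1, 2, 2)), filter_fraction=0.0)
        assert all(p.retained for p in preds)

    def test_increasing_fraction_never_readds(self):
        model = _StubModel(self._single_class_scores(60))
        kept = None
        for frac in (0.0, 0.1, 0.3, 0.5):
            preds = predict_filtered(model, np.zeros((60, 1, 2, 2)), filter_fraction=frac)
            now = {p.cell_id for p in preds if p.retained}
            if kept is not None:
                assert now <= kept
            kept = now

    def test_invalid_fraction_raises(self):
        model = _StubModel(self._single_class_scores(10))
        with pytest.raises(ValueError):
            predict_filtered(model, np.zeros((10, 1, 2, 2)), filter_fraction=1.0)


class TestMetrics:
    def test_perfect_classifier(self):
        y = np.repeat(np.arange(9), 5)
        scores = np.eye(9)[y]
        acc, f1, aucs, conf = _metrics(y, y, scores, 9)
        assert acc == 1.0 and f1 == 1.0
        assert all(v == 1.0 for v in aucs.values())
        assert conf.trace() == len(y)

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(3)
        y = np.repeat(np.arange(9), 400)
        scores = rng.random((len(y), 9))
        scores /= scores.sum(axis=1, keepdims=True)
        acc, f1, aucs, conf = _metrics(y, scores.argmax(1), scores, 9)
        assert abs(acc - 1 / 9) < 0.03
        assert all(abs(v - 0.5) < 0.05 for v in aucs.values())

    def test_confusion_diagonal_equals_accuracy(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 9, 300)
        pred = rng.integers(0, 9, 300)
        scores = np.eye(9)[pred]
        acc, _, _, conf = _metrics(y, pred, scores, 9)
        assert conf.trace() / conf.sum() == pytest.approx(acc)
        assert np.array_equal(conf.sum(axis=1), np.bincount(y, minlength=9))


class TestPreprocess:
    def test_std_projection_of_constant_stack_is_zero(self):
        assert np.all(_std_projection(np.full((8, 10, 10), 3.0)) == 0)

    def test_composite_shape_and_range(self, noiseless_field):
        f = noiseless_field
        lab = int(f.truth_objects["label"].iloc[0])
        comp = preprocess_cell(
            {ch: f.stacks[ch] for ch in ("BF", "SPB", "DAPI")}, f.label_mask, lab
        )
        assert comp.image.shape == (80, 80, 3)
        assert comp.image.min() >= 0.0 and comp.image.max() <= 1.0

    def test_channel_order_bf_spb_dapi(self):
        """A signal present only in the SPB stack lands in channel index 1."""
        rng = np.random.default_rng(5)
        mask = np.zeros((40, 40), dtype=np.int32)
        mask[10:30, 10:30] = 1
        flat = {ch: rng.random((6, 40, 40)) * 0.01 for ch in ("BF", "DAPI")}
        spb = np.zeros((6, 40, 40))
        spb[3, 20, 20] = 100.0  # high variance along z at one pixel
        comp = preprocess_cell({**flat, "SPB": spb}, mask, 1)
        # after local thresholding the SPB plane is sparse: a single bright
        # dot (plus the boundary overlay), unlike the noise-filled BF plane
        spb_plane = comp.image[:, :, 1]
        bf_plane = comp.image[:, :, 0]
        assert spb_plane.max() == 1.0
        assert (spb_plane > 0).mean() < 0.05
        assert (bf_plane > 0).mean() > 5 * (spb_plane > 0).mean()

    def test_mother_and_bud_composites_differ(self, noiseless_field):
        f = noiseless_field
        buds = f.truth_objects[f.truth_objects.role == "bud"]
        if buds.empty:
            pytest.skip("field has no budded cell")
        bud = buds.iloc[0]
        mother_lab = int(bud.mother_label)
        bud_lab = int(bud.label)
        stacks = {ch: f.stacks[ch] for ch in ("BF", "SPB", "DAPI")}
        comp_m = preprocess_cell(stacks, f.label_mask, mother_lab, partner_id=bud_lab)
        comp_b = preprocess_cell(stacks, f.label_mask, bud_lab, partner_id=mother_lab)
        assert not np.array_equal(comp_m.image, comp_b.image)

    def test_degenerate_mask_raises(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[5, 5] = 1
        stacks = {ch: np.zeros((4, 20, 20)) for ch in ("BF", "SPB", "DAPI")}
        with pytest.raises(ValueError):
            preprocess_cell(stacks, mask, 1)


def test_class_labels_cover_all_nine_phases():
    assert len(CLASSES) == 9 and "G2-Bud" in CLASSES
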
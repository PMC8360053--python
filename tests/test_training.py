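import numpy as np
import pytest

from spcnet.labels import SoftLabelVolume
from spcnet.model import ModelConfig
from spcnet.training import (
    ClassWeights,
    PreparedCase,
    TrainConfig,
    augment_sample,
    compute_class_weights,
    make_folds,
    select_training_slices,
    train_fold,
    weighted_cce,
)
from spcnet.volume import VolumeError

from oracles import scalar_weighted_cce


def _case_from_hard(hard, gland=None, case_id="c0", tag="prostatectomy-like"):
    """PreparedCase from a (S, H, W) integer label array."""
    hard = np.asarray(hard)
    probs = np.stack([(hard == c).astype(float) for c in range(3)])
    labels = SoftLabelVolume(probs, np.zeros(hard.shape, bool), 0.6, 3.0)
    gland = np.ones(hard.shape, bool) if gland is None else gland
    rng = np.random.default_rng(0)
    return PreparedCase(
        case_id=case_id,
        t2w=rng.standard_normal(hard.shape),
        adc=rng.standard_normal(hard.shape),
        gland=gland,
        labels=labels,
        cohort_tag=tag,
    )


class TestSliceSelection:
    def test_cancer_slices_only(self):
        hard = np.zeros((6, 4, 4), int)
        hard[2, 1, 1] = 2
        hard[3, 2, 2] = 1
        case = _case_from_hard(hard)
        assert select_training_slices([case]) == [("c0", 2), ("c0", 3)]

    def test_normal_case_all_gland_slices(self):
        hard = np.zeros((6, 4, 4), int)
        gland = np.zeros((6, 4, 4), bool)
        gland[1:5] = True
        case = _case_from_hard(hard, gland, tag="normal")
        assert [s for _, s in select_training_slices([case])] == [1, 2, 3, 4]

    def test_empty_cohort(self):
        assert select_training_slices([]) == []

    def test_gland_required(self):
        case = _case_from_hard(np.zeros((2, 4, 4), int), np.zeros((2, 4, 4), bool))
        with pytest.raises(VolumeError):
            select_training_slices([case])


class TestClassWeights:
    def test_balanced_gives_three(self):
        hard = np.repeat([0, 1, 2], 4).reshape(1, 3, 4)
        case = _case_from_hard(hard)
        w = compute_class_weights([case], [("c0", 0)])
        assert w.w == pytest.approx((3.0, 3.0, 3.0))
        assert w.M_total == 12

    def test_hand_counted_example(self):
        # 6 pixels: 4 normal, 1 indolent, 1 aggressive -> w = (1.5, 6, 6)
        hard = np.array([[[0, 0, 0], [0, 1, 2]]])
        case = _case_from_hard(hard)
        w = compute_class_weights([case], [("c0", 0)])
        assert w.w == pytest.approx((1.5, 6.0, 6.0))

    def test_soft_labels_count_fractionally(self):
        probs = np.zeros((3, 1, 1, 4))
        probs[0, 0, 0, :2] = 1.0
        probs[1, 0, 0, 2:] = 0.5
        probs[2, 0, 0, 2:] = 0.5
        labels = SoftLabelVolume(probs, np.array([[[0, 0, 1, 1]]], bool), 0.6, 3.0)
        case = PreparedCase(
            "c0",
            np.zeros((1, 1, 4)),
            np.zeros((1, 1, 4)),
            np.ones((1, 1, 4), bool),
            labels,
        )
        w = compute_class_weights([case], [("c0", 0)])
        # masses: normal 2, indolent 1, aggressive 1; M = 4
        assert w.w == pytest.approx((2.0, 4.0, 4.0))

    def test_zero_mass_class_errors_with_name(self):
        probs = np.zeros((3, 1, 1, 2))
        probs[1:, 0, 0, :] = 0.5
        labels = SoftLabelVolume(probs, np.ones((1, 1, 2), bool), 0.6, 3.0)
        case = PreparedCase(
            "c0",
            np.zeros((1, 1, 2)),
            np.zeros((1, 1, 2)),
            np.ones((1, 1, 2), bool),
            labels,
        )
        with pytest.raises(VolumeError, match="normal"):
            compute_class_weights([case], [("c0", 0)])


class TestWeightedCCE:
    def test_perfect_prediction_near_zero(self):
        w = ClassWeights((1.0, 1.0, 1.0), 1)
        loss = weighted_cce(np.array([[1.0, 0, 0]]), np.array([[1.0, 0, 0]]), w)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_closed_form(self):
        w = ClassWeights((3.0, 3.0, 3.0), 1)
        loss = weighted_cce(
            np.array([[1 / 3, 1 / 3, 1 / 3]]), np.array([[0.0, 1.0, 0.0]]), w
        )
        assert loss == pytest.approx(3 * np.log(3), rel=1e-9)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), 50)
        y = rng.dirichlet(np.ones(3), 50)
        l1 = weighted_cce(p, y, ClassWeights((1.0, 2.0, 3.0), 50))
        l2 = weighted_cce(p, y, ClassWeights((2.0, 4.0, 6.0), 50))
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_matches_scalar_oracle_on_soft_labels(self):
        """Vectorized loss agrees with an independent scalar implementation
        to 1e-9 over 1000 random soft-labeled pixels."""
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(3), 1000)
        y = rng.dirichlet(np.ones(3), 1000)
        half = rng.random(1000) < 0.3  # some 0.5/0.5 ungraded-style labels
        y[half] = (0.0, 0.5, 0.5)
        w = (1.1, 17.3, 42.0)
        ours = weighted_cce(p, y, ClassWeights(w, 1000))
        assert ours == pytest.approx(scalar_weighted_cce(p, y, w), abs=1e-9)

    def test_unit_weights_equal_plain_cce(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(3), 200)
        y = np.eye(3)[rng.integers(0, 3, 200)]
        ours = weighted_cce(p, y, ClassWeights((1.0, 1.0, 1.0), 200))
        plain = -np.mean(np.log(np.clip(p[np.arange(200), y.argmax(1)], 1e-7, 1)))
        assert ours == pytest.approx(plain, abs=1e-12)

    def test_inverse_proportion_weights_balance_classes(self):
        """With w_i = M / m_i, every class's total weighted label mass is the
        same (= M), so the expected per-class loss contributions match."""
        hard = np.zeros((1, 10, 100), int)
        hard[0, :, :20] = 1
        hard[0, :, 20:27] = 2  # imbalanced: 730 / 200 / 70
        case = _case_from_hard(hard)
        w = compute_class_weights([case], [("c0", 0)])
        masses = [case.labels.probs[c].sum() for c in range(3)]
        weighted = [wi * mi for wi, mi in zip(w.w, masses)]
        np.testing.assert_allclose(weighted, w.M_total, rtol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(VolumeError):
            weighted_cce(
                np.ones((2, 3)), np.ones((3, 3)), ClassWeights((1, 1, 1), 1)
            )


class TestFolds:
    def test_partition(self):
        ids = [f"c{i}" for i in range(10)]
        folds = make_folds(ids, 5, seed=3)
        assert sorted(folds) == sorted(ids)
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert (sizes == 2).all()

    def test_deterministic(self):
        ids = [f"c{i}" for i in range(7)]
        assert make_folds(ids, 3, 5) == make_folds(ids, 3, 5)

    def test_too_few_cases(self):
        with pytest.raises(VolumeError):
            make_folds(["a"], 2, 0)


class TestAugmentation:
    def _sample(self, rng):
        x = rng.standard_normal((3, 32, 32))
        y = np.zeros((3, 32, 32))
        y[0] = 1.0
        y[:, 10:20, 10:20] = np.array([0.0, 1.0, 0.0])[:, None, None]
        m = np.zeros((32, 32), bool)
        m[4:28, 4:28] = True
        return x, y, m

    def test_identity_without_rotation_or_flip(self):
        rng = np.random.default_rng(0)
        x, y, m = self._sample(rng)
        cfg = TrainConfig(rotation_range_deg=(0.0, 0.0), lr_flip=False)
        (x2,), y2, (m2,) = augment_sample([x], y, [m], rng, cfg)
        np.testing.assert_array_equal(x2, x)
        np.testing.assert_array_equal(y2, y)
        np.testing.assert_array_equal(m2, m)

    def test_flip_twice_is_identity(self):
        rng = np.random.default_rng(1)
        x, y, m = self._sample(rng)
        np.testing.assert_array_equal(x[..., ::-1][..., ::-1], x)

    def test_labels_stay_valid_probabilities(self):
        rng = np.random.default_rng(2)
        x, y, m = self._sample(rng)
        cfg = TrainConfig()
        for _ in range(5):
            _, y2, _ = augment_sample([x], y, [m], rng, cfg)
            np.testing.assert_allclose(y2.sum(axis=0), 1.0, atol=1e-12)

    def test_rotation_preserves_gland_area(self, mixed_prepared):
        """In-plane rotation of an interior gland changes its pixel count by
        less than 5%."""
        rng = np.random.default_rng(3)
        cfg = TrainConfig()
        s = int(np.flatnonzero(mixed_prepared.gland.any(axis=(1, 2)))[3])
        m = mixed_prepared.gland[s]
        before = m.sum()
        for _ in range(5):
            _, _, (m2,) = augment_sample(
                [mixed_prepared.t2w[s][None]],
                mixed_prepared.labels.probs[:, s],
                [m],
                rng,
                cfg,
            )
            assert abs(int(m2.sum()) - before) <= 0.05 * before


class TestTrainFold:
    def _tiny_cases(self, n=3):
        rng = np.random.default_rng(4)
        cases = []
        for i in range(n):
            hard = np.zeros((4, 16, 16), int)
            hard[1:3, 5:10, 5:10] = 1
            hard[2, 6:8, 6:8] = 2
            case = _case_from_hard(hard, case_id=f"c{i}")
            # give the lesion real contrast so the loss can fall
            case.adc[hard > 0] -= 3.0
            case.adc[hard == 2] -= 2.0
            cases.append(case)
        return cases

    def _cfgs(self, epochs=2):
        model_cfg = ModelConfig(
            n_scales=3, branch_depth=1, base_width=4, input_size_px=16, seed=0
        )
        train_cfg = TrainConfig(
            epochs=epochs, batch_size=4, n_folds=2, seed=1, augment=False
        )
        return model_cfg, train_cfg

    def test_smoke_loss_decreases(self):
        cases = self._tiny_cases()
        model_cfg, train_cfg = self._cfgs(epochs=3)
        _, history = train_fold(cases, [], model_cfg, train_cfg)
        assert history["train_loss"][-1] < history["train_loss"][0]

    def test_seeded_runs_identical(self):
        cases = self._tiny_cases()
        model_cfg, train_cfg = self._cfgs()
        _, h1 = train_fold(cases, [], model_cfg, train_cfg)
        _, h2 = train_fold(cases, [], model_cfg, train_cfg)
        assert h1["train_loss"] == pytest.approx(h2["train_loss"], rel=1e-12)

    def test_empty_train_set_rejected(self):
        model_cfg, train_cfg = self._cfgs()
        with pytest.raises(VolumeError):
            train_fold([], [], model_cfg, train_cfg)
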
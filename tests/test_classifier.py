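import numpy as np
import pytest

from swemg import (
    ActionLabel,
    ClassifierConfig,
    NoiseModel,
    RmsLogisticBaseline,
    SplitSpec,
    build_model,
    evaluate,
    simulate_corpus,
    split_corpus,
    train,
)
from swemg.classifier import (
    LABEL_TO_INDEX,
    SplitError,
    _report_from_predictions,
    corpus_to_tensors,
)

TINY_CFG = ClassifierConfig(conv_widths=(4, 6, 8), fc_nodes=32, epochs=2, seed=0,
                            tta_shift_segments=0)


@pytest.fixture(scope="module")
def small_corpus():
    """2 subjects x 11 actions x 3 reps, quiet conditions."""
    noise = NoiseModel(baseline_rms=1.0, hum_amplitude=0.0, artifact_rate=0.0)
    return simulate_corpus(n_subjects=2, n_reps=3, seed=1, noise=noise)


class TestSplit:
    def test_study_scale_partition_sizes(self):
        labels = [lab for lab in ActionLabel for _ in range(50)]
        corpus = [_FakeRec(lab) for lab in labels]
        tr, va, te = split_corpus(corpus, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (330, 110, 110)

    def test_every_class_in_every_partition(self, small_corpus):
        for part in split_corpus(small_corpus, SplitSpec(seed=3)):
            assert {r.label for r in part} == set(ActionLabel)

    def test_one_recording_per_class_rejected(self):
        corpus = [_FakeRec(lab) for lab in ActionLabel]
        with pytest.raises(SplitError):
            split_corpus(corpus, SplitSpec(seed=0))

    def test_deterministic_in_seed(self, small_corpus):
        a = split_corpus(small_corpus, SplitSpec(seed=5))
        b = split_corpus(small_corpus, SplitSpec(seed=5))
        for pa, pb in zip(a, b):
            assert [id(r) for r in pa] == [id(r) for r in pb]

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_frac=0.5, val_frac=0.2, test_frac=0.2)


class _FakeRec:
    def __init__(self, label):
        self.label = label


class TestModel:
    def test_softmax_head_is_probability_vector(self):
        model = build_model(TINY_CFG)
        x = np.random.default_rng(0).standard_normal((3, 16, 31, 125)).astype(np.float32)
        p = model.predict_proba(x)
        assert p.shape == (3, 11)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_head_width_follows_config(self):
        cfg = ClassifierConfig(conv_widths=(4, 6, 8), fc_nodes=32, n_classes=2, seed=0)
        model = build_model(cfg)
        x = np.zeros((1, 16, 31, 125), dtype=np.float32)
        assert model.predict_proba(x).shape == (1, 2)

    def test_eval_forward_deterministic(self):
        model = build_model(TINY_CFG)
        x = np.random.default_rng(1).standard_normal((2, 16, 31, 125)).astype(np.float32)
        assert np.array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_incompatible_input_shape_rejected(self):
        model = build_model(TINY_CFG)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 16, 10, 10), dtype=np.float32))

    def test_penultimate_feature_width_is_fc_nodes(self):
        cfg = ClassifierConfig(seed=0)
        model = build_model(cfg)
        assert model.head.params["W"].shape == (512, 11)
        assert model.fc2.params["W"].shape == (512, 512)


class TestTrainAndEvaluate:
    def test_training_fits_separable_corpus(self, small_corpus):
        parts = split_corpus(small_corpus, SplitSpec(seed=0))
        cfg = ClassifierConfig(conv_widths=(8, 16, 24), fc_nodes=64, epochs=20, patience=20,
                               batch_size=8, dropout=0.0, augment_shift_segments=0, seed=0)
        model = build_model(cfg)
        report = train(model, parts, cfg)
        x_tr, y_tr = corpus_to_tensors(parts[0])
        assert (model.predict(x_tr) == y_tr).mean() >= 0.8  # optimization works
        assert report.overall_accuracy > 2 / 11  # generalizes above chance
        assert report.confusion.sum() == len(parts[2])
        assert report.split_sizes == (len(parts[0]), len(parts[1]), len(parts[2]))

    def test_same_seed_identical_reports(self, small_corpus):
        parts = split_corpus(small_corpus, SplitSpec(seed=0))
        reports = []
        for _ in range(2):
            model = build_model(TINY_CFG)
            reports.append(train(model, parts, TINY_CFG))
        assert np.array_equal(reports[0].confusion, reports[1].confusion)
        assert reports[0].train_loss == reports[1].train_loss

    def test_evaluate_requires_data(self, small_corpus):
        model = build_model(TINY_CFG)
        with pytest.raises(ValueError):
            evaluate(model, [])

    def test_evaluate_counts_match(self, small_corpus):
        model = build_model(TINY_CFG)
        report = evaluate(model, small_corpus[:22])
        assert report.confusion.sum() == 22


class TestReportArithmetic:
    def test_perfect_predictions_diagonal(self):
        y = np.arange(11)
        rep = _report_from_predictions(y, y, 11, (0, 0, 11))
        assert rep.overall_accuracy == 1.0
        assert np.array_equal(rep.confusion, np.eye(11, dtype=int))

    def test_single_class_predictor_one_column(self):
        y_true = np.array([0, 1, 2, 3])
        y_pred = np.zeros(4, dtype=int)
        rep = _report_from_predictions(y_true, y_pred, 11, (0, 0, 4))
        nonzero_cols = np.flatnonzero(rep.confusion.sum(axis=0))
        assert list(nonzero_cols) == [0]

    def test_two_of_three_correct(self):
        y_true = np.array([0, 1, 2])
        y_pred = np.array([0, 1, 1])
        rep = _report_from_predictions(y_true, y_pred, 11, (0, 0, 3))
        assert rep.overall_accuracy == pytest.approx(2 / 3)
        assert rep.per_class_accuracy["dry_swallow"] == 1.0
        assert rep.per_class_accuracy["water_10ml"] == 0.0

    def test_row_sums_equal_class_counts(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 11, 200)
        y_pred = rng.integers(0, 11, 200)
        rep = _report_from_predictions(y_true, y_pred, 11, (0, 0, 200))
        assert np.array_equal(rep.confusion.sum(axis=1), np.bincount(y_true, minlength=11))


class TestBaselineClassifier:
    def test_rms_logistic_separates_quiet_corpus(self, small_corpus):
        base = RmsLogisticBaseline(seed=0).fit(small_corpus)
        assert base.score(small_corpus) > 0.8  # amplitude/laterality features suffice

    def test_noise_degradation_monotone(self):
        """Raising baseline noise 10x must not improve classification."""
        accs = {}
        for rms_uv in (1.0, 10.0):
            noise = NoiseModel(baseline_rms=rms_uv, hum_amplitude=0.0, artifact_rate=0.0)
            corpus = simulate_corpus(2, 3, seed=2, noise=noise)
            tr, va, te = split_corpus(corpus, SplitSpec(seed=0))
            base = RmsLogisticBaseline(seed=0).fit(tr + va)
            accs[rms_uv] = base.score(te)
        assert accs[10.0] <= accs[1.0] + 0.10  # stochastic tolerance


class TestTensors:
    def test_corpus_to_tensors_shapes_and_labels(self, small_corpus):
        x, y = corpus_to_tensors(small_corpus[:5])
        assert x.shape == (5, 16, 31, 125)
        assert x.dtype == np.float32
        assert all(y[i] == LABEL_TO_INDEX[small_corpus[i].label] for i in range(5))
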
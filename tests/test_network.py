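"""Network mechanics: gradients, masking, decoding, ensembling, persistence."""

import numpy as np
import pytest

from mircleave import (
    CutSiteModel,
    ModelConfig,
    PredictionResult,
    call_cuts,
    encode,
    ensemble_predict,
    normalized_binary_predict,
    train_replicate,
)
from mircleave.encoding import LABEL_CLASSES, O_INDEX, vocab_size
from mircleave.network import PRESETS, _pad_batch, _pad_labels


def _tiny_cfg(**kw):
    base = dict(
        input_mode="seq_only", embedding_dim=4, dropout=0.0, lstm1_units=5,
        lstm2_units=3, learning_rate=1e-2, epsilon_exp=-7.0, batch_size=4,
        max_epochs=3, patience=5, seed=0, dtype="float64",
    )
    base.update(kw)
    return ModelConfig(**base)


class TestGradients:
    def test_analytic_gradients_match_numerical(self):
        """Finite-difference check of the full backward pass (both layers,
        ragged mask, float64)."""
        cfg = _tiny_cfg()
        model = CutSiteModel(cfg)
        rng = np.random.default_rng(0)
        toks = [rng.integers(1, vocab_size("seq_only"), size=n) for n in (7, 4, 6)]
        X, mask, _ = _pad_batch(toks, np.float64)
        Y = np.array(
            [rng.integers(0, 5, size=X.shape[1]) for _ in toks], dtype=np.int64
        )

        def loss_fn():
            probs, _ = model._forward(X, mask, training=False)
            p = np.take_along_axis(probs, Y[:, :, None], axis=2)[:, :, 0]
            return float(-(np.log(p) * mask).sum() / mask.sum())

        _, grads = model.loss_and_grads(X, mask, Y, drop_rng=rng)
        params = model.parameters()
        eps = 1e-6
        for name, arr in params.items():
            flat = arr.ravel()
            idxs = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_fn()
                flat[i] = orig - eps
                down = loss_fn()
                flat[i] = orig
                num = (up - down) / (2 * eps)
                ana = grads[name].ravel()[i]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-7), name


class TestForwardContracts:
    def test_rows_softmax_normalized_any_length(self):
        model = CutSiteModel(_tiny_cfg())
        rng = np.random.default_rng(1)
        for n in (3, 17, 41):
            toks = rng.integers(1, model.vocab, size=n)
            scores = model.predict_scores([toks])[0]
            assert scores.shape == (n, 5)
            np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_padding_never_changes_decision_values(self):
        model = CutSiteModel(_tiny_cfg())
        rng = np.random.default_rng(2)
        toks = [rng.integers(1, model.vocab, size=n) for n in (31, 9, 20, 14)]
        batched = model.predict_scores(toks)
        single = [model.predict_scores([t])[0] for t in toks]
        for b, s in zip(batched, single):
            np.testing.assert_allclose(b, s, atol=1e-10)

    def test_lstm2_zero_gives_single_recurrent_layer(self):
        model = CutSiteModel(_tiny_cfg(lstm2_units=0))
        assert len(model.layers) == 1

    def test_table_presets_build(self):
        for name, cfg in PRESETS.items():
            model = CutSiteModel(cfg)
            assert model.vocab == vocab_size(cfg.input_mode)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=0.6)
        with pytest.raises(ValueError):
            ModelConfig(input_mode="nope")


class TestDecoding:
    def test_leftmost_argmax_per_class(self):
        dv = np.full((4, 5), 0.1)
        dv[2, LABEL_CLASSES.index("DC3")] = 0.9
        cuts = call_cuts(dv)
        assert cuts["DC3"] == 2
        assert set(cuts) == {"DR5", "DC5", "DC3", "DR3"}

    def test_constant_column_ties_leftmost(self):
        dv = np.full((6, 5), 0.2)
        assert all(pos == 0 for pos in call_cuts(dv).values())

    def test_shift_equivariance_with_stub_scorer(self):
        """Shifting a shift-equivariant score matrix shifts all calls by k."""
        rng = np.random.default_rng(3)
        dv = rng.random((30, 5))
        base = call_cuts(dv)
        for k in (1, 5, 11):
            rolled = np.roll(dv, k, axis=0)
            shifted = call_cuts(rolled)
            for cls, pos in base.items():
                assert shifted[cls] == (pos + k) % 30

    def test_o_class_never_called(self):
        dv = np.zeros((5, 5))
        dv[:, O_INDEX] = 1.0
        assert "O" not in call_cuts(dv)


class TestNormalizedBinary:
    def test_forced_arithmetic(self):
        dv = np.zeros((3, 5))
        dv[:, 0] = [0.1, 0.4, 0.2]
        res = PredictionResult(dv, call_cuts(dv))
        pos = normalized_binary_predict(res, "DR5", threshold=0.5)
        # normalized [0.25, 1.0, 0.5]: only the max exceeds 0.5 strictly
        assert pos.tolist() == [False, True, False]

    def test_ties_all_positive(self):
        dv = np.zeros((2, 5))
        dv[:, 0] = [0.2, 0.2]
        res = PredictionResult(dv, call_cuts(dv))
        assert normalized_binary_predict(res, "DR5").tolist() == [True, True]

    def test_all_zero_rejected(self):
        res = PredictionResult(np.zeros((3, 5)), {})
        with pytest.raises(ValueError):
            normalized_binary_predict(res, "DR5")


def _labeled_examples(n, rng, length=40):
    from mircleave.encoding import LabeledExample

    out = []
    for i in range(n):
        toks = rng.integers(1, 6, size=length)
        labels = np.full(length, O_INDEX, dtype=np.int32)
        for j, cls in enumerate(("DR5", "DC5", "DC3", "DR3")):
            labels[5 + 8 * j] = j
        out.append(LabeledExample(toks.astype(np.int32), labels, f"x{i}"))
    return out


class TestTraining:
    def test_smoke_loss_decreases(self):
        rng = np.random.default_rng(4)
        train = _labeled_examples(50, rng)
        val = _labeled_examples(10, rng)
        cfg = _tiny_cfg(embedding_dim=8, lstm1_units=16, lstm2_units=0,
                        max_epochs=3, dtype="float32")
        model, hist = train_replicate(CutSiteModel(cfg), train, val, cfg)
        assert len(hist["loss"]) == 3
        assert hist["loss"][-1] < hist["loss"][0]

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(5)
        train = _labeled_examples(20, rng)
        val = _labeled_examples(5, rng)
        cfg = _tiny_cfg(max_epochs=2, dtype="float32", dropout=0.3)
        losses = []
        for _ in range(2):
            _, hist = train_replicate(CutSiteModel(cfg), train, val, cfg)
            losses.append(hist["val_loss"])
        assert losses[0] == losses[1]

    def test_empty_sets_rejected(self):
        cfg = _tiny_cfg()
        with pytest.raises(ValueError):
            train_replicate(CutSiteModel(cfg), [], [], cfg)


class TestEnsemble:
    def test_identical_members_equal_single(self):
        model = CutSiteModel(_tiny_cfg())
        rng = np.random.default_rng(6)
        from mircleave.encoding import LabeledExample

        ex = LabeledExample(rng.integers(1, 6, size=25).astype(np.int32), None, "e")
        single = model.predict(ex)
        ens = ensemble_predict([model, model], ex)
        np.testing.assert_allclose(ens.decision_values, single.decision_values, atol=1e-12)
        assert ens.called_cuts == single.called_cuts

    def test_mean_combination(self):
        a = np.array([[0.2], [0.8]])
        b = np.array([[0.6], [0.4]])
        mean = np.mean([a, b], axis=0)
        np.testing.assert_allclose(mean[:, 0], [0.4, 0.6])
        assert int(np.argmax(mean[:, 0])) == 1

    def test_mismatched_modes_rejected(self):
        m1 = CutSiteModel(_tiny_cfg())
        m2 = CutSiteModel(_tiny_cfg(input_mode="seq_bprna"))
        from mircleave.encoding import LabeledExample

        ex = LabeledExample(np.array([1, 2, 3], dtype=np.int32), None, "e")
        with pytest.raises(ValueError):
            ensemble_predict([m1, m2], ex)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, tiny_model, small_split):
        from mircleave.encoding import encode_dataset, structure_for

        tiny_model.save(tmp_path / "m")
        back = CutSiteModel.load(tmp_path / "m")
        recs = small_split.test[:3]
        exs = encode_dataset(
            recs, [structure_for(r, "seq_bprna") for r in recs], mode="seq_bprna"
        )
        for ex in exs:
            np.testing.assert_allclose(
                back.predict(ex).decision_values,
                tiny_model.predict(ex).decision_values,
                atol=1e-7,
            )

    def test_ensemble_manifest(self, tmp_path, tiny_model):
        from mircleave import load_ensemble, save_ensemble

        save_ensemble(tmp_path / "ens", [tiny_model, tiny_model])
        models = load_ensemble(tmp_path / "ens")
        assert len(models) == 2


class TestEncoding:
    def test_seq_only_tokens(self):
        from mircleave import ExtendedPrecursor

        rec = ExtendedPrecursor("r", "t", "ACGU", (0, 4))
        ex = encode(rec, None, mode="seq_only")
        assert len(ex.tokens) == 4
        assert vocab_size("seq_only") == 6
        assert all(1 <= t < 6 for t in ex.tokens)

    def test_joint_tokens_distinct(self):
        from mircleave import ExtendedPrecursor

        rec = ExtendedPrecursor("r", "t", "AC", (0, 2))
        ex = encode(rec, "LH", mode="seq_bprna")
        ex2 = encode(rec, "LL", mode="seq_bprna")
        assert ex.tokens[0] == ex2.tokens[0]
        assert ex.tokens[1] != ex2.tokens[1]

    def test_labels_follow_cut_convention(self):
        from mircleave import ExtendedPrecursor

        rec = ExtendedPrecursor(
            "r", "t", "ACGUACGUAC", (0, 10),
            cuts={"DR5": 1, "DC5": 3, "DC3": 5, "DR3": 8},
        )
        ex = encode(rec, None, mode="seq_only")
        assert ex.labels[3] == LABEL_CLASSES.index("DC5")
        assert (ex.labels == O_INDEX).sum() == 6

    def test_structure_length_mismatch(self):
        from mircleave import ExtendedPrecursor

        rec = ExtendedPrecursor("r", "t", "ACGU", (0, 4))
        with pytest.raises(ValueError):
            encode(rec, "LH", mode="seq_bprna")
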
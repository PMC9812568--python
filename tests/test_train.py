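"""Training loop: learnability, determinism, ablation semantics, checkpoints."""

import numpy as np
import pytest

from kgner import (
    EmptyCorpusError,
    EncoderConfig,
    Model,
    TrainConfig,
    build_model,
    entity_metrics,
    label_inventory,
    load_model,
    predict,
    save_model,
    token_accuracy,
    train,
)
from kgner.corpus import Corpus, Sentence
from kgner.train import _truncate

TINY_ENC = EncoderConfig(d=16, seed=0)


@pytest.fixture(scope="module")
def toy(small_bundle):
    """First 12 train / 6 dev sentences: enough to overfit quickly."""
    tr = Corpus.from_sentences(list(small_bundle.corpora["train"])[:12], split="train")
    dv = Corpus.from_sentences(list(small_bundle.corpora["dev"])[:6], split="dev")
    return tr, dv, small_bundle.kg


def quick_cfg(**kw):
    base = dict(epochs=8, batch_size=4, dropout=0.0, seed=0, learning_rate=1e-2)
    base.update(kw)
    return TrainConfig(**base)


class TestLabelInventory:
    def test_stable_order(self, small_bundle):
        inv = label_inventory(small_bundle.corpora["train"])
        assert inv[0] == "O"
        assert inv == ["O", "B-Disease", "I-Disease", "B-Drug", "I-Drug",
                       "B-Target", "I-Target"]


class TestTrainingDynamics:
    def test_overfits_toy_corpus_to_perfect_token_accuracy(self, toy):
        tr, dv, kg = toy
        cfg = quick_cfg(epochs=30)
        model, report = train(tr, dv, kg, cfg, encoder_cfg=TINY_ENC, K=2, d_h=8)
        pred = predict(model, list(tr), kg)
        assert token_accuracy([s.labels for s in tr], pred) == 1.0
        assert report.losses[-1] < report.losses[0]

    def test_loss_decreases_across_seeds(self, toy):
        tr, dv, kg = toy
        for seed in (0, 1, 2):
            cfg = quick_cfg(seed=seed, epochs=4)
            _, report = train(
                tr, dv, kg, cfg, encoder_cfg=EncoderConfig(d=16, seed=seed), K=2, d_h=8
            )
            assert report.losses[-1] < report.losses[0]

    def test_best_model_restored(self, toy):
        tr, dv, kg = toy
        cfg = quick_cfg(epochs=6)
        model, report = train(tr, dv, kg, cfg, encoder_cfg=TINY_ENC, K=2, d_h=8)
        pred = predict(model, list(dv), kg)
        f1 = entity_metrics([s.labels for s in dv], pred).f1
        assert f1 == pytest.approx(report.best_dev_f1)
        assert report.best_epoch == int(np.argmax([m.f1 for m in report.dev_metrics]))

    def test_empty_corpus_rejected(self, toy):
        _, dv, kg = toy
        empty = Corpus.from_sentences([], split="train")
        with pytest.raises(EmptyCorpusError):
            train(empty, dv, kg, quick_cfg())


class TestDeterminism:
    def test_same_seed_same_run(self, toy):
        tr, dv, kg = toy
        cfg = quick_cfg(epochs=3, dropout=0.2)
        m1, r1 = train(tr, dv, kg, cfg, encoder_cfg=TINY_ENC, K=2, d_h=8)
        m2, r2 = train(tr, dv, kg, cfg, encoder_cfg=TINY_ENC, K=2, d_h=8)
        assert r1.losses == r2.losses
        for k, v in m1.parameters().items():
            assert np.array_equal(v, m2.parameters()[k]), k
        assert predict(m1, list(dv), kg) == predict(m2, list(dv), kg)

    def test_different_seed_different_run(self, toy):
        tr, dv, kg = toy
        m1, r1 = train(tr, dv, kg, quick_cfg(epochs=2, seed=0),
                       encoder_cfg=EncoderConfig(d=16, seed=0), K=2, d_h=8)
        _, r2 = train(tr, dv, kg, quick_cfg(epochs=2, seed=1),
                      encoder_cfg=EncoderConfig(d=16, seed=1), K=2, d_h=8)
        assert r1.losses != r2.losses


class TestAblationSemantics:
    def test_none_equals_relation_with_frozen_w2(self, toy):
        """Disabling the knowledge path and freezing w2 at zero coincide."""
        tr, dv, kg = toy
        m1, r1 = train(tr, dv, kg, quick_cfg(epochs=3, ablation="none"),
                       encoder_cfg=TINY_ENC, K=2, d_h=8)
        m2, r2 = train(tr, dv, kg, quick_cfg(epochs=3, ablation="relation", freeze_w2=True),
                       encoder_cfg=TINY_ENC, K=2, d_h=8)
        assert r1.losses == pytest.approx(r2.losses, abs=1e-9)
        assert predict(m1, list(dv), kg) == predict(m2, list(dv), kg)

    def test_no_kg_equals_ablation_none(self, toy):
        """With no KG at all, the relation model degenerates to none."""
        tr, dv, kg = toy
        cfg = quick_cfg(epochs=2, ablation="relation")
        m1, r1 = train(tr, dv, None, cfg, encoder_cfg=TINY_ENC, K=2, d_h=8)
        m2, r2 = train(tr, dv, kg, quick_cfg(epochs=2, ablation="none"),
                       encoder_cfg=TINY_ENC, K=2, d_h=8)
        # the knowledge path is inert in both runs (Ht = 0 without matches),
        # so the training traces coincide; vocabularies differ (m2's encoder
        # also covers KG surfaces), so comparison is on train-covered tokens
        assert r1.losses == pytest.approx(r2.losses, abs=1e-9)
        assert predict(m1, list(tr), None) == predict(m2, list(tr), kg)

    def test_concept_mode_uses_identity_adjacency(self, toy):
        tr, _, kg = toy
        from kgner.train import _prepare_sentence

        model = build_model(tr, kg, encoder_cfg=TINY_ENC, K=2, d_h=8, ablation="concept")
        seen = 0
        for s in tr:
            prep = _prepare_sentence(model, s, kg)
            if prep.graph is not None and len(prep.graph.node_ids) > 1:
                m = len(prep.graph.node_ids)
                assert np.array_equal(prep.graph.adjacency, np.eye(m, dtype=np.int8))
                seen += 1
        assert seen > 0


class TestPrediction:
    def test_predictions_always_legal_bio(self, toy):
        tr, dv, kg = toy
        model, _ = train(tr, dv, kg, quick_cfg(epochs=1), encoder_cfg=TINY_ENC, K=2, d_h=8)
        from kgner import validate_bio

        for labs in predict(model, list(dv), kg):
            assert validate_bio(labs) == labs

    def test_prediction_independent_of_batching(self, toy):
        tr, dv, kg = toy
        model, _ = train(tr, dv, kg, quick_cfg(epochs=1), encoder_cfg=TINY_ENC, K=2, d_h=8)
        whole = predict(model, list(dv), kg)
        single = [predict(model, [s], kg)[0] for s in dv]
        assert whole == single


class TestTruncation:
    def test_short_sentence_untouched(self):
        s = Sentence(["a", "b"], ["O", "O"])
        out, truncated = _truncate(s, 5)
        assert out is s and not truncated

    def test_span_crossing_boundary_dropped(self):
        s = Sentence(["a", "b", "c", "d"], ["O", "O", "B-X", "I-X"])
        out, truncated = _truncate(s, 3)
        assert truncated
        assert out.tokens == ["a", "b", "c"]
        assert out.labels == ["O", "O", "O"]

    def test_span_inside_boundary_kept(self):
        s = Sentence(["a", "b", "c", "d"], ["B-X", "I-X", "O", "O"])
        out, _ = _truncate(s, 3)
        assert out.labels == ["B-X", "I-X", "O"]

    def test_counted_in_report(self, toy):
        tr, dv, kg = toy
        cfg = quick_cfg(epochs=1, max_len=9)
        _, report = train(tr, dv, kg, cfg, encoder_cfg=TINY_ENC, K=2, d_h=8)
        expected = sum(1 for s in tr if len(s) > 9)
        assert report.n_truncated == expected > 0


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, toy, tmp_path):
        tr, dv, kg = toy
        model, _ = train(tr, dv, kg, quick_cfg(epochs=2), encoder_cfg=TINY_ENC, K=2, d_h=8)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert isinstance(loaded, Model)
        for k, v in model.parameters().items():
            assert np.array_equal(v, loaded.parameters()[k]), k
        assert predict(model, list(dv), kg) == predict(loaded, list(dv), kg)

    def test_version_check(self, toy, tmp_path):
        tr, dv, kg = toy
        model = build_model(tr, kg, encoder_cfg=TINY_ENC, K=2, d_h=8)
        path = tmp_path / "model.npz"
        save_model(model, path)
        import json

        data = dict(np.load(path))
        meta = json.loads(bytes(data["meta"]).decode())
        meta["version"] = 99
        data["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **data)
        with pytest.raises(ValueError, match="version"):
            load_model(path)
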
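"""Training loops: LR schedule, determinism, checkpoints, fine-tuning."""

import numpy as np
import pytest

from cmixup import (
    AugmentConfig,
    CurriculumConfig,
    FinetuneConfig,
    PretrainConfig,
    build_model,
    cosine_lr,
    embedding_std,
    evaluate,
    finetune,
    load_checkpoint,
    pretrain,
    save_checkpoint,
)

from conftest import TINY_ENCODER

FAST_AUG = AugmentConfig(resize_to=32, crop=False, apply_affine_p=0.0)


def _pretrain_cfg(epochs=2, seed=5):
    return PretrainConfig(
        epochs=epochs, batch_size=32, curriculum=CurriculumConfig(total_steps=epochs),
        augment=FAST_AUG, encoder=TINY_ENCODER, seed=seed,
    )


def test_cosine_lr_endpoints_and_midpoint():
    assert cosine_lr(0.01, 0, 100) == pytest.approx(0.01)
    assert cosine_lr(0.01, 100, 100) == pytest.approx(0.0)
    assert cosine_lr(0.01, 50, 100) == pytest.approx(0.005)
    with pytest.raises(ValueError):
        cosine_lr(0.01, 101, 100)


def test_pretrain_is_bit_deterministic(small_corpus):
    pool, _ = small_corpus
    pool = pool[:48]
    cfg = _pretrain_cfg()
    runs = []
    for _ in range(2):
        model = build_model(TINY_ENCODER, np.random.default_rng(1))
        _, losses, alphas, lams = pretrain(pool, model, cfg)
        runs.append((losses, alphas, lams))
    assert runs[0][0] == runs[1][0]  # loss trace identical to the bit
    assert runs[0][1] == runs[1][1]
    assert runs[0][2] == runs[1][2]  # λ draws identical


def test_pretrain_traces_have_expected_lengths(small_corpus):
    pool, _ = small_corpus
    pool = pool[:48]
    cfg = _pretrain_cfg(epochs=3)
    model = build_model(TINY_ENCODER, np.random.default_rng(2))
    _, losses, alphas, lams = pretrain(pool, model, cfg)
    assert len(losses) == 3 and len(alphas) == 3
    assert len(lams) == 3 * 2  # two batches of 32 per epoch
    assert all(np.isfinite(v) for v in losses)
    assert all(0.0 <= l <= 0.5 for l in lams)


def test_pretrain_rejects_empty_pool():
    model = build_model(TINY_ENCODER, np.random.default_rng(0))
    with pytest.raises(ValueError):
        pretrain([], model, _pretrain_cfg())


def test_degenerate_curriculum_keeps_lambda_near_zero(small_corpus):
    """With α pinned at ~0 the Beta draws collapse onto {0, 1}; after the
    0.5-cap almost every λ is ≈ 0, so the mixed view is the plain second view
    and the run degenerates to vanilla siamese training."""
    pool, _ = small_corpus
    pool = pool[:48]
    cfg = _pretrain_cfg(epochs=2)
    cfg.curriculum = CurriculumConfig(alpha_max=1e-6, alpha_min=1e-6,
                                      scheduler="constant", total_steps=2)
    model = build_model(TINY_ENCODER, np.random.default_rng(3))
    _, _, _, lams = pretrain(pool, model, cfg)
    lams = np.array(lams)
    assert np.all((lams < 1e-9) | (lams == 0.5))


def test_checkpoint_roundtrip_preserves_outputs(tmp_path, small_corpus, tiny_model):
    pool, _ = small_corpus
    from cmixup.nn import Tensor

    x = np.stack(pool[:4])
    tiny_model.eval()
    before = tiny_model.project(Tensor(x)).data
    path = save_checkpoint(tmp_path / "ckpt.npz", tiny_model,
                           config={"note": "test"}, traces={"loss": [0.1]})
    fresh = build_model(TINY_ENCODER, np.random.default_rng(999))
    load_checkpoint(path, fresh)
    fresh.eval()
    after = fresh.project(Tensor(x)).data
    np.testing.assert_array_equal(before, after)
    assert path.with_suffix(".json").exists()


def test_finetune_zero_epochs_leaves_head_at_init(small_corpus, tiny_model):
    _, labeled = small_corpus
    cfg = FinetuneConfig(epochs=0, batch_size=16, mode="full_finetune", seed=0)
    classifier, history = finetune(tiny_model, labeled[:20], cfg, n_classes=4)
    assert history["loss"] == [] and history["train_accuracy"] == []
    preds = classifier.predict([x for x, _ in labeled[:8]])
    assert preds.shape == (8,)


def test_finetune_rejects_out_of_range_labels(tiny_model):
    bad = [(np.zeros((3, 32, 32)), 7)]
    with pytest.raises(ValueError):
        finetune(tiny_model, bad, FinetuneConfig(epochs=1), n_classes=4)


def test_full_finetune_learns_the_synthetic_task(small_corpus, tiny_model):
    _, labeled = small_corpus
    cfg = FinetuneConfig(epochs=8, batch_size=16, lr=0.05, mode="full_finetune",
                         seed=1)
    classifier, history = finetune(tiny_model, labeled, cfg, n_classes=4)
    assert history["loss"][-1] < history["loss"][0]
    assert history["train_accuracy"][-1] > 0.5  # chance is 0.25


def test_linear_probe_history_and_determinism(small_corpus, tiny_model):
    _, labeled = small_corpus
    cfg = FinetuneConfig(epochs=5, batch_size=16, mode="linear_probe", seed=2)
    c1, h1 = finetune(tiny_model, labeled, cfg, n_classes=4)
    c2, h2 = finetune(tiny_model, labeled, cfg, n_classes=4)
    assert h1 == h2
    imgs = [x for x, _ in labeled[:10]]
    np.testing.assert_array_equal(c1.predict(imgs), c2.predict(imgs))


def test_embedding_std_positive_for_untrained_model(small_corpus, tiny_model):
    pool, _ = small_corpus
    assert embedding_std(tiny_model, pool[:32]) > 0.0


def test_evaluation_consistent_with_returned_confusion(small_corpus, tiny_model):
    from cmixup.evaluation import metrics

    _, labeled = small_corpus
    cfg = FinetuneConfig(epochs=3, batch_size=16, mode="linear_probe", seed=3)
    classifier, _ = finetune(tiny_model, labeled[:40], cfg, n_classes=4)
    cm, report = evaluate(classifier, labeled[40:])
    recomputed = metrics(cm)
    assert report.accuracy == recomputed.accuracy
    assert report.f1 == recomputed.f1
    assert cm.sum() == len(labeled[40:])
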
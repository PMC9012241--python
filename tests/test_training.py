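"""Masked-LM corruption, losses, learning-rate schedules, and metrics."""

import numpy as np
import pytest

from dattprot.autograd import Tensor
from dattprot.nn import Linear
from dattprot.sequence_codec import TokenSequence, Vocabulary
from dattprot.training import (FinetuneConfig, PretrainConfig, SkipRecord,
                               evaluate, finetune_lr, mlm_corrupt, mlm_loss,
                               pretrain_lr)


def make_seq(vocab, n_real, l, with_mask_tokens=0):
    rng = np.random.default_rng(n_real * l + 1)
    ids = np.full(l, vocab.pad_id, dtype=np.int64)
    ids[:n_real] = rng.integers(0, vocab.n_residues, n_real)
    if with_mask_tokens:
        ids[:with_mask_tokens] = vocab.mask_id
    mask = np.zeros(l, bool)
    mask[:n_real] = True
    return TokenSequence(ids=ids, mask=mask, raw_length=n_real)


class TestMLMCorrupt:
    def test_fifteen_percent_of_eligible_selected(self, vocab, rng):
        seq = make_seq(vocab, 100, 120)
        _, tgt = mlm_corrupt(seq, PretrainConfig(), rng, vocab)
        assert len(tgt) == 15

    def test_short_sequence_gets_at_least_one_target(self, vocab, rng):
        seq = make_seq(vocab, 3, 8)
        _, tgt = mlm_corrupt(seq, PretrainConfig(), rng, vocab)
        assert len(tgt) == 1

    def test_all_pad_raises_skip_signal(self, vocab, rng):
        seq = make_seq(vocab, 0, 8)
        with pytest.raises(SkipRecord):
            mlm_corrupt(seq, PretrainConfig(), rng, vocab)

    def test_unknown_tokens_ineligible(self, vocab, rng):
        # all real positions were X (MASK) in the raw input
        seq = make_seq(vocab, 4, 8, with_mask_tokens=4)
        with pytest.raises(SkipRecord):
            mlm_corrupt(seq, PretrainConfig(), rng, vocab)

    def test_action_proportions_match_80_10_10(self, vocab):
        rng = np.random.default_rng(99)
        cfg = PretrainConfig()
        seq = make_seq(vocab, 100, 100)
        n_mask = n_rand = n_keep = 0
        total = 0
        while total < 10_000:
            corrupted, tgt = mlm_corrupt(seq, cfg, rng, vocab)
            for pos, orig in zip(tgt.positions, tgt.original_ids):
                new = corrupted.ids[pos]
                if new == vocab.mask_id:
                    n_mask += 1
                elif new == orig:
                    n_keep += 1
                else:
                    n_rand += 1
            total += len(tgt)
        assert 0.78 <= n_mask / total <= 0.82
        # a replacement draw may coincide with the original token (1/22 chance),
        # so observed changed-token fraction centers on 0.1 * 21/22 ~ 0.0955
        assert 0.085 <= n_rand / total <= 0.115

    def test_never_selects_pad_or_unknown_positions(self, vocab):
        rng = np.random.default_rng(5)
        for trial in range(200):
            n_real = int(rng.integers(2, 30))
            n_unknown = int(rng.integers(0, n_real))
            seq = make_seq(vocab, n_real, 32, with_mask_tokens=n_unknown)
            if n_unknown == n_real:
                continue
            _, tgt = mlm_corrupt(seq, PretrainConfig(), rng, vocab)
            assert (tgt.positions >= n_unknown).all()
            assert (tgt.positions < n_real).all()

    def test_targets_record_original_ids(self, vocab, rng):
        seq = make_seq(vocab, 50, 64)
        corrupted, tgt = mlm_corrupt(seq, PretrainConfig(), rng, vocab)
        assert np.array_equal(tgt.original_ids, seq.ids[tgt.positions])
        untouched = np.setdiff1d(np.arange(50), tgt.positions)
        assert np.array_equal(corrupted.ids[untouched], seq.ids[untouched])


class TestMLMLoss:
    def test_uniform_decoder_gives_log_22(self, vocab, rng):
        from dattprot.training import MLMTargets
        dec = Linear(8, vocab.n_residues, rng)
        dec.W.data[:] = 0.0
        dec.b.data[:] = 0.0
        F = rng.normal(size=(10, 8))
        tgt = MLMTargets(positions=np.arange(5),
                         original_ids=rng.integers(0, 22, 5))
        loss = mlm_loss(F, tgt, dec)
        assert np.isclose(float(loss.data), np.log(22), atol=1e-10)

    def test_confident_correct_decoder_approaches_zero(self, vocab, rng):
        from dattprot.training import MLMTargets
        dec = Linear(4, vocab.n_residues, rng)
        dec.W.data[:] = 0.0
        dec.b.data[:] = -1000.0
        dec.b.data[3] = 1000.0
        F = rng.normal(size=(6, 4))
        tgt = MLMTargets(positions=np.arange(3), original_ids=np.full(3, 3))
        assert float(mlm_loss(F, tgt, dec).data) < 1e-8

    def test_matches_hand_computed_cross_entropy(self, vocab, rng):
        from dattprot.training import MLMTargets
        dec = Linear(4, vocab.n_residues, rng)
        F = rng.normal(size=(7, 4))
        tgt = MLMTargets(positions=np.array([1, 4]),
                         original_ids=np.array([0, 9]))
        loss = float(mlm_loss(F, tgt, dec).data)
        total = 0.0
        for pos, lab in [(1, 0), (4, 9)]:
            z = F[pos] @ dec.W.data + dec.b.data
            total -= (z[lab] - np.log(np.exp(z - z.max()).sum()) - z.max())
        assert np.isclose(loss, total / 2, atol=1e-7)

    def test_empty_targets_rejected(self, vocab, rng):
        from dattprot.training import MLMTargets
        dec = Linear(4, vocab.n_residues, rng)
        with pytest.raises(ValueError):
            mlm_loss(rng.normal(size=(3, 4)),
                     MLMTargets(np.array([], int), np.array([], int)), dec)


class TestSchedules:
    def test_six_layer_peak_at_warmup_boundary(self):
        cfg = PretrainConfig(peak_lr=5e-5, warmup_steps=50_000)
        assert np.isclose(pretrain_lr(50_000, cfg), 5e-5)

    def test_three_layer_peak(self):
        cfg = PretrainConfig(peak_lr=1e-4, warmup_steps=50_000)
        assert np.isclose(pretrain_lr(50_000, cfg), 1e-4)

    def test_zero_step_rate_is_zero(self):
        assert pretrain_lr(0, PretrainConfig()) == 0.0

    def test_continuous_at_warmup_and_nonnegative(self):
        cfg = PretrainConfig(peak_lr=1e-3, warmup_steps=100)
        before = pretrain_lr(99, cfg)
        at = pretrain_lr(100, cfg)
        after = pretrain_lr(101, cfg)
        assert before < at and np.isclose(at, 1e-3)
        assert np.isclose(after, at * np.sqrt(100 / 101))  # no jump, smooth decay
        steps = np.arange(0, 1000, 7)
        assert all(pretrain_lr(int(s), cfg) >= 0 for s in steps)

    @pytest.mark.parametrize("iteration,expected", [
        (0, 1e-5), (99, 1e-5), (100, 9.5e-6), (250, 9.025e-6),
    ])
    def test_finetune_decay_closed_form(self, iteration, expected):
        assert np.isclose(finetune_lr(iteration, FinetuneConfig()), expected,
                          rtol=1e-12)


class TestTrainingLoop:
    def test_one_adamw_step_descends_convex_toy(self, rng):
        from dattprot.optim import AdamW
        w = Tensor(np.array([3.0, -2.0]), requires_grad=True)
        w.requires_grad = True
        loss0 = float(((w - 1.0) ** 2).sum().data)
        opt = AdamW([w], lr=0.1)
        loss = ((w - 1.0) ** 2).sum()
        loss.backward()
        opt.step()
        loss1 = float(((Tensor(w.data) - 1.0) ** 2).sum().data)
        assert loss1 < loss0

    def test_identical_seeds_give_identical_loss_traces(self):
        from dattprot.estimators import DAttProtClassifier
        X = ["ACDEFGHIKLMNPQRSTVWY" * 2] * 6 + ["WYWYWYWYWYWYWYWYWYWY"] * 6
        y = [0] * 6 + [1] * 6
        traces = []
        for _ in range(2):
            clf = DAttProtClassifier(l=16, f=8, n_layers=1, h=2,
                                     kernel_sizes=(3,), channel_mult=2,
                                     max_epochs=2, batch_size=4,
                                     initial_lr=1e-3, random_state=7)
            clf.fit(X, y)
            traces.append(clf.history_["train_loss"])
        assert traces[0] == traces[1]

    def test_nonfinite_loss_aborts_with_diagnostic(self, rng):
        from dattprot.model import DAttProtModel, ModelConfig
        from dattprot.training import finetune
        m = DAttProtModel(ModelConfig(l=8, f=8, n_layers=1, h=2,
                                      kernel_sizes=(3,), n_classes=2), rng)
        m.head.linear.b.data[:] = np.nan
        ids = rng.integers(0, 22, size=(4, 8))
        mask = np.ones((4, 8), bool)
        with pytest.raises(FloatingPointError):
            finetune(m, ids, mask, np.array([0, 1, 0, 1]),
                     FinetuneConfig(max_epochs=1, batch_size=4), rng)


class TestEvaluate:
    def test_perfect_predictions(self):
        r = evaluate([0, 1, 2, 1], [0, 1, 2, 1])
        assert r.accuracy == 1.0 and r.macro_f1 == 1.0

    def test_constant_predictor_on_balanced_binary(self):
        labels = [0] * 50 + [1] * 50
        r = evaluate([0] * 100, labels)
        assert np.isclose(r.accuracy, 0.5)
        # class 0: P=0.5, R=1 -> F1=2/3; class 1: F1=0
        assert np.isclose(r.macro_f1, (2 / 3 + 0) / 2)

    def test_three_class_confusion_counts(self):
        # confusion [[5,0,0],[0,4,1],[0,2,3]] row=truth col=prediction
        truth = [0] * 5 + [1] * 5 + [2] * 5
        pred = [0] * 5 + [1] * 4 + [2] + [1] * 2 + [2] * 3
        r = evaluate(pred, truth)
        assert np.isclose(r.accuracy, 12 / 15)
        assert r.macro_f1 <= max(r.f1.values()) + 1e-12

    def test_empty_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])
        with pytest.raises(ValueError):
            evaluate([1, 2], [1])
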
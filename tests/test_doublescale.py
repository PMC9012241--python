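"""Multi-scale features, feature agreement, and the double-scale attention matrix."""

import numpy as np
import pytest

from dattprot.autograd import Tensor
from dattprot.doublescale_core import (MultiScaleExtractor, ScaleSet,
                                       agreement_scores, attention_matrix,
                                       central_vectors, extract_scale_features,
                                       mix_features)
from dattprot.nn import Conv1dSame


def as_t(arrs):
    return [Tensor(a) for a in arrs]


class TestScaleSet:
    def test_default_kernels(self):
        assert ScaleSet().kernel_sizes == (5, 10, 20)

    @pytest.mark.parametrize("bad", [(), (0, 3), (5, 5), (10, 5)])
    def test_invalid_sets_rejected(self, bad):
        with pytest.raises(ValueError):
            ScaleSet(bad)

    @pytest.mark.parametrize("length,expected", [
        (5, 5), (9, 10), (7, 5),    # |7-5| = 2 < |7-10| = 3
        (15, 10),                    # tie |15-10| = |15-20| -> smaller kernel
        (19, 20), (25, 20),
    ])
    def test_closest_kernel_with_smaller_tie_break(self, length, expected):
        assert ScaleSet((5, 10, 20)).closest(length) == expected


class TestConvolution:
    def test_ones_kernel_size3_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(0)
        conv = Conv1dSame(1, 1, 3, rng)
        conv.W.data[:] = 1.0
        conv.b.data[:] = 0.0
        x = np.ones((1, 8, 1))
        out = conv(Tensor(x)).data[0, :, 0]
        # interior rows: window sum 3 scaled by 1/sqrt(3)
        assert np.allclose(out[1:-1], 3 / np.sqrt(3))
        # boundary rows see one zero pad: sum 2
        assert np.allclose(out[[0, -1]], 2 / np.sqrt(3))

    def test_random_kernel_matches_naive_convolution(self, rng):
        f, C, S, l = 3, 4, 5, 12
        conv = Conv1dSame(f, C, S, rng)
        x = rng.normal(size=(1, l, f))
        out = conv(Tensor(x)).data[0]
        W = conv.W.data.reshape(S, f, C)
        left = (S - 1 + 1) // 2
        xp = np.vstack([np.zeros((left, f)), x[0], np.zeros((S - 1 - left, f))])
        for j in range(l):
            acc = sum(xp[j + s] @ W[s] for s in range(S)) + conv.b.data
            assert np.allclose(out[j], acc / np.sqrt(S), atol=1e-10)

    def test_even_kernel_uses_left_of_center_window(self, rng):
        conv = Conv1dSame(1, 1, 4, rng)
        conv.W.data[:] = 0.0
        conv.b.data[:] = 0.0
        # weight only the first tap: output j reads input j - ceil(3/2) = j - 2
        conv.W.data[0, 0] = 1.0
        x = np.arange(1.0, 9.0).reshape(1, 8, 1)
        out = conv(Tensor(x)).data[0, :, 0] * np.sqrt(4)
        assert np.allclose(out[2:], x[0, :6, 0])
        assert np.allclose(out[:2], 0.0)

    def test_kernel_larger_than_sequence_rejected(self, rng):
        conv = Conv1dSame(2, 2, 9, rng)
        with pytest.raises(ValueError):
            conv(Tensor(np.zeros((1, 5, 2))))

    def test_extractor_output_shapes_and_channel_counts(self, rng):
        f, l = 8, 32
        scales = ScaleSet((5, 10, 20))
        ext = MultiScaleExtractor(f, scales, rng, channel_mult=16)
        assert [c.channels for c in ext.convs] == [80, 160, 320]
        maps = extract_scale_features(rng.normal(size=(l, f)), scales, ext)
        assert all(m.shape == (l, f) for m in maps)

    def test_pad_centered_rows_zeroed(self, rng):
        f, l = 4, 16
        scales = ScaleSet((3, 5))
        ext = MultiScaleExtractor(f, scales, rng)
        mask = np.ones(l, bool)
        mask[10:] = False
        maps = extract_scale_features(rng.normal(size=(l, f)), scales, ext, mask)
        for m in maps:
            assert np.allclose(m[10:], 0.0)


class TestCentralVectors:
    def test_identical_vectors_average_to_themselves(self):
        u = np.array([[1.0, 2.0, 3.0]])
        out = central_vectors(Tensor(u[None]), as_t([u[None]] * 3)).data
        assert np.allclose(out, u)

    def test_two_vector_arithmetic_mean(self):
        g = np.array([[[1.0, 0.0]]])
        s = np.array([[[0.0, 1.0]]])
        out = central_vectors(Tensor(g), as_t([s])).data
        assert np.allclose(out, [[[0.5, 0.5]]])

    def test_matches_explicit_loop_oracle(self, rng):
        N, l, f = 3, 6, 4
        g = rng.normal(size=(1, l, f))
        maps = [rng.normal(size=(1, l, f)) for _ in range(N)]
        out = central_vectors(Tensor(g), as_t(maps)).data[0]
        for j in range(l):
            expected = (g[0, j] + sum(m[0, j] for m in maps)) / (N + 1)
            assert np.allclose(out[j], expected, atol=1e-7)

    def test_ablation_without_global_changes_scores(self, rng):
        g = Tensor(rng.normal(size=(1, 5, 4)))
        maps = as_t([rng.normal(size=(1, 5, 4)) for _ in range(2)])
        a_with = agreement_scores(maps, central_vectors(g, maps, True)).data
        a_without = agreement_scores(maps, central_vectors(g, maps, False)).data
        assert not np.allclose(a_with, a_without)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            central_vectors(Tensor(np.zeros((1, 4, 2))),
                            as_t([np.zeros((1, 5, 2))]))


class TestAgreement:
    def test_self_agreement_is_squared_norm_over_sqrt_f(self):
        u = np.array([[[1.0, 2.0, 2.0, 0.0]]])
        A = agreement_scores(as_t([u]), Tensor(u)).data
        assert np.allclose(A, 9.0 / 2.0)  # ||u||^2 / sqrt(4)

    def test_orthogonal_vectors_score_zero(self):
        a = np.array([[[1.0, 0.0]]])
        b = np.array([[[0.0, 1.0]]])
        assert np.allclose(agreement_scores(as_t([a]), Tensor(b)).data, 0.0)

    def test_dim_divisor_option(self):
        u = np.array([[[2.0, 0.0, 0.0, 0.0]]])
        assert np.allclose(agreement_scores(as_t([u]), Tensor(u), "dim").data, 1.0)

    def test_matches_loop_oracle(self, rng):
        N, l, f = 3, 6, 4
        maps = [rng.normal(size=(1, l, f)) for _ in range(N)]
        cent = rng.normal(size=(1, l, f))
        A = agreement_scores(as_t(maps), Tensor(cent)).data[0]
        for k in range(N):
            for j in range(l):
                assert np.isclose(A[k, j], maps[k][0, j] @ cent[0, j] / 2.0,
                                  atol=1e-7)


class TestAttentionMatrix:
    def test_constant_scores_give_uniform_joint(self):
        A = Tensor(np.full((1, 3, 10), 0.7))
        W, v = attention_matrix(A, np.ones((1, 10), bool))
        assert np.allclose(W.data, 1 / 30, atol=1e-12)
        assert np.allclose(v.data, 3 / 30, atol=1e-12)

    def test_joint_and_margin_normalized(self, rng):
        A = Tensor(rng.normal(size=(4, 3, 8)) * 5)
        mask = np.ones((4, 8), bool)
        mask[2, 5:] = False
        W, v = attention_matrix(A, mask)
        assert np.allclose(W.data.sum(axis=(1, 2)), 1.0, atol=1e-6)
        assert np.allclose(v.data.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(v.data, W.data.sum(axis=1), atol=1e-12)

    def test_pad_columns_carry_no_mass(self, rng):
        A = Tensor(rng.normal(size=(1, 2, 10)) * 10)
        mask = np.ones((1, 10), bool)
        mask[0, 7:] = False
        W, v = attention_matrix(A, mask)
        assert W.data[0, :, 7:].sum() < 1e-8
        assert v.data[0, 7:].sum() < 1e-8

    def test_all_pad_rejected(self):
        with pytest.raises(ValueError):
            attention_matrix(Tensor(np.zeros((1, 2, 4))), np.zeros((1, 4), bool))


class TestMixing:
    def test_single_scale_mixture_is_identity(self, rng):
        m = rng.normal(size=(1, 6, 3))
        A = Tensor(rng.normal(size=(1, 1, 6)))
        mask = np.ones((1, 6), bool)
        W, v = attention_matrix(A, mask)
        out = mix_features(W, v, as_t([m]), mask).data
        assert np.allclose(out, m, atol=1e-9)

    def test_equal_weights_give_scale_mean(self):
        maps = [np.full((1, 4, 2), 1.0), np.full((1, 4, 2), 3.0)]
        A = Tensor(np.zeros((1, 2, 4)))
        mask = np.ones((1, 4), bool)
        W, v = attention_matrix(A, mask)
        out = mix_features(W, v, as_t(maps), mask).data
        assert np.allclose(out, 2.0, atol=1e-9)

    def test_matches_conditional_weight_loop_oracle(self, rng):
        N, l, f = 3, 7, 4
        maps = [rng.normal(size=(1, l, f)) for _ in range(N)]
        A = Tensor(rng.normal(size=(1, N, l)))
        mask = np.ones((1, l), bool)
        W, v = attention_matrix(A, mask)
        out = mix_features(W, v, as_t(maps), mask).data[0]
        for j in range(l):
            expected = sum(W.data[0, k, j] / v.data[0, j] * maps[k][0, j]
                           for k in range(N))
            assert np.allclose(out[j], expected, atol=1e-7)

    def test_conditional_weights_normalize_per_position(self, rng):
        A = Tensor(rng.normal(size=(2, 3, 9)))
        mask = np.ones((2, 9), bool)
        mask[1, 6:] = False
        W, v = attention_matrix(A, mask)
        cond = W.data / (v.data[:, None, :] + 1e-12)
        assert np.allclose(cond[0].sum(axis=0), 1.0, atol=1e-6)
        assert np.allclose(cond[1, :, :6].sum(axis=0), 1.0, atol=1e-6)

    def test_mixture_row_norm_bounded_by_largest_scale_row(self, rng):
        N, l, f = 3, 5, 4
        maps = [rng.normal(size=(1, l, f)) for _ in range(N)]
        A = Tensor(rng.normal(size=(1, N, l)))
        mask = np.ones((1, l), bool)
        W, v = attention_matrix(A, mask)
        out = mix_features(W, v, as_t(maps), mask).data[0]
        for j in range(l):
            assert np.linalg.norm(out[j]) <= max(
                np.linalg.norm(m[0, j]) for m in maps) + 1e-9


def test_scale_permutation_equivariance(rng):
    """Permuting scale order permutes A and W rows and leaves F_mixed unchanged."""
    N, l, f = 3, 8, 4
    maps = [rng.normal(size=(1, l, f)) for _ in range(N)]
    g = rng.normal(size=(1, l, f))
    mask = np.ones((1, l), bool)
    perm = [2, 0, 1]

    def run(ms):
        cent = central_vectors(Tensor(g), as_t(ms))
        A = agreement_scores(as_t(ms), cent)
        W, v = attention_matrix(A, mask)
        return A.data, W.data, mix_features(W, v, as_t(ms), mask).data

    A1, W1, F1 = run(maps)
    A2, W2, F2 = run([maps[i] for i in perm])
    assert np.allclose(A2, A1[:, perm])
    assert np.allclose(W2, W1[:, perm])
    assert np.allclose(F2, F1, atol=1e-9)
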
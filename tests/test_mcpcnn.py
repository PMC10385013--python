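import numpy as np
import pytest
from scipy import stats

from ddigauss import autodiff as ad
from ddigauss.candidates import (
    encode_positions,
    generate_candidates,
    pad_or_truncate,
)
from ddigauss.embeddings import EmbeddingTable, build_channel_set, embed_batch
from ddigauss.mcpcnn import (
    MCPCNN,
    ClassifierParams,
    ConvFilterBank,
    NoiseConfig,
    attention_weights,
    classify,
    convolve,
    gaussian_noise,
    mcpcnn_forward,
    piecewise_max_pool,
    truncated_normal_moments,
)
from ddigauss.candidates import PAD_TOKEN

from conftest import make_sentence


class TestConvolve:
    def test_feature_map_length_is_n_minus_h_plus_1(self, rng):
        seq = rng.normal(size=(1, 6, 4))
        bank = ConvFilterBank.create(width=4, n_channels=1,
                                     window_sizes=(3,), n_filters=2, seed=0)
        maps = convolve(seq, bank)
        assert all(m.values.shape == (4,) for m in maps)

    def test_zero_weights_zero_bias_tanh_gives_zero_map(self, rng):
        bank = ConvFilterBank.create(width=4, n_channels=1,
                                     window_sizes=(3,), n_filters=2, seed=0)
        bank.weights[3].data[:] = 0.0
        maps = convolve(rng.normal(size=(1, 8, 4)), bank)
        assert all(np.all(m.values == 0) for m in maps)

    def test_hand_computed_dot_products(self):
        bank = ConvFilterBank.create(width=1, n_channels=1,
                                     window_sizes=(2,), n_filters=1,
                                     nonlinearity="identity", seed=0)
        bank.weights[2].data[:] = [[1.0], [1.0]]
        bank.biases[2].data[:] = 0.0
        (fmap,) = convolve(np.array([[[1.0], [2.0], [3.0]]]), bank)
        assert np.allclose(fmap.values, [3.0, 5.0])

    def test_sequence_shorter_than_window_rejected(self, rng):
        bank = ConvFilterBank.create(width=4, n_channels=1,
                                     window_sizes=(9,), n_filters=1)
        with pytest.raises(ValueError, match="9"):
            convolve(rng.normal(size=(1, 6, 4)), bank)

    def test_multichannel_filter_sums_channel_contributions(self, rng):
        seq = rng.normal(size=(2, 6, 3))
        bank = ConvFilterBank.create(width=3, n_channels=2,
                                     window_sizes=(3,), n_filters=4, seed=1)
        joint = convolve(seq, bank)
        # splitting the filter by channel and summing pre-activations
        # must reproduce the joint response
        W = bank.weights[3].data
        hW = 3 * 3
        pre = np.zeros((4, 4))
        for c in range(2):
            sub = ConvFilterBank.create(width=3, n_channels=1,
                                        window_sizes=(3,), n_filters=4,
                                        nonlinearity="identity", seed=1)
            sub.weights[3].data = W[c * hW : (c + 1) * hW]
            sub.biases[3].data[:] = 0.0
            sub_maps = convolve(seq[c][None], sub)
            pre += np.stack([m.values for m in sub_maps], axis=1)
        pre += bank.biases[3].data
        assert np.allclose(np.tanh(pre),
                           np.stack([m.values for m in joint], axis=1))


class TestPiecewisePool:
    def test_segment_maxima_worked_example(self):
        assert piecewise_max_pool(
            np.array([1, 5, 2, 7, 3, 4, 9.0]), 2, 4) == (5.0, 7.0, 9.0)

    def test_empty_right_segment_yields_zero(self):
        assert piecewise_max_pool(np.array([1.0, 2.0, 3.0]), 0, 2)[2] == 0.0

    def test_invalid_anchor_order_rejected(self):
        with pytest.raises(ValueError):
            piecewise_max_pool(np.array([1.0, 2.0]), 1, 1)

    def test_matches_bruteforce_oracle_on_random_inputs(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            values = rng.normal(size=n)
            p1 = int(rng.integers(0, n - 1))
            p2 = int(rng.integers(p1 + 1, n + 2))
            got = piecewise_max_pool(values, p1, p2)
            # independent brute-force loop over explicit segments
            segments = ([], [], [])
            for i, v in enumerate(values):
                segments[0 if i <= p1 else (1 if i <= p2 else 2)].append(v)
            want = tuple(max(s) if s else 0.0 for s in segments)
            assert got == want

    def test_collapsed_segments_degenerate_to_global_max(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=20)
        m1, m2, m3 = piecewise_max_pool(values, 18, 19)
        assert np.isclose(max(m1, m2, m3), values.max())
        # p1 at the end: first segment covers everything
        assert np.isclose(piecewise_max_pool(values, 19, 25)[0],
                          values.max())


class TestAttention:
    def test_identical_rows_get_uniform_weights(self, rng):
        seq = np.tile(rng.normal(size=4), (4, 1))
        W, v = rng.normal(size=(4, 4)), rng.normal(size=4)
        alpha = attention_weights(seq, np.ones(4, bool), W, v)
        assert np.allclose(alpha, 0.25)

    def test_pad_positions_get_exact_zero(self, rng):
        seq = rng.normal(size=(6, 4))
        mask = np.array([True] * 4 + [False] * 2)
        alpha = attention_weights(seq, mask, rng.normal(size=(4, 4)),
                                  rng.normal(size=4))
        assert np.all(alpha[4:] == 0.0)

    def test_normalization_over_many_random_inputs(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            L = int(rng.integers(2, 30))
            mask = rng.random(L) < 0.8
            if not mask.any():
                mask[0] = True
            alpha = attention_weights(rng.normal(size=(L, 3)), mask,
                                      rng.normal(size=(3, 3)),
                                      rng.normal(size=3))
            assert abs(alpha.sum() - 1.0) < 1e-6
            assert np.all(alpha >= 0)

    def test_all_pad_input_rejected(self, rng):
        with pytest.raises(ValueError, match="all-pad"):
            attention_weights(np.zeros((3, 2)), np.zeros(3, bool),
                              np.zeros((2, 2)), np.zeros(2))


class TestGaussianNoise:
    def test_zero_std_is_bitwise_identity(self, rng):
        v = rng.normal(size=100)
        out = gaussian_noise(v, NoiseConfig(std=0.0), rng, training=True)
        assert out is v

    def test_eval_mode_is_bitwise_identity(self, rng):
        v = rng.normal(size=100)
        out = gaussian_noise(v, NoiseConfig(std=0.5), rng, training=False)
        assert out is v

    def test_negative_std_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(std=-0.1)

    def test_deterministic_given_generator_state(self):
        v = np.zeros(50)
        cfg = NoiseConfig(std=0.2)
        a = gaussian_noise(v, cfg, np.random.default_rng(3), True)
        b = gaussian_noise(v, cfg, np.random.default_rng(3), True)
        assert np.array_equal(a, b)

    def test_truncated_scheme_respects_range_and_moments(self):
        cfg = NoiseConfig(std=0.1, elem_prob=1.0, trunc_range=(0.0, 0.3),
                          site="embedding")
        rng = np.random.default_rng(11)
        n = 100_000
        pert = gaussian_noise(np.zeros(n), cfg, rng, training=True)
        assert pert.min() >= 0.0 and pert.max() <= 0.3
        mean, var = truncated_normal_moments(cfg)
        se_mean = np.sqrt(var / n)
        assert abs(pert.mean() - mean) < 3 * se_mean
        # variance of the sample variance via the 4th central moment
        m4 = stats.truncnorm.moment(4, 0.0, 3.0, scale=0.1) \
            - 4 * mean * stats.truncnorm.moment(3, 0.0, 3.0, scale=0.1) \
            + 6 * mean**2 * stats.truncnorm.moment(2, 0.0, 3.0, scale=0.1) \
            - 3 * mean**4
        se_var = np.sqrt((m4 - var**2) / n)
        assert abs(pert.var() - var) < 3 * se_var

    def test_element_probability_selects_subset(self):
        cfg = NoiseConfig(std=1.0, elem_prob=0.3, trunc_range=(0.0, 0.3),
                          site="embedding")
        rng = np.random.default_rng(4)
        pert = gaussian_noise(np.zeros(100_000), cfg, rng, training=True)
        frac = np.mean(pert != 0)
        assert abs(frac - 0.3) < 0.01


class TestClassify:
    def test_zero_weights_give_uniform_distribution(self):
        params = ClassifierParams.create(m=8, n_classes=5)
        params.Ws.data[:] = 0.0
        probs = classify(np.ones(8), params)
        assert np.allclose(probs, 0.2)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(9)
        params = ClassifierParams.create(m=8, n_classes=5, seed=2)
        z = rng.normal(size=(1000, 8))
        probs = classify(z, params)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs > 0) & (probs < 1))

    def test_bias_dominates_zero_weights(self):
        params = ClassifierParams.create(m=4, n_classes=5)
        params.Ws.data[:] = 0.0
        params.d.data[:] = [10.0, 0, 0, 0, 0]
        probs = classify(np.ones(4), params)
        assert probs.argmax() == 0 and probs[0] > 0.99

    def test_shape_mismatch_rejected(self):
        params = ClassifierParams.create(m=8, n_classes=5)
        with pytest.raises(ValueError, match="feature length"):
            classify(np.ones(5), params)


def toy_setup(seed=0, k=4, n_channels=1, max_len=12):
    words = ["decreases", "the", "effect", "of", "and", "DRUG1", "DRUG2",
             "DRUGN"]
    rng = np.random.default_rng(seed)
    tables = []
    for c in range(n_channels):
        mat = np.vstack([np.zeros(k), rng.normal(size=(len(words), k))])
        tables.append(EmbeddingTable(
            vocab={PAD_TOKEN: 0, **{w: i + 1 for i, w in enumerate(words)}},
            matrix=mat, k=k, name=f"c{c}"))
    cset = build_channel_set(tables, max_dist=20, k_pos=2, seed=seed)
    sent = make_sentence("Abc decreases the effect of Xyz", ["Abc", "Xyz"])
    (inst,) = generate_candidates(sent)
    inst = pad_or_truncate(encode_positions(inst, 20), max_len)
    return cset, inst


class TestForward:
    def test_inference_is_deterministic_despite_noise_config(self):
        cset, inst = toy_setup()
        model = MCPCNN(width=cset.width, n_channels=1, window_sizes=(3, 5),
                       n_filters=4, noise=NoiseConfig(std=5.0), seed=1)
        a = mcpcnn_forward(inst, cset, model, training=False)
        b = mcpcnn_forward(inst, cset, model, training=False)
        assert np.array_equal(a, b)
        assert abs(a.sum() - 1.0) < 1e-6

    def test_zero_std_equals_noise_free_graph_bitwise(self):
        cset, inst = toy_setup()
        quiet = MCPCNN(width=cset.width, n_channels=1, window_sizes=(3,),
                       n_filters=4, dropout=0.0,
                       noise=NoiseConfig(std=0.0), seed=2)
        loud = MCPCNN(width=cset.width, n_channels=1, window_sizes=(3,),
                      n_filters=4, dropout=0.0,
                      noise=NoiseConfig(std=0.3), seed=2)
        rng = np.random.default_rng(0)
        a = mcpcnn_forward(inst, cset, quiet, rng=rng, training=True)
        b = mcpcnn_forward(inst, cset, loud, training=False)
        c = mcpcnn_forward(inst, cset, quiet, training=False)
        assert np.array_equal(a, c)  # sigma=0 in training == eval graph
        assert np.array_equal(b, c)  # eval mode ignores noise entirely

    def test_hand_traced_single_filter_pipeline(self):
        """Full trace: conv (identity-free), piecewise pool, softmax."""
        cset, inst = toy_setup(k=4, n_channels=1)
        model = MCPCNN(width=cset.width, n_channels=1, window_sizes=(3,),
                       n_filters=2, dropout=0.0, attention=False,
                       noise=NoiseConfig(std=0.0), seed=3)
        X, mask, p1, p2 = embed_batch([inst], cset)
        probs = ad.softmax(model.forward_batch(X, mask, p1, p2),
                           axis=-1).data[0]
        # independent trace with the reference ops
        W = model.bank.weights[3].data
        b = model.bank.biases[3].data
        L, width = X.shape[2], X.shape[3]
        P = L - 3 + 1
        fmap = np.empty((P, 2))
        for i in range(P):
            window = X[0, 0, i : i + 3, :].reshape(-1)
            fmap[i] = np.tanh(window @ W + b)
        # the model concatenates per-segment (B, F) blocks
        z_model = np.concatenate([
            [piecewise_max_pool(fmap[:, f], int(p1[0]), int(p2[0]))[s]
             for f in range(2)] for s in range(3)
        ])
        o = z_model @ model.clf.Ws.data + model.clf.d.data
        e = np.exp(o - o.max())
        assert np.allclose(probs, e / e.sum(), atol=1e-12)

    def test_training_loss_decreases_on_separable_toy(self):
        """Gradient smoke: 20 steps on a 64-instance separable batch."""
        cset, inst = toy_setup(k=4)
        from ddigauss.training import Adam
        rng = np.random.default_rng(0)
        X, mask, p1, p2 = embed_batch([inst] * 64, cset)
        X = X + rng.normal(0, 0.05, size=X.shape) * mask[:, None, :, None]
        y = np.tile(np.arange(4), 16)
        X[np.arange(64), :, 1, :] += y[:, None, None]  # class-coded token
        model = MCPCNN(width=cset.width, n_channels=1, window_sizes=(3,),
                       n_filters=8, dropout=0.0,
                       noise=NoiseConfig(std=0.0), seed=4)
        opt = Adam(model.parameters(), lr=3e-3)
        losses = []
        for _ in range(20):
            opt.zero_grad()
            loss, _ = model.loss_and_preds((X, mask, p1, p2, y), rng, True)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[-1] < losses[0] * 0.7


@pytest.fixture
def rng():
    return np.random.default_rng(21)
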
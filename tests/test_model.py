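"""Multi-scaled self-attention model: masks, blocks, training dynamics."""

import numpy as np
import pytest

from msadta._autograd import Tensor
from msadta.model import (
    NEG_INF,
    DTAModel,
    HeadParams,
    ModelConfig,
    attention_head,
    build_band_mask,
    load_checkpoint,
    save_checkpoint,
)
from msadta.synthetic import SyntheticSpec, generate_affinity_dataset
from msadta.model import encode_dataset, triples_to_arrays

from _oracles import softmax as np_softmax, vanilla_mha_block


def _random_head(rng, e, d_h):
    return HeadParams(
        W_Q=Tensor(rng.normal(size=(e, d_h))),
        W_K=Tensor(rng.normal(size=(e, d_h))),
        W_V=Tensor(rng.normal(size=(e, d_h))),
    )


class TestBandMask:
    def test_zero_window_opens_only_the_diagonal(self):
        m = build_band_mask(3, 0).matrix
        assert np.array_equal(m == 0, np.eye(3, dtype=bool))

    def test_wide_window_opens_everything(self):
        assert np.all(build_band_mask(4, 3).matrix == 0)
        assert np.all(build_band_mask(4, 99).matrix == 0)

    def test_window_one_is_tridiagonal(self):
        open_ = build_band_mask(4, 1).matrix == 0
        expected = np.abs(np.subtract.outer(np.arange(4), np.arange(4))) <= 1
        assert np.array_equal(open_, expected)

    def test_diagonal_always_open(self):
        for m in (0, 1, 5):
            assert np.all(np.diag(build_band_mask(7, m).matrix) == 0)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            build_band_mask(0, 1)
        with pytest.raises(ValueError):
            build_band_mask(3, -1)


class TestAttentionHead:
    def test_zero_window_copies_value_vectors(self, rng):
        E = Tensor(rng.normal(size=(6, 8)))
        head = _random_head(rng, 8, 4)
        out = attention_head(E, head, build_band_mask(6, 0))
        np.testing.assert_array_almost_equal(out.data, (E @ head.W_V).data, decimal=12)

    def test_full_window_matches_unmasked_reference(self, rng):
        from _oracles import vanilla_attention

        E = rng.normal(size=(5, 8))
        head = _random_head(rng, 8, 4)
        out = attention_head(Tensor(E), head, build_band_mask(5, 4))
        ref = vanilla_attention(E, head.W_Q.data, head.W_K.data, head.W_V.data)
        np.testing.assert_allclose(out.data, ref, atol=1e-6)

    @pytest.mark.parametrize("m", [0, 1, 2, 4, 7])
    def test_weights_banded_and_normalized(self, rng, m):
        """Softmax rows sum to 1 and are exactly zero outside the band."""
        l, e, d_h = 8, 8, 4
        E = rng.normal(size=(l, e))
        head = _random_head(rng, e, d_h)
        mask = build_band_mask(l, m)
        out = attention_head(Tensor(E), head, mask)
        Q, K, V = E @ head.W_Q.data, E @ head.W_K.data, E @ head.W_V.data
        weights = np_softmax(Q @ K.T / np.sqrt(d_h) + mask.matrix)
        np.testing.assert_allclose(weights.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(weights[mask.matrix < NEG_INF / 2] < 1e-30)
        np.testing.assert_allclose(out.data, weights @ V, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        E = Tensor(rng.normal(size=(6, 10)))
        head = _random_head(rng, 8, 4)
        with pytest.raises(ValueError):
            attention_head(E, head, build_band_mask(6, 2))


class TestBlock:
    def _model(self, seed=0, **kw):
        defaults = dict(
            l_d=7, l_p=7, e_d=12, e_p=12, n_heads=3, window_sizes=(0, 2, 6),
            L_d=1, L_p=1, ffn_hidden=(8, 8, 4, 1), dropout=0.0,
        )
        defaults.update(kw)
        cfg = ModelConfig(**defaults)
        return DTAModel(cfg, 9, 9, seed=seed), cfg

    def test_output_shape_and_determinism(self):
        model, cfg = self._model()
        ids = np.array([[1, 2, 3, 4, 5, 6, 7]])
        a = model.encode_side(ids, "drug").data
        b = model.encode_side(ids, "drug").data
        assert a.shape == (1, cfg.l_d, cfg.e_d)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("n_blocks", [1, 2])
    def test_stacking_preserves_shape(self, n_blocks):
        model, cfg = self._model(L_d=n_blocks)
        ids = np.array([[1, 2, 3, 4, 5, 6, 7]])
        assert model.encode_side(ids, "drug").shape == (1, cfg.l_d, cfg.e_d)

    def test_all_wide_windows_equal_vanilla_multihead_block(self):
        """With every head's window covering the whole sequence the block
        must reduce to a standard Transformer encoder block."""
        model, cfg = self._model(window_sizes=(6, 6, 6))
        ids = np.array([[1, 2, 3, 4, 5, 6, 7]])  # no padding
        E = model.embed(ids, "drug").data[0]
        got = model.encode_side(ids, "drug").data[0]
        p = model._params
        heads = [
            (p[f"drug.block0.head{h}.W_Q"].data,
             p[f"drug.block0.head{h}.W_K"].data,
             p[f"drug.block0.head{h}.W_V"].data)
            for h in range(cfg.n_heads)
        ]
        ref = vanilla_mha_block(
            E, heads,
            (p["drug.block0.ln1.gamma"].data, p["drug.block0.ln1.beta"].data),
            (p["drug.block0.ffn.W"].data, p["drug.block0.ffn.b"].data),
            (p["drug.block0.ln2.gamma"].data, p["drug.block0.ln2.beta"].data),
        )
        np.testing.assert_allclose(got, ref, atol=1e-6)

    def test_permuting_positions_changes_output(self):
        model, _ = self._model()
        ids = np.array([[1, 2, 3, 4, 5, 6, 7]])
        base = model.forward(ids, ids).data
        perm = ids[:, ::-1].copy()
        assert not np.allclose(model.forward(perm, ids).data, base)


class TestEmbedding:
    def test_zero_token_table_leaves_position_embedding(self):
        cfg = ModelConfig(l_d=5, l_p=5, e_d=8, e_p=8, n_heads=2,
                          window_sizes=(0, 1), L_d=1, L_p=1,
                          ffn_hidden=(4, 4, 2, 1), dropout=0.0)
        model = DTAModel(cfg, 6, 6, seed=0)
        model._params["drug.tok_emb"].data[...] = 0.0
        out = model.embed(np.array([[1, 2, 3, 0, 0]]), "drug")
        np.testing.assert_array_equal(out.data[0], model._params["drug.pos_emb"].data)

    def test_out_of_range_ids_rejected(self):
        cfg = ModelConfig(l_d=3, l_p=3, e_d=4, e_p=4, n_heads=2,
                          window_sizes=(0,), L_d=1, L_p=1,
                          ffn_hidden=(4, 4, 2, 1), dropout=0.0)
        model = DTAModel(cfg, 5, 5, seed=0)
        with pytest.raises(ValueError):
            model.embed(np.array([[1, 2, 99]]), "drug")


class TestInteraction:
    def test_zero_weights_give_zero_output(self):
        cfg = ModelConfig(l_d=4, l_p=4, e_d=4, e_p=4, n_heads=2,
                          window_sizes=(0, 1), L_d=1, L_p=1,
                          ffn_hidden=(6, 6, 3, 1), dropout=0.0)
        model = DTAModel(cfg, 5, 5, seed=0)
        for name, p in model._params.items():
            if name.startswith("inter."):
                p.data[...] = 0.0
        out = model.forward(np.array([[1, 2, 3, 4]]), np.array([[1, 1, 2, 0]]))
        assert out.data.shape == (1,)
        assert out.data[0] == 0.0


class TestTraining:
    def _synthetic_arrays(self, config, n_drugs=20, n_proteins=10, seed=3):
        ds = generate_affinity_dataset(
            SyntheticSpec(n_drugs=n_drugs, n_proteins=n_proteins,
                          noise_sd=0.1, seed=seed)
        )
        vd, vp, xd, xp = encode_dataset(ds, config, 40, 40)
        arrays = triples_to_arrays(ds, xd, xp)
        return vd, vp, arrays

    def test_beats_constant_mean_predictor(self, small_config):
        """200 planted-signal pairs, 30 epochs: final train MSE must drop
        below the variance of the targets (the mean predictor's MSE)."""
        vd, vp, (xd, xp, y) = self._synthetic_arrays(small_config)
        model = DTAModel(small_config, vd.n_ids, vp.n_ids, seed=0)
        trace = model.fit(xd, xp, y, seed=0, epochs=30)
        assert y.size == 200
        assert trace[-1] < np.var(y)

    def test_identical_seeds_identical_traces(self, small_config):
        vd, vp, (xd, xp, y) = self._synthetic_arrays(small_config)
        traces = []
        for _ in range(2):
            model = DTAModel(small_config, vd.n_ids, vp.n_ids, seed=4)
            traces.append(model.fit(xd, xp, y, seed=4, epochs=3))
        assert traces[0] == traces[1]

    def test_zero_learning_rate_freezes_loss(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, learning_rate=0.0)
        vd, vp, (xd, xp, y) = self._synthetic_arrays(cfg)
        model = DTAModel(cfg, vd.n_ids, vp.n_ids, seed=0)
        trace = model.fit(xd, xp, y, seed=0, epochs=3)
        assert max(trace) - min(trace) < 1e-12

    def test_nan_loss_aborts_with_diagnostic(self, small_config):
        vd, vp, (xd, xp, y) = self._synthetic_arrays(small_config)
        y = y.copy()
        y[3] = np.nan  # poisoned target makes the batch loss non-finite
        model = DTAModel(small_config, vd.n_ids, vp.n_ids, seed=0)
        with pytest.raises(FloatingPointError, match="non-finite"):
            model.fit(xd, xp, y, seed=0, epochs=1)


class TestConfig:
    def test_heads_must_divide_embedding(self):
        with pytest.raises(ValueError):
            ModelConfig(e_d=10, n_heads=4)

    def test_more_windows_than_heads_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_heads=2, window_sizes=(0, 1, 2))

    def test_window_cycling_when_fewer_windows_than_heads(self):
        cfg = ModelConfig(n_heads=4, window_sizes=(0, 1))
        assert [cfg.head_window(h) for h in range(4)] == [0, 1, 0, 1]

    def test_e_p_defaults_to_e_d(self):
        assert ModelConfig(e_d=64).e_p == 64

    @pytest.mark.parametrize("name, l_d, l_p, e_d, L_d, L_p",
                             [("kiba", 80, 800, 128, 2, 2),
                              ("davis", 36, 900, 64, 2, 1)])
    def test_shipped_presets(self, name, l_d, l_p, e_d, L_d, L_p):
        cfg = ModelConfig.preset(name)
        assert (cfg.l_d, cfg.l_p, cfg.e_d, cfg.L_d, cfg.L_p) == (l_d, l_p, e_d, L_d, L_p)
        assert cfg.window_sizes == (0, 1, 2, 3)
        assert cfg.ffn_hidden == (1024, 1024, 512, 1)
        assert cfg.dropout == 0.1
        assert cfg.learning_rate == 1e-4

    def test_parameter_count_matches_closed_form_for_kiba_config(self):
        """Closed-form count from the config must equal the allocated count."""
        cfg = ModelConfig.preset("kiba")
        n_drug_tokens, n_protein_tokens = 100, 120
        model = DTAModel(cfg, n_drug_tokens, n_protein_tokens, seed=0)

        def encoder_count(n_tok, l, e, blocks, n_heads):
            per_block = 3 * e * e + 2 * e + (e * e + e) + 2 * e
            return n_tok * e + l * e + blocks * per_block

        widths = (cfg.l_d * cfg.e_d + cfg.l_p * cfg.e_p,) + cfg.ffn_hidden
        inter = sum(a * b + b for a, b in zip(widths, widths[1:]))
        expected = (
            encoder_count(n_drug_tokens, cfg.l_d, cfg.e_d, cfg.L_d, cfg.n_heads)
            + encoder_count(n_protein_tokens, cfg.l_p, cfg.e_p, cfg.L_p, cfg.n_heads)
            + inter
        )
        assert model.n_parameters == expected


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, small_config, tmp_path):
        ds = generate_affinity_dataset(
            SyntheticSpec(n_drugs=6, n_proteins=4, noise_sd=0.1, seed=5)
        )
        vd, vp, xd, xp = encode_dataset(ds, small_config, 20, 20)
        arr_d, arr_p, y = triples_to_arrays(ds, xd, xp)
        model = DTAModel(small_config, vd.n_ids, vp.n_ids, seed=2)
        model.fit(arr_d, arr_p, y, seed=2, epochs=2)
        before = model.predict(arr_d, arr_p)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, vd, vp)
        loaded, vd2, vp2 = load_checkpoint(path)
        np.testing.assert_array_equal(loaded.predict(arr_d, arr_p), before)
        assert vd2 == vd and vp2 == vp
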
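import math

import numpy as np
import pytest

import pbac
from pbac.network import softmax

from conftest import hand_model


def rand_attention(P=5, H=3, seed=0):
    rng = np.random.default_rng(seed)
    return pbac.AttentionParams(rng.normal(size=(P, H)), rng.normal(size=(H, P)))


class TestAttention:
    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        params = rand_attention(seed=seed)
        out = pbac.attention_forward(rng.normal(size=(7, 5)) * 10, params)
        np.testing.assert_allclose(out.Wa.sum(axis=1), 1.0, atol=1e-6)
        assert (out.Wa >= 0).all()

    def test_zero_parameters_give_uniform(self):
        params = pbac.AttentionParams(np.zeros((4, 2)), np.zeros((2, 4)))
        out = pbac.attention_forward(np.array([[1.0, -2.0, 3.0, 0.5]]), params)
        np.testing.assert_allclose(out.Wa, 0.25)

    def test_scalar_hand_computation(self):
        # P=3, H=2 worked by hand with explicit scalar arithmetic
        W1 = np.array([[0.5, -0.2], [0.1, 0.3], [-0.4, 0.2]])
        W2 = np.array([[0.3, -0.1, 0.2], [0.4, 0.2, -0.3]])
        x = np.array([1.0, -1.0, 2.0])
        t = [math.tanh(sum(x[i] * W1[i, h] for i in range(3))) for h in range(2)]
        s = [sum(t[h] * W2[h, p] for h in range(2)) for p in range(3)]
        es = [math.exp(v - max(s)) for v in s]
        wa = [v / sum(es) for v in es]
        out = pbac.attention_forward(x, pbac.AttentionParams(W1, W2))
        np.testing.assert_allclose(out.Wa[0], wa, atol=1e-12)
        np.testing.assert_allclose(out.Xa[0], x * np.array(wa), atol=1e-12)

    def test_shift_invariance_of_softmax_scores(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=(4, 6))
        np.testing.assert_allclose(softmax(s), softmax(s + 123.4), atol=1e-12)

    def test_nonfinite_input_rejected(self):
        params = rand_attention()
        with pytest.raises(ValueError, match="finite"):
            pbac.attention_forward(np.array([[np.nan, 0, 0, 0, 0]]), params)


class TestConv:
    def test_center_tap_identity(self):
        params = pbac.ConvParams(np.array([[0.0, 1.0, 0.0]]), np.zeros(1))
        x = np.array([[1.0, -2.0, 3.5, 0.0]])
        np.testing.assert_allclose(pbac.conv_forward(x, params)[0, 0], x[0])

    def test_hand_convolution(self):
        params = pbac.ConvParams(np.array([[1.0, 1.0, 1.0]]), np.zeros(1))
        out = pbac.conv_forward(np.array([[1.0, 2.0, 3.0]]), params)
        np.testing.assert_allclose(out[0, 0], [3.0, 6.0, 5.0])

    @pytest.mark.parametrize("P", [1, 2, 3, 8, 50])
    def test_length_preserved(self, P):
        rng = np.random.default_rng(P)
        params = pbac.ConvParams(rng.normal(size=(4, 3)), rng.normal(size=4))
        out = pbac.conv_forward(rng.normal(size=(2, P)), params)
        assert out.shape == (2, 4, P)


class TestHead:
    def test_zero_parameters_give_half_half(self):
        params = pbac.HeadParams(np.zeros((6, 2)), np.zeros(2))
        out = pbac.head_forward(np.zeros((3, 2, 3)), params)
        np.testing.assert_allclose(out, 0.5)

    def test_probability_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        params = pbac.HeadParams(rng.normal(size=(8, 2)), rng.normal(size=2))
        out = pbac.head_forward(rng.normal(size=(5, 4, 2)), params)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_scalar_softmax_oracle(self):
        Wf = np.array([[0.7, -0.3], [0.2, 0.9]])
        b = np.array([0.1, -0.2])
        z = np.array([[1.5, -0.5]])
        logits = [sum(z[0][i] * Wf[i, k] for i in range(2)) + b[k] for k in range(2)]
        e = [math.exp(v) for v in logits]
        expected = [v / sum(e) for v in e]
        out = pbac.head_forward(z, pbac.HeadParams(Wf, b))
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_regression_head_returns_scalars(self):
        params = pbac.HeadParams(np.array([[2.0], [1.0]]), np.array([0.5]))
        out = pbac.head_forward(np.array([[1.0, 3.0]]), params, head_type="regress_ic50")
        np.testing.assert_allclose(out, [5.5])


class TestForward:
    def test_end_to_end_scalar_oracle(self):
        """P=3, H=2, C=1 hand-parameterised model vs scalar arithmetic."""
        model = hand_model()
        x = np.array([0.5, -1.0, 2.0, 1.5])
        # mask stage: mean of member genes per pathway
        xm = [
            (x[0] + x[1]) / 2.0,  # A = {g1, g2}
            (x[1] + x[2]) / 2.0,  # B = {g2, g3}
            x[3] / 1.0,  # C = {g4}
        ]
        W1, W2 = model.params["W1"], model.params["W2"]
        t = [math.tanh(sum(xm[i] * W1[i, h] for i in range(3))) for h in range(2)]
        s = [sum(t[h] * W2[h, p] for h in range(2)) for p in range(3)]
        es = [math.exp(v - max(s)) for v in s]
        wa = [v / sum(es) for v in es]
        xa = [xm[p] * wa[p] for p in range(3)]
        k = model.params["Wk"][0]
        padded = [0.0, *xa, 0.0]
        xc = [
            k[0] * padded[p] + k[1] * padded[p + 1] + k[2] * padded[p + 2] + 0.1
            for p in range(3)
        ]
        Wf, bf = model.params["Wf"], model.params["bf"]
        logits = [sum(xc[i] * Wf[i, kk] for i in range(3)) + bf[kk] for kk in range(2)]
        e = [math.exp(v - max(logits)) for v in logits]
        expected = [v / sum(e) for v in e]

        preds, att = model.forward(x[None, :])
        np.testing.assert_allclose(att.Wa[0], wa, atol=1e-6)
        np.testing.assert_allclose(att.Xa[0], xa, atol=1e-6)
        np.testing.assert_allclose(preds[0], expected, atol=1e-6)

    def test_no_attention_returns_uniform_and_scaled(self):
        model = hand_model()
        variant = pbac.make_variant(model.mask, "no_attention", latent_dim=2, conv_channels=1)
        x = np.random.default_rng(0).normal(size=(4, 4))
        _, att = variant.forward(x)
        np.testing.assert_allclose(att.Wa, 1 / 3)
        xm = (x @ model.mask.M.T) / model.mask.M.sum(axis=1)
        np.testing.assert_allclose(att.Xa, xm / 3)

    def test_unmasked_gene_has_zero_influence(self):
        # g5 belongs to no pathway: perturbing it must leave output bit-identical
        mask = pbac.MaskMatrix(
            ["A", "B"],
            ["g1", "g2", "g3", "g4", "g5"],
            np.array([[1.0, 1, 0, 0, 0], [0, 0, 1, 1, 0]]),
        )
        model = pbac.PBACModel.init(mask, latent_dim=2, conv_channels=2, seed=4)
        x = np.random.default_rng(2).normal(size=(3, 5))
        base, _ = model.forward(x)
        x2 = x.copy()
        x2[:, 4] += 1000.0
        perturbed, _ = model.forward(x2)
        assert (base == perturbed).all()

    def test_pathway_permutation_equivariance(self):
        """Permuting pathways consistently in mask/attention/head permutes Wa
        identically and, with the symmetric kernel [0,1,0], leaves the
        classification output unchanged."""
        model = hand_model()
        model.params["Wk"] = np.array([[0.0, 1.0, 0.0]])
        x = np.random.default_rng(6).normal(size=(2, 4))
        preds, att = model.forward(x)

        perm = [2, 0, 1]
        mask_p = pbac.MaskMatrix(
            [model.mask.pathway_names[i] for i in perm],
            model.mask.gene_ids,
            model.mask.M[perm],
        )
        model_p = pbac.PBACModel.init(mask_p, latent_dim=2, conv_channels=1, seed=0)
        model_p.params["W1"] = model.params["W1"][perm]
        model_p.params["W2"] = model.params["W2"][:, perm]
        model_p.params["Wk"] = model.params["Wk"].copy()
        model_p.params["bk"] = model.params["bk"].copy()
        model_p.params["Wf"] = model.params["Wf"][perm]
        model_p.params["bf"] = model.params["bf"].copy()
        model_p.standardizer = None
        preds_p, att_p = model_p.forward(x)
        np.testing.assert_allclose(att_p.Wa, att.Wa[:, perm], atol=1e-12)
        np.testing.assert_allclose(preds_p, preds, atol=1e-12)


class TestVariants:
    def test_none_is_default(self, tiny_collection):
        mask = pbac.build_mask(tiny_collection, ["g1", "g2", "g3", "g4"])
        a = pbac.make_variant(mask, "none", seed=1)
        b = pbac.PBACModel.init(mask, seed=1)
        assert a.ablation == "none"
        for key in a.params:
            np.testing.assert_array_equal(a.params[key], b.params[key])

    def test_no_mask_parameter_count(self, tiny_collection):
        genes = ["g1", "g2", "g3", "g4"]
        mask = pbac.build_mask(tiny_collection, genes)
        full = pbac.make_variant(mask, "none", seed=0)
        dense = pbac.make_variant(mask, "no_mask", seed=0)
        n, P = len(genes), mask.n_pathways
        assert dense.n_params == full.n_params + n * P + P

    def test_no_attention_has_no_attention_gradients(self, tiny_collection):
        mask = pbac.build_mask(tiny_collection, ["g1", "g2", "g3", "g4"])
        model = pbac.make_variant(mask, "no_attention", seed=0)
        assert "W1" not in model.params and "W2" not in model.params
        x = np.random.default_rng(0).normal(size=(4, 4))
        _, cache, _ = model._forward_cached(x)
        grads = model._backward(cache, np.ones((4, 2)) / 4)
        assert "W1" not in grads and "W2" not in grads

    def test_unknown_variant_rejected(self, tiny_collection):
        mask = pbac.build_mask(tiny_collection, ["g1", "g2", "g3", "g4"])
        with pytest.raises(ValueError, match="unknown ablation"):
            pbac.make_variant(mask, "no_conv")


class TestGradients:
    @pytest.mark.parametrize("ablation", ["none", "no_mask"])
    @pytest.mark.parametrize("head_type", ["classify", "regress_ic50"])
    def test_backward_matches_finite_differences(self, ablation, head_type):
        rng = np.random.default_rng(11)
        mask = pbac.MaskMatrix(
            ["A", "B", "C"],
            ["g1", "g2", "g3", "g4", "g5"],
            np.array([[1.0, 1, 0, 0, 0], [0, 1, 1, 1, 0], [0, 0, 0, 1, 1]]),
        )
        model = pbac.PBACModel.init(
            mask, latent_dim=2, conv_channels=2, ablation=ablation,
            head_type=head_type, seed=5,
        )
        X = rng.normal(size=(4, 5))
        y = np.array([0, 1, 1, 0])

        def loss_value():
            _, cache, _ = model._forward_cached(X)
            logits = cache["logits"]
            if head_type == "classify":
                z = logits - logits.max(axis=1, keepdims=True)
                logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
                return -logp[np.arange(4), y].mean()
            return ((logits[:, 0] - y) ** 2).mean()

        _, cache, _ = model._forward_cached(X)
        logits = cache["logits"]
        if head_type == "classify":
            z = logits - logits.max(axis=1, keepdims=True)
            probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            onehot = np.zeros_like(probs)
            onehot[np.arange(4), y] = 1.0
            dlogits = (probs - onehot) / 4
        else:
            dlogits = (2 * (logits[:, 0] - y) / 4)[:, None]
        grads = model._backward(cache, dlogits)

        eps = 1e-6
        for name, g in grads.items():
            flat = model.params[name].ravel()
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), name


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, fitted_small_model):
        model = fitted_small_model
        model.save(tmp_path / "ckpt")
        back = pbac.PBACModel.load(tmp_path / "ckpt")
        x = np.random.default_rng(1).normal(size=(3, model.mask.n_genes))
        np.testing.assert_array_equal(model.forward(x)[0], back.forward(x)[0])
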
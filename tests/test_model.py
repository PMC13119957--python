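"""Network contracts: shapes, determinism, fusion invariants, and the
zero-influence guarantee for absent modalities."""

import numpy as np
import pytest

from modrepair.autodiff import Tensor
from modrepair.model import EncoderSpec, RepairNet

SHAPES = {"imu": (40, 3), "ecg": (40, 1), "eda": (40, 1)}


@pytest.fixture(scope="module")
def net() -> RepairNet:
    n = RepairNet(SHAPES, seed=42)
    n.eval()
    return n


@pytest.fixture(scope="module")
def windows():
    rng = np.random.default_rng(2)
    return {m: rng.standard_normal((8,) + s).astype(np.float32)
            for m, s in SHAPES.items()}


class TestEncoder:
    def test_output_shape_and_finiteness(self, net, windows):
        z = net.encode_modality("imu", windows["imu"])
        assert z.shape == (8, 128)
        assert np.isfinite(z.data).all()

    def test_zero_input_finite(self, net):
        z = net.encode_modality("ecg", np.zeros((2, 40, 1), dtype=np.float32))
        assert np.isfinite(z.data).all()

    def test_eval_mode_deterministic(self, net, windows):
        a = net.encode_modality("imu", windows["imu"]).data
        b = net.encode_modality("imu", windows["imu"]).data
        np.testing.assert_array_equal(a, b)

    def test_batch_equivariance(self, net, windows):
        x = windows["imu"]
        whole = net.encode_modality("imu", x).data
        parts = np.concatenate([net.encode_modality("imu", x[:3]).data,
                                net.encode_modality("imu", x[3:]).data])
        np.testing.assert_allclose(whole, parts, atol=1e-5)

    def test_channel_mismatch_raises(self, net):
        with pytest.raises(ValueError):
            net.encode_modality("imu", np.zeros((1, 40, 2), dtype=np.float32))

    def test_seed_reproducible_init(self):
        a = RepairNet(SHAPES, seed=7).named_state()
        b = RepairNet(SHAPES, seed=7).named_state()
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])


class TestFusion:
    def test_singleton_presence_gives_weight_one(self, net, windows):
        presence = np.zeros((8, 3), bool)
        presence[:, 1] = True
        emb = net.embed(windows, presence)
        np.testing.assert_allclose(emb.attention[:, 1], 1.0, atol=1e-6)
        assert (emb.attention[:, [0, 2]] == 0).all()

    def test_identical_embeddings_share_weight_equally(self, net):
        z = Tensor(np.random.default_rng(0)
                   .standard_normal((4, 128)).astype(np.float32))
        fused, attn = net.fusion([z, z, z], np.ones((4, 3), bool))
        np.testing.assert_allclose(attn, 1 / 3, atol=1e-6)

    def test_weights_sum_to_one_over_present(self, net, windows):
        rng = np.random.default_rng(5)
        presence = rng.random((8, 3)) > 0.4
        presence[~presence.any(axis=1), 0] = True
        emb = net.embed(windows, presence)
        np.testing.assert_allclose(emb.attention.sum(axis=1), 1.0, atol=1e-6)
        assert (emb.attention[~presence] == 0).all()

    def test_all_absent_row_rejected(self, net, windows):
        presence = np.ones((8, 3), bool)
        presence[3] = False
        with pytest.raises(ValueError):
            net.embed(windows, presence)

    def test_permutation_consistency(self, windows):
        """Permuting modality slot order permutes weights identically and
        leaves the fused vector unchanged."""
        net1 = RepairNet(SHAPES, seed=3)
        net1.eval()
        perm_shapes = {k: SHAPES[k] for k in ["eda", "imu", "ecg"]}
        net2 = RepairNet(perm_shapes, seed=99)
        net2.eval()
        # align parameters: same encoders per modality, same fusion map
        for m in SHAPES:
            net2.encoders[m].load_state(net1.encoders[m].named_state())
        net2.fusion.load_state(net1.fusion.named_state())
        e1 = net1.embed(windows, np.ones((8, 3), bool))
        e2 = net2.embed(windows, np.ones((8, 3), bool))
        np.testing.assert_allclose(e1.fused.data, e2.fused.data, atol=1e-5)
        for j1, m in enumerate(net1.modalities):
            j2 = net2.modalities.index(m)
            np.testing.assert_allclose(e1.attention[:, j1],
                                       e2.attention[:, j2], atol=1e-6)

    def test_absent_modality_has_zero_influence(self, net, windows):
        """Arbitrary garbage in an absent modality cannot change fused,
        presence-head, or decoder outputs."""
        presence = np.ones((8, 3), bool)
        presence[:, 2] = False
        emb1 = net.embed(windows, presence)
        corrupted = dict(windows)
        corrupted["eda"] = windows["eda"] + 1e6
        emb2 = net.embed(corrupted, presence)
        np.testing.assert_array_equal(emb1.fused.data, emb2.fused.data)
        np.testing.assert_array_equal(
            net.presence_logits(emb1.fused).data,
            net.presence_logits(emb2.fused).data)
        r1 = net.decode_missing(emb1.fused, presence)
        r2 = net.decode_missing(emb2.fused, presence)
        for m in net.modalities:
            np.testing.assert_array_equal(r1[m].data, r2[m].data)


class TestHeads:
    def test_presence_probabilities_bounded(self, net, windows):
        probs = net.predict_presence(windows)
        assert probs.shape == (8, 3)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_decoder_matches_window_shapes(self, net, windows):
        emb = net.embed(windows, np.ones((8, 3), bool))
        recon = net.decode_missing(emb.fused, np.ones((8, 3)))
        for m, (t_w, c) in SHAPES.items():
            assert recon[m].shape == (8, t_w, c)

    def test_projection_dimension(self, net, windows):
        z = net.encode_modality("imu", windows["imu"])
        assert net.project(z).shape == (8, 64)

    def test_forward_finite_on_bounded_inputs(self, net):
        x = {m: np.full((4,) + s, 10.0, dtype=np.float32)
             for m, s in SHAPES.items()}
        emb = net.embed(x, np.ones((4, 3), bool))
        assert np.isfinite(emb.fused.data).all()
        recon = net.decode_missing(emb.fused, np.ones((4, 3)))
        assert all(np.isfinite(r.data).all() for r in recon.values())

    def test_unknown_modality_errors(self, net):
        with pytest.raises(KeyError):
            net.encode_modality("ppg", np.zeros((1, 40, 1), dtype=np.float32))


class TestCheckpoint:
    def test_save_load_round_trip(self, net, windows, tmp_path):
        path = tmp_path / "model.npz"
        net.save(path)
        back = RepairNet.load(path)
        back.eval()
        e1 = net.embed(windows, np.ones((8, 3), bool))
        e2 = back.embed(windows, np.ones((8, 3), bool))
        np.testing.assert_array_equal(e1.fused.data, e2.fused.data)

    def test_spec_round_trip(self, tmp_path):
        spec = EncoderSpec(kernels=(3, 3), channels=(8, 16), proj_dim=5)
        small = RepairNet({"a": (12, 1)}, spec=spec, seed=0)
        small.save(tmp_path / "m.npz")
        again = RepairNet.load(tmp_path / "m.npz")
        assert again.spec.channels == (8, 16)
        assert again.spec.proj_dim == 5
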
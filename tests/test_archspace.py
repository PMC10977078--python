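"""Search-space decoding, shape propagation, parameter accounting."""

import numpy as np
import pytest

from preictal.archspace import (
    FULL_OPTION_SETS,
    arch_to_actions,
    build_model,
    decode_arch,
    decode_arch_string,
    encode_arch,
    model_size_bytes,
    parameter_count,
    propagate_shape,
    space_size,
)


def random_actions(rng):
    return [int(rng.integers(len(o))) for o in FULL_OPTION_SETS]


class TestDecode:
    def test_all_zeros_is_smallest_architecture(self):
        arch = decode_arch([0] * 15)
        for b in arch.blocks:
            assert b.n_filters == 4
            assert (b.kw if b.temporal else b.kh) == 1
            assert (b.pw if b.temporal else b.ph) == 1

    def test_bijection_roundtrip(self, rng):
        for _ in range(100):
            actions = random_actions(rng)
            arch = decode_arch(actions)
            assert arch_to_actions(arch) == actions
            assert decode_arch_string(encode_arch(arch)) == arch

    def test_out_of_range_names_position(self):
        actions = [0] * 15
        actions[7] = 9
        with pytest.raises(ValueError, match="position 7"):
            decode_arch(actions)
        with pytest.raises(ValueError, match="expected 15"):
            decode_arch([0] * 14)

    def test_full_space_cardinality(self):
        assert space_size() == (4 * 3 * 4) ** 3 * (4 * 3 * 3) ** 2 == 143_327_232

    def test_reduced_space_enumeration(self):
        # {1,2} kernels, fixed filters and pools: 2 choices per block = 2^5
        reduced = []
        for block in range(5):
            reduced += [(1, 2), (4,), (1,)]
        assert space_size(reduced) == 32
        seen = {
            encode_arch(decode_arch([b >> i & 1 if j == 0 else 0
                                     for i in range(5) for j in range(3)], reduced))
            for b in range(32)
        }
        assert len(seen) == 32  # explicit enumeration: all distinct


class TestShapes:
    def test_channel_count_preserved_through_temporal_blocks(self):
        arch = decode_arch_string("1x8f8p1x4|1x2f8p1x4|1x1f4p1x1|1x1f4p1x1|1x1f4p1x1")
        shapes = propagate_shape(arch, (23, 7680))
        for f, h, w in shapes[:3]:
            assert h == 23  # temporal blocks never touch the channel axis

    def test_shape_error_names_block(self):
        arch = decode_arch_string("1x8f8p1x16|1x8f8p1x16|1x8f8p1x16|1x1f4p1x1|1x1f4p1x1")
        with pytest.raises(ValueError, match="block 2"):
            propagate_shape(arch, (4, 600))

    def test_propagation_matches_actual_forward_shapes(self, rng):
        """Independent oracle: run a real forward pass and compare shapes."""
        checked = 0
        while checked < 20:
            actions = random_actions(rng)
            arch = decode_arch(actions)
            try:
                shapes = propagate_shape(arch, (8, 1024))
            except ValueError:
                continue
            net = build_model(arch, (8, 1024), seed=0)
            x = rng.normal(size=(2, 1, 8, 1024))
            z = x
            for i, (conv, bn, act, pool) in enumerate(net.block_index):
                for lyr in (conv, bn, act, pool):
                    z = lyr.forward(z, training=True)
                assert z.shape[1:] == shapes[i]
            checked += 1


class TestAccounting:
    def test_conv_weight_formula(self):
        arch = decode_arch_string("1x8f8p1x4|1x2f16p1x1|1x1f4p1x1|2x1f8p2x1|1x1f4p1x1")
        c = parameter_count(arch)
        hand = 8 * 1 * 8 + 2 * 8 * 16 + 1 * 16 * 4 + 2 * 4 * 8 + 1 * 8 * 4
        assert c["conv_weights"] == hand
        assert c["dense_weights"] == 4 * 2

    def test_dense_head_bytes_q8(self):
        # a 16->2 dense head with bias at Q=8 contributes (16*2 + 2) bytes
        arch = decode_arch_string("1x1f4p1x1|1x1f4p1x1|1x1f4p1x1|1x1f4p1x1|1x1f16p1x1")
        with_head = model_size_bytes(arch, 8, count_bn=False)
        c = parameter_count(arch)
        assert with_head - c["conv_weights"] == 16 * 2 + 2 == 34

    def test_binary_payload_is_8x_smaller(self):
        arch = decode_arch_string("1x8f8p1x4|1x2f16p1x1|1x1f4p1x1|2x1f8p2x1|1x1f4p1x1")
        q8 = model_size_bytes(arch, 8, count_bn=False, with_dense_bias=False)
        q1 = model_size_bytes(arch, 1, count_bn=False, with_dense_bias=False)
        n = parameter_count(arch)["total_weights"]
        assert q8 == n
        assert q1 == -(-n // 8)
        if n % 8 == 0:
            assert q8 == 8 * q1

    def test_monotone_in_q(self):
        arch = decode_arch([1] * 15)
        sizes = [model_size_bytes(arch, q) for q in (1, 2, 4, 8)]
        assert sizes == sorted(sizes)


class TestChannelIndependence:
    def test_zeroing_one_channel_only_affects_that_channel(self, rng):
        """Temporal blocks must process channels independently."""
        arch = decode_arch_string("1x8f8p1x4|1x2f8p1x4|1x1f4p1x1|1x1f4p1x1|1x1f4p1x1")
        net = build_model(arch, (6, 512), seed=1)
        x = rng.normal(size=(1, 1, 6, 512))
        x2 = x.copy()
        x2[:, :, 3, :] = 0.0

        def maps_through_temporal(z):
            outs = []
            for conv, bn, act, pool in net.block_index[:3]:
                for lyr in (conv, bn, act, pool):
                    z = lyr.forward(z, training=False)
                outs.append(z)
            return outs

        for a, b in zip(maps_through_temporal(x), maps_through_temporal(x2)):
            diff = np.abs(a - b).sum(axis=(0, 1, 3))  # per channel row
            assert diff[3] > 0
            others = np.delete(diff, 3)
            assert np.allclose(others, 0.0)


def test_softmax_output_normalized(rng):
    arch = decode_arch([0] * 15)
    net = build_model(arch, (4, 64), seed=0)
    p = net.predict_proba(rng.normal(size=(5, 4, 64)))
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(p >= 0)
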
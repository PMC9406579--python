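"""Architecture contracts: block semantics, attention behaviour, shape
round-trips, and the analytic parameter-count oracle."""

import numpy as np
import pytest

from rdaunet import (
    ArchitectureConfig,
    ConfigurationError,
    RDAUNet,
    ShapeError,
    build_attention_gate,
    build_dense_block,
    build_res_block,
    build_rda_unet,
    count_parameters,
    describe,
)
from rdaunet.architecture import forward
from rdaunet.nn import Tensor, bce_loss


# ----------------------------------------------------- analytic param oracle
def conv_params(k, cin, cout, bias=True):
    return k * k * cin * cout + (cout if bias else 0)


def res_block_params(cin, cout, norm=True):
    total = conv_params(3, cin, cout) + conv_params(3, cout, cout)
    if norm:
        total += 2 * cout + 2 * cout
    if cin != cout:
        total += conv_params(1, cin, cout)
    return total


def dense_block_params(cin, layers, growth, norm=True):
    total = 0
    for i in range(layers):
        total += conv_params(3, cin + i * growth, growth)
        if norm:
            total += 2 * growth
    return total


def attention_gate_params(skip, gate, inter):
    return (
        conv_params(1, gate, inter)  # w_gate, with bias
        + conv_params(1, skip, inter, bias=False)  # strided w_skip
        + conv_params(1, inter, 1)  # psi
    )


def analytic_unet_params(cfg: ArchitectureConfig) -> int:
    """Closed-form layer-by-layer summation following the documented layout."""
    norm = cfg.norm == "batchnorm"
    total = 0
    channels = cfg.input_channels
    skips = []
    for level in range(cfg.depth + 1):  # encoder levels + bottleneck
        width = cfg.base_filters * 2**level
        growth = cfg.growth_rate if cfg.growth_rate is not None else max(1, width // 2)
        total += res_block_params(channels, width, norm)
        total += dense_block_params(width, cfg.dense_layers, growth, norm)
        channels = width + cfg.dense_layers * growth
        if level < cfg.depth:
            skips.append(channels)
    for level in range(cfg.depth - 1, -1, -1):
        width = cfg.base_filters * 2**level
        skip = skips[level]
        inter = (
            cfg.attention_inter_channels
            if cfg.attention_inter_channels is not None
            else max(1, skip // 2)
        )
        total += 4 * channels * width + width  # transposed conv 2x2 + bias
        total += attention_gate_params(skip, channels, inter)
        total += conv_params(3, width + skip, width) + conv_params(3, width, width)
        if norm:
            total += 4 * width
        channels = width
    total += conv_params(1, channels, cfg.output_channels)
    return total


# ------------------------------------------------------------------ ResBlock
class TestResBlock:
    def test_zeroed_residual_branch_is_identity(self, rng):
        block = build_res_block(8, 8, seed=3)
        block.zero_residual_branch()
        block.eval()
        x = rng.normal(size=(2, 8, 16, 16)).astype(np.float32)
        out = block(Tensor(x)).data
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_shape_preserved(self, rng):
        block = build_res_block(8, 8, seed=0).eval()
        out = block(Tensor(rng.normal(size=(1, 8, 32, 32)).astype(np.float32)))
        assert out.shape == (1, 8, 32, 32)

    def test_channel_change_uses_1x1_shortcut(self):
        block = build_res_block(8, 16, seed=0)
        assert block.shortcut.weight.size + block.shortcut.bias.size == 8 * 16 + 16


# ---------------------------------------------------------------- DenseBlock
class TestDenseBlock:
    def test_empty_block_is_identity(self, rng):
        block = build_dense_block(8, layers=0, growth_rate=4, seed=0)
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(block(Tensor(x)).data, x)

    @pytest.mark.parametrize("cin,layers,growth", [(16, 4, 8), (8, 2, 4), (3, 5, 7)])
    def test_output_channel_arithmetic(self, rng, cin, layers, growth):
        block = build_dense_block(cin, layers, growth, seed=1).eval()
        out = block(Tensor(rng.normal(size=(1, cin, 8, 8)).astype(np.float32)))
        assert out.shape[1] == cin + layers * growth == block.out_channels

    def test_dense_connectivity_ablation(self, rng):
        """Perturbing the first dense layer changes the input to every later
        layer (each layer consumes the concatenation of all predecessors)."""
        x = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        block = build_dense_block(8, layers=4, growth_rate=4, seed=2).eval()

        def layer_inputs():
            feats = [x]
            inputs = []
            from rdaunet import nn

            for conv, norm in zip(block.convs, block.norms):
                inp = feats[0] if len(feats) == 1 else nn.concatenate(feats, axis=1)
                inputs.append(inp.data.copy())
                feats.append(block.act(norm(conv(inp))))
            return inputs

        before = layer_inputs()
        block.convs[0].weight.data += 1.0  # perturb layer 1's output
        after = layer_inputs()
        for i in range(1, 4):  # layers 2..L see the perturbation
            assert not np.allclose(before[i], after[i])
        np.testing.assert_array_equal(before[0], after[0])  # layer 1 input unchanged


# ------------------------------------------------------------- AttentionGate
class TestAttentionGate:
    def test_saturated_open_gate_passes_skip_through(self, rng):
        gate = build_attention_gate(4, 8, seed=0)
        gate.psi.bias.data[:] = 20.0  # alpha -> 1
        x = Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        out = gate(x, g).data
        assert np.max(np.abs(out - x.data)) < 1e-6 * max(1.0, np.abs(x.data).max())

    def test_saturated_closed_gate_suppresses_skip(self, rng):
        gate = build_attention_gate(4, 8, seed=0)
        gate.psi.bias.data[:] = -20.0  # alpha -> 0
        x = Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        assert np.max(np.abs(gate(x, g).data)) < 1e-6

    def test_coefficients_in_open_unit_interval(self, rng):
        gate = build_attention_gate(6, 12, seed=4)
        x = Tensor(rng.normal(size=(2, 6, 16, 16)).astype(np.float32))
        g = Tensor(rng.normal(size=(2, 12, 8, 8)).astype(np.float32))
        alpha = gate.attention_coefficients(x, g).data
        assert np.all((alpha > 0.0) & (alpha < 1.0))

    def test_wrong_spatial_ratio_rejected(self, rng):
        gate = build_attention_gate(4, 8, seed=0)
        x = Tensor(np.zeros((1, 4, 16, 16), dtype=np.float32))
        g = Tensor(np.zeros((1, 8, 16, 16), dtype=np.float32))
        with pytest.raises(ShapeError):
            gate(x, g)


# -------------------------------------------------------------------- U-Net
class TestRDAUNet:
    def test_default_forward_contract_at_224(self, rng):
        net = build_rda_unet(seed=0)
        out = forward(net, rng.normal(size=(1, 224, 224)).astype(np.float32))
        assert out.shape == (1, 224, 224)
        assert np.all((out > 0.0) & (out < 1.0))

    @pytest.mark.parametrize("size,depth", [(64, 3), (128, 4)])
    def test_shape_contract_small_sizes(self, rng, size, depth):
        cfg = ArchitectureConfig(input_size=size, depth=depth, base_filters=4, dense_layers=2)
        net = build_rda_unet(cfg, seed=1)
        out = forward(net, rng.normal(size=(2, size, size)).astype(np.float32))
        assert out.shape == (2, size, size)
        assert np.all((out > 0.0) & (out < 1.0))

    def test_one_attention_gate_per_decoder_stage(self):
        cfg = ArchitectureConfig(input_size=64, depth=3, base_filters=4, dense_layers=1)
        net = build_rda_unet(cfg, seed=0)
        assert len(net.attention_gates) == 3

    def test_not_degenerate_at_initialization(self):
        cfg = ArchitectureConfig(input_size=32, depth=2, base_filters=4, dense_layers=1)
        net = build_rda_unet(cfg, seed=0)
        zero = forward(net, np.zeros((1, 32, 32), dtype=np.float32))
        one = forward(net, np.ones((1, 32, 32), dtype=np.float32))
        assert not np.allclose(zero, one)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ConfigurationError):
            ArchitectureConfig(input_size=100, depth=3).validate()

    def test_wrong_input_size_raises_shape_error(self):
        cfg = ArchitectureConfig(input_size=32, depth=2, base_filters=4, dense_layers=1)
        net = build_rda_unet(cfg, seed=0)
        with pytest.raises(ShapeError):
            net(Tensor(np.zeros((1, 1, 16, 16), dtype=np.float32)))

    def test_batch_order_equivariance(self, rng):
        cfg = ArchitectureConfig(input_size=32, depth=2, base_filters=4, dense_layers=1)
        net = build_rda_unet(cfg, seed=0)
        batch = rng.normal(size=(3, 32, 32)).astype(np.float32)
        out = forward(net, batch)
        out_perm = forward(net, batch[[2, 0, 1]])
        np.testing.assert_allclose(out_perm, out[[2, 0, 1]], atol=1e-6)


# --------------------------------------------------------------- parameters
class TestParameterCount:
    def test_single_conv_closed_form(self):
        from rdaunet import nn

        conv = nn.Conv2d(1, 8, 3)
        assert count_parameters(conv) == 80  # 3*3*1*8 + 8

    @pytest.mark.parametrize(
        "cfg",
        [
            ArchitectureConfig(input_size=64, depth=3, base_filters=8),
            ArchitectureConfig(input_size=32, depth=2, base_filters=4, dense_layers=2),
            ArchitectureConfig(input_size=224, depth=4, base_filters=16),
            ArchitectureConfig(input_size=64, depth=2, base_filters=6, dense_layers=3, norm="none"),
        ],
    )
    def test_matches_analytic_summation(self, cfg):
        net = RDAUNet(cfg, seed=0)
        assert count_parameters(net) == analytic_unet_params(cfg)

    def test_doubling_base_filters_roughly_quadruples(self):
        a = analytic_unet_params(ArchitectureConfig(input_size=64, depth=3, base_filters=8))
        b = analytic_unet_params(ArchitectureConfig(input_size=64, depth=3, base_filters=16))
        assert 3.5 < b / a < 4.5

    def test_describe_manifest_totals(self):
        cfg = ArchitectureConfig(input_size=32, depth=2, base_filters=4, dense_layers=1)
        net = RDAUNet(cfg, seed=0)
        tsv = describe(net)
        lines = [l for l in tsv.strip().splitlines()[1:] if l]
        total_row = lines[-1]
        assert int(total_row.split("\t")[-1]) == count_parameters(net)
        # per-node params on distinct leaf modules sum to the total
        seen, acc = set(), 0
        for line in lines[:-1]:
            node, typ, shape, params = line.split("\t")
            if node not in seen:
                seen.add(node)
                acc += int(params)
        assert acc == count_parameters(net)


def test_end_to_end_gradient_check(rng):
    """Finite differences through the whole network on a 16x16 config.

    The loss surface has ReLU/max-pool kinks, so each probe first verifies
    that the central-difference estimate is itself stable across two step
    sizes before comparing it with the analytic gradient.
    """
    cfg = ArchitectureConfig(
        input_size=16, depth=2, base_filters=2, dense_layers=1, norm="none"
    )
    net = RDAUNet(cfg, seed=0).train()
    for p in net.parameters():
        p.data = p.data.astype(np.float64)
    x = Tensor(rng.normal(size=(2, 1, 16, 16)))
    y = (rng.random((2, 1, 16, 16)) > 0.5).astype(np.float64)

    def loss():
        return bce_loss(net(x), y)

    loss().backward()

    def central_diff(p, idx, eps):
        orig = p.data[idx]
        p.data[idx] = orig + eps
        lp = float(loss().data)
        p.data[idx] = orig - eps
        lm = float(loss().data)
        p.data[idx] = orig
        return (lp - lm) / (2 * eps)

    params = net.parameters()
    checked = 0
    for p in [params[0], params[len(params) // 3], params[len(params) // 2], params[-1], params[-2]]:
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in p.data.shape)
            fd_a = central_diff(p, idx, 1e-5)
            fd_b = central_diff(p, idx, 1e-6)
            if abs(fd_a) < 1e-8 or abs(fd_a - fd_b) / abs(fd_a) > 1e-5:
                continue  # near-zero or kink-contaminated probe
            assert abs(float(p.grad[idx]) - fd_a) / abs(fd_a) < 1e-4
            checked += 1
    assert checked >= 5
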
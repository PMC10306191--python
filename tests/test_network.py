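"""Recurrent network simulator: determinism, sequences, state carry-over."""

import numpy as np
import pytest

from rsvpsim import (
    AdaptationParams,
    ConfigError,
    LayerSpec,
    NetworkConfig,
    ShapeError,
    build_network,
    get_preset,
    make_sequence,
)


def dense_config(lateral=False, adaptation=None, seed=0, units=12,
                 input_shape=(1, 4, 4), readout=6):
    return NetworkConfig(
        input_shape=input_shape,
        layer_specs=[LayerSpec(kind="dense", units=units, lateral=lateral)],
        readout_dim=readout,
        adaptation=adaptation or AdaptationParams(),
        seed=seed,
    )


@pytest.fixture()
def frames(rng):
    return rng.uniform(0, 1, (3, 1, 4, 4))


class TestMakeSequence:
    def test_six_images_four_steps(self, rng):
        seq = make_sequence(list(rng.uniform(0, 1, (6, 1, 4, 4))), 4)
        assert seq.n_steps == 24

    def test_single_image_single_step(self, rng):
        assert make_sequence([rng.uniform(0, 1, (1, 4, 4))], 1).n_steps == 1

    def test_step_to_image_map(self, frames):
        seq = make_sequence(list(frames), 2)
        np.testing.assert_array_equal(seq.step_to_image, [0, 0, 1, 1, 2, 2])

    def test_boundaries_tile_without_gaps(self, frames):
        seq = make_sequence(list(frames), 3)
        covered = []
        for i, first, last in seq.boundaries:
            covered.extend(range(first, last))
            assert np.all(seq.step_to_image[first:last] == i)
        assert covered == list(range(seq.n_steps))

    def test_heterogeneous_shapes_rejected(self, rng):
        with pytest.raises(ShapeError):
            make_sequence([rng.uniform(0, 1, (1, 4, 4)),
                           rng.uniform(0, 1, (1, 5, 5))], 2)

    def test_empty_rejected(self):
        with pytest.raises(ShapeError):
            make_sequence([], 1)


class TestBuild:
    def test_identical_seeds_identical_outputs(self, frames):
        seq = make_sequence(list(frames), 2)
        t1 = build_network(dense_config(seed=5)).run_sequential(seq)
        t2 = build_network(dense_config(seed=5)).run_sequential(seq)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_beta_zero_equals_none_bitwise(self, frames):
        seq = make_sequence(list(frames), 3)
        b0 = AdaptationParams("exponential", (0.96,), 0.0)
        t1 = build_network(dense_config(lateral=True, adaptation=b0,
                                        seed=2)).run_sequential(seq)
        t2 = build_network(dense_config(lateral=True, seed=2)).run_sequential(seq)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_identity_network_reproduces_input(self):
        cfg = NetworkConfig(
            input_shape=(4,),
            layer_specs=[LayerSpec(kind="dense", units=4)],
            readout_dim=4,
        )
        net = build_network(cfg)
        net.layers[0].W = np.eye(4)
        net.readout_W = np.eye(4)
        x = np.array([0.1, 0.4, 0.0, 0.9])
        trace = net.run_single_image(x, 1)
        np.testing.assert_allclose(trace.values[0], x, rtol=1e-12)

    @pytest.mark.parametrize(
        "kwargs", [dict(layer_specs=[]), dict(readout_dim=1)]
    )
    def test_invalid_config_rejected(self, kwargs):
        base = dict(
            input_shape=(1, 4, 4),
            layer_specs=[LayerSpec(kind="dense", units=4)],
            readout_dim=6,
        )
        with pytest.raises(ConfigError):
            NetworkConfig(**{**base, **kwargs})

    def test_frame_shape_mismatch(self, rng):
        net = build_network(dense_config())
        with pytest.raises(ShapeError):
            net.run_single_image(rng.uniform(0, 1, (1, 5, 5)), 1)


class TestRuns:
    def test_single_image_equals_one_image_sequential(self, frames):
        net = build_network(dense_config(lateral=True,
                                         adaptation=get_preset("powerlaw-paper")))
        t1 = net.run_single_image(frames[0], 5)
        t2 = net.run_sequential(make_sequence([frames[0]], 5))
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_memoryless_network_repeats_outputs(self, frames):
        net = build_network(dense_config(lateral=False))
        trace = net.run_sequential(make_sequence(list(frames), 4))
        for _, first, last in make_sequence(list(frames), 4).boundaries:
            block = trace.values[first:last]
            assert np.ptp(block, axis=0).max() == 0.0

    def test_recurrence_carries_history(self, frames):
        net = build_network(dense_config(lateral=True, seed=9))
        with_a = net.run_sequential(make_sequence([frames[0], frames[1]], 2))
        fresh = net.run_sequential(make_sequence([frames[1]], 2))
        assert not np.allclose(with_a.values[2:], fresh.values)

    @pytest.mark.parametrize(
        "lateral,adaptation,expect_equal",
        [
            (False, AdaptationParams(), True),
            (True, AdaptationParams(), False),
            (False, AdaptationParams("exponential", (0.96,), 0.7), False),
        ],
    )
    def test_reset_equivalence(self, frames, lateral, adaptation, expect_equal):
        """Concatenated single-image runs equal the sequential run exactly
        when no state can carry over, and differ when it can."""
        net = build_network(dense_config(lateral=lateral, adaptation=adaptation,
                                         seed=4))
        seq = net.run_sequential(make_sequence(list(frames), 3)).values
        cat = np.vstack(
            [net.run_single_image(f, 3).values for f in frames]
        )
        assert np.array_equal(seq, cat) == expect_equal

    def test_readout_is_linear(self, rng):
        net = build_network(dense_config())
        h = rng.uniform(0, 1, 12)
        np.testing.assert_allclose(net.readout(2 * h), 2 * net.readout(h),
                                   rtol=1e-12)

    def test_step_count_conservation(self, frames):
        trace = build_network(dense_config()).run_sequential(
            make_sequence(list(frames), 7)
        )
        assert trace.n_steps == 3 * 7
        assert len(trace.step_to_image) == 21


class TestConvAndNormalization:
    def test_conv_network_runs_and_is_deterministic(self, rng):
        cfg = NetworkConfig(
            input_shape=(1, 6, 6),
            layer_specs=[
                LayerSpec(kind="conv", units=3, kernel_size=3, lateral=True),
                LayerSpec(kind="dense", units=8),
            ],
            readout_dim=4,
            adaptation=get_preset("exponential-vinken"),
            seed=11,
        )
        frames = rng.uniform(0, 1, (2, 1, 6, 6))
        t1 = build_network(cfg).run_sequential(make_sequence(list(frames), 2))
        t2 = build_network(cfg).run_sequential(make_sequence(list(frames), 2))
        np.testing.assert_array_equal(t1.values, t2.values)
        assert t1.values.shape == (4, 4)

    def test_frozen_statistics_standardize_calibration_batch(self, rng):
        cfg = dense_config(units=10, input_shape=(1, 5, 5), seed=6)
        net = build_network(cfg)
        batch = rng.uniform(0, 1, (40, 1, 5, 5))
        net.freeze_normalization(batch, at_step=1)
        pres = []
        for im in batch:
            state = net.init_state()
            _, _, pre = net.step(im, state, collect="pre")
            pres.append(pre[0])
        pres = np.stack(pres)
        np.testing.assert_allclose(pres.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(pres.std(axis=0), 1.0, atol=1e-4)

    def test_trace_tidy_export(self, frames):
        trace = build_network(dense_config()).run_sequential(
            make_sequence(list(frames), 2)
        )
        df = trace.to_frame()
        assert set(df.columns) == {"step", "image_index", "category",
                                   "activation"}
        assert len(df) == trace.n_steps * trace.n_categories
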
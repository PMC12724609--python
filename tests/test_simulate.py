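import math

import numpy as np
import pytest

from spillsmooth.aggregate import mean_aggregate
from spillsmooth.evaluate import auroc
from spillsmooth.model import IntensityImage
from spillsmooth.morphology import boundary_labels
from spillsmooth.simulate import (
    ChannelSpec,
    SimulationConfig,
    assign_classes,
    downsample_intensity,
    downsample_mask,
    draw_cell_means,
    generate_label_volume,
    poissonize_image,
    sample_counts,
    simulate_dataset,
)


class TestGeometry:
    def test_dense_packing_and_calibration(self):
        cfg = SimulationConfig(seed=4)
        vol = generate_label_volume(cfg)
        sl = vol[0]
        assert (sl == 0).mean() < 0.05  # essentially no background
        ids, counts = np.unique(sl, return_counts=True)
        areas = counts[ids > 0] / cfg.super_res_px_per_um**2
        assert len(areas) >= 500
        assert np.median(areas) == pytest.approx(31.0, rel=0.15)
        diam = 2 * np.sqrt(np.median(areas) / math.pi)
        assert diam == pytest.approx(6.0, rel=0.15)

    def test_single_slice_degenerate_stack(self):
        cfg = SimulationConfig(field_um=(40.0, 40.0), n_z_slices=1, seed=1)
        vol = generate_label_volume(cfg)
        assert vol.shape[0] == 1

    def test_seed_determinism(self):
        cfg = SimulationConfig(field_um=(40.0, 40.0), n_z_slices=3, seed=9)
        assert np.array_equal(generate_label_volume(cfg), generate_label_volume(cfg))

    def test_z_slices_correlated(self):
        cfg = SimulationConfig(field_um=(40.0, 40.0), n_z_slices=3, seed=2)
        vol = generate_label_volume(cfg)
        # adjacent slices share most of their labeling
        agree = (vol[0] == vol[1]).mean()
        assert agree > 0.5

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            generate_label_volume(
                SimulationConfig(field_um=(10.0, 10.0), target_median_area_um2=31.0)
            )


class TestTruth:
    def test_extreme_probabilities(self, rng):
        labels = np.arange(1, 101).reshape(10, 10)
        all_pos = assign_classes(labels, 1.0, rng, ["c"])
        all_neg = assign_classes(labels, 0.0, rng, ["c"])
        assert np.all(all_pos["class_c"] == 1)
        assert np.all(all_neg["class_c"] == 0)

    def test_binomial_fraction(self, rng):
        labels = np.arange(1, 1001).reshape(20, 50)
        truth = assign_classes(labels, 0.5, rng, ["c"])
        assert abs(truth["class_c"].mean() - 0.5) < 0.05  # 3 sigma

    def test_deterministic_channel_means(self, rng):
        labels = np.arange(1, 11).reshape(2, 5)
        spec = ChannelSpec("c", mu_neg=0.0, mu_pos=100.0, deterministic=True)
        truth = assign_classes(labels, 0.5, rng, ["c"])
        truth = draw_cell_means(truth, spec, rng)
        pos = truth["class_c"] == 1
        assert np.all(truth.loc[pos, "mean_c"] == 100.0)
        assert np.all(truth.loc[~pos, "mean_c"] == 0.0)

    def test_sigma_zero_degenerate_lognormal(self, rng):
        labels = np.arange(1, 11).reshape(2, 5)
        spec = ChannelSpec("c", mu_neg=0.5, mu_pos=1.3, sigma=0.0)
        truth = assign_classes(labels, 0.0, rng, ["c"])
        truth = draw_cell_means(truth, spec, rng)
        assert np.allclose(truth["mean_c"], math.exp(0.5))

    def test_truncated_normal_moment(self, rng):
        # closed-form mean of N(mu, sigma) truncated to [0, inf):
        # mu + sigma * phi(alpha) / (1 - Phi(alpha)), alpha = -mu/sigma
        labels = np.arange(1, 10_001).reshape(100, 100)
        mu, sigma = 0.5, 0.3
        spec = ChannelSpec("c", mu_neg=mu, mu_pos=1.3, sigma=sigma)
        truth = assign_classes(labels, 0.0, rng, ["c"])
        truth = draw_cell_means(truth, spec, rng)
        t = np.log(truth["mean_c"].to_numpy())
        alpha = -mu / sigma
        phi = math.exp(-0.5 * alpha * alpha) / math.sqrt(2 * math.pi)
        big_phi = 0.5 * (1 + math.erf(alpha / math.sqrt(2)))
        expected = mu + sigma * phi / (1 - big_phi)
        se = sigma / math.sqrt(len(t))
        assert abs(t.mean() - expected) < 4 * se


class TestRendering:
    def small_volume(self, seed=3, n_z=1):
        cfg = SimulationConfig(
            field_um=(30.0, 30.0), super_res_px_per_um=2, n_z_slices=n_z, seed=seed
        )
        return cfg, generate_label_volume(cfg)

    def test_deterministic_whole_cell_values_binary(self, rng):
        from spillsmooth.simulate import render_mean_intensity

        _, vol = self.small_volume()
        spec = ChannelSpec(
            "c", 0.0, 100.0, deterministic=True, offset=0.0, noise_amplitude=0.0
        )
        truth = draw_cell_means(assign_classes(vol, 0.5, rng, ["c"]), spec, rng)
        out = render_mean_intensity(vol, truth, spec)
        assert set(np.unique(out)) <= {0.0, 100.0}

    def test_membrane_interior_is_offset_only(self, rng):
        from spillsmooth.simulate import render_mean_intensity

        _, vol = self.small_volume()
        spec = ChannelSpec(
            "c", 0.0, 100.0, deterministic=True, localization="membrane",
            offset=0.25, noise_amplitude=0.0,
        )
        truth = draw_cell_means(assign_classes(vol, 1.0, rng, ["c"]), spec, rng)
        out = render_mean_intensity(vol, truth, spec)
        interior = (vol[0] > 0) & (boundary_labels(vol[0]) == 0)
        assert np.all(out[0][interior] == 0.25)

    def test_offset_is_global_minimum(self, rng):
        from spillsmooth.simulate import render_mean_intensity

        _, vol = self.small_volume()
        spec = ChannelSpec(
            "c", 1.0, 2.0, sigma=0.1, offset=0.1, noise_amplitude=0.0
        )
        truth = draw_cell_means(assign_classes(vol, 0.5, rng, ["c"]), spec, rng)
        out = render_mean_intensity(vol, truth, spec)
        assert out.min() >= 0.1


class TestDownsampling:
    def test_mask_identity(self):
        x = np.arange(16, dtype=np.int32).reshape(4, 4)
        assert np.array_equal(downsample_mask(x, 1), x)

    def test_mask_constant(self):
        x = np.full((2, 8, 8), 3, dtype=np.int32)
        assert np.all(downsample_mask(x, 2) == 3)

    def test_z_mode_majority(self):
        col = np.zeros((3, 1, 1), dtype=np.int32)
        col[:, 0, 0] = [1, 1, 2]
        assert downsample_mask(col, 1)[0, 0] == 1

    def test_z_mode_tie_smallest_label(self):
        col = np.zeros((2, 1, 1), dtype=np.int32)
        col[:, 0, 0] = [5, 2]
        assert downsample_mask(col, 1)[0, 0] == 2

    def test_intensity_identity_and_constant(self, rng):
        x = rng.uniform(0, 1, (6, 6))
        assert np.array_equal(downsample_intensity(x, 1), x)
        c = np.full((3, 4, 4), 2.5)
        assert np.allclose(downsample_intensity(c, 2), 2.5)

    def test_block_mean_value(self):
        x = np.array([[1.0, 2.0], [3.0, 6.0]])
        assert downsample_intensity(x, 2)[0, 0] == pytest.approx(3.0)

    def test_global_mean_conserved(self, rng):
        x = rng.uniform(0, 5, (3, 12, 12))
        out = downsample_intensity(x, 3)
        assert out.mean() == pytest.approx(x.mean(), rel=1e-9)

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            downsample_intensity(np.zeros((5, 5)), 2)
        with pytest.raises(ValueError):
            downsample_mask(np.zeros((5, 5), dtype=np.int32), 2)


class TestCounts:
    def test_zero_mean_zero_counts(self, rng):
        assert np.all(sample_counts(np.zeros((5, 5)), rng) == 0)

    def test_poisson_mean_clt_bound(self):
        rng = np.random.default_rng(0)
        counts = sample_counts(np.full((100, 100), 100.0), rng)
        assert abs(counts.mean() - 100.0) < 0.3

    def test_negative_mean_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_counts(np.array([[-1.0]]), rng)

    def test_seed_determinism(self):
        mean = np.full((10, 10), 3.0)
        a = sample_counts(mean, np.random.default_rng(5))
        b = sample_counts(mean, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_poissonize_pseudocount(self):
        rng = np.random.default_rng(1)
        img = IntensityImage(np.zeros((400, 250)))
        out = poissonize_image(img, rng, pseudo=0.5)
        assert abs(out.pixels.mean() - 0.5) < 0.01

    def test_poissonize_zero_pseudo(self, rng):
        img = IntensityImage(np.zeros((5, 5)))
        assert np.all(poissonize_image(img, rng, pseudo=0.0).pixels == 0)


class TestSimulateDataset:
    def test_end_to_end_determinism(self):
        cfg = SimulationConfig(field_um=(40.0, 40.0), super_res_px_per_um=2, seed=8)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        assert np.array_equal(d1.mask.labels, d2.mask.labels)
        for name in d1.counts:
            assert np.array_equal(d1.counts[name].pixels, d2.counts[name].pixels)
        assert d1.truth.equals(d2.truth)

    def test_full_resolution_noise_free_perfect_auroc(self):
        det = ChannelSpec(
            "det", 0.0, 100.0, deterministic=True, offset=0.0, noise_amplitude=0.0
        )
        cfg = SimulationConfig(
            field_um=(40.0, 40.0), super_res_px_per_um=2, channels=[det], seed=6
        )
        ds = simulate_dataset(cfg)
        means = mean_aggregate(ds.noise_free["det"], ds.mask)
        truth = ds.truth.set_index("cell_id")["class_det"]
        assert auroc(means.to_numpy(), truth.loc[means.index].to_numpy()) == 1.0

    def test_membrane_mean_matches_boundary_fraction(self):
        det = ChannelSpec(
            "det", 0.0, 100.0, deterministic=True, localization="membrane",
            offset=0.0, noise_amplitude=0.0,
        )
        cfg = SimulationConfig(
            field_um=(40.0, 40.0), super_res_px_per_um=2, channels=[det],
            p_positive=1.0, seed=13,
        )
        ds = simulate_dataset(cfg)
        means = mean_aggregate(ds.noise_free["det"], ds.mask)
        rings = boundary_labels(ds.mask.labels)
        for cid in ds.mask.cell_ids()[:20]:
            area = int((ds.mask.labels == cid).sum())
            ring = int((rings == cid).sum())
            assert means.loc[cid] == pytest.approx(100.0 * ring / area)
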
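import numpy as np
import pytest

from fetalt2star import (
    AcquisitionSpec,
    PhantomSpec,
    TissueParams,
    add_rician_noise,
    build_label_volume,
    lookup_reference_t2star,
    render_multiecho,
    sample_slice_stack,
    simulate_signal,
)
from fetalt2star.phantom import add_gaussian_noise
from fetalt2star.reference import BIN_MIDPOINTS, REFERENCE_T2STAR, REGIONS


class TestAcquisitionSpec:
    def test_defaults_match_protocol(self):
        acq = AcquisitionSpec()
        assert acq.echo_times == (42.0, 107.0, 172.0)
        assert acq.in_plane_resolution == 3.0
        assert acq.slice_thickness == 3.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(echo_times=(42.0, 42.0, 172.0)),
            dict(echo_times=(172.0, 107.0, 42.0)),
            dict(echo_times=(-5.0, 42.0)),
            dict(n_dynamics=0),
            dict(in_plane_resolution=0.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionSpec(**kwargs)


class TestLabelVolume:
    def test_seven_regions_plus_background(self):
        lv = build_label_volume(PhantomSpec(gestational_age=30, grid_shape=(64,) * 3, seed=1))
        assert set(np.unique(lv.labels)) == set(range(8))

    def test_deterministic(self):
        spec = PhantomSpec(gestational_age=30, grid_shape=(48,) * 3, seed=1)
        assert np.array_equal(build_label_volume(spec).labels, build_label_volume(spec).labels)

    def test_brain_grows_with_gestational_age(self):
        counts = [
            int((build_label_volume(PhantomSpec(gestational_age=ga, grid_shape=(48,) * 3)).labels > 0).sum())
            for ga in range(20, 41, 2)
        ]
        assert all(b > a for a, b in zip(counts, counts[1:]))

    def test_too_small_grid_names_missing_region(self):
        with pytest.raises(ValueError, match="region"):
            build_label_volume(PhantomSpec(gestational_age=20, grid_shape=(10, 10, 10)))

    def test_all_regions_inside_grid_bounds(self):
        for ga in (20.0, 40.0):
            lv = build_label_volume(PhantomSpec(gestational_age=ga, grid_shape=(48,) * 3))
            edge = np.zeros(lv.labels.shape, bool)
            edge[[0, -1], :, :] = edge[:, [0, -1], :] = edge[:, :, [0, -1]] = True
            assert (lv.labels[edge] == 0).all()


class TestReferenceLookup:
    def test_bin_midpoints_reproduce_table_exactly(self):
        for region in REGIONS:
            for mid, mean in zip(BIN_MIDPOINTS, REFERENCE_T2STAR[region]["mean"]):
                assert lookup_reference_t2star(region, float(mid)) == pytest.approx(mean)

    def test_published_anchor_values(self):
        assert lookup_reference_t2star("white_matter", 27.0) == pytest.approx(331.6)
        assert lookup_reference_t2star("brainstem", 39.0) == pytest.approx(149.6)

    def test_interpolation_between_bins(self):
        # halfway between the 20-22 and 22-24 cerebellum means
        expected = (315.8 + 337.4) / 2.0
        assert lookup_reference_t2star("cerebellum", 22.0) == pytest.approx(expected)

    def test_constant_extrapolation_within_range(self):
        assert lookup_reference_t2star("eCSF", 20.0) == lookup_reference_t2star("eCSF", 21.0)
        assert lookup_reference_t2star("eCSF", 40.0) == lookup_reference_t2star("eCSF", 39.0)

    def test_range_errors(self):
        with pytest.raises(ValueError):
            lookup_reference_t2star("eCSF", 19.9)
        with pytest.raises(ValueError):
            lookup_reference_t2star("eCSF", 40.1)
        with pytest.raises(KeyError):
            lookup_reference_t2star("cortex", 30.0)


class TestSignalModel:
    def test_te_zero_returns_s0(self):
        assert simulate_signal(1000.0, 123.0, [0.0])[0] == pytest.approx(1000.0)

    def test_e_folding(self):
        assert simulate_signal(1000.0, 107.0, [107.0])[0] == pytest.approx(1000.0 / np.e)

    def test_matches_direct_exponential(self):
        te = np.array([42.0, 107.0, 172.0])
        got = simulate_signal(1000.0, 250.0, te)
        assert np.allclose(got, 1000.0 * np.exp(-te / 250.0), rtol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            simulate_signal(1000.0, 0.0, [42.0])
        with pytest.raises(ValueError):
            simulate_signal(-1.0, 100.0, [42.0])


class TestNoise:
    def test_sigma_zero_is_identity(self):
        x = np.linspace(0, 10, 32)
        assert np.array_equal(add_rician_noise(x, 0.0, seed=3), x)

    def test_seed_determinism(self):
        x = np.ones((8, 8))
        assert np.array_equal(add_rician_noise(x, 2.0, seed=5), add_rician_noise(x, 2.0, seed=5))

    def test_rayleigh_mean_at_zero_signal(self, rng):
        # magnitude noise on zero signal is Rayleigh with mean sigma*sqrt(pi/2)
        sigma = 3.0
        draws = add_rician_noise(np.zeros(200_000), sigma, seed=11)
        assert draws.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.01)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -1.0)
        with pytest.raises(ValueError):
            add_gaussian_noise(np.ones(3), -1.0)


class TestRenderMultiecho:
    def test_uniform_regions_and_background(self, phantom48):
        _, labels, tissue, volume = phantom48
        for region in REGIONS:
            mask = labels.region_mask(region)
            for e in range(3):
                vals = volume.data[..., e][mask]
                assert np.allclose(vals, vals.flat[0])
        assert np.all(volume.data[labels.labels == 0] == 0)

    def test_decay_ratio_matches_formula(self, phantom48):
        _, labels, tissue, volume = phantom48
        for region in REGIONS:
            mask = labels.region_mask(region)
            ratio = volume.data[..., 2][mask].mean() / volume.data[..., 0][mask].mean()
            assert ratio == pytest.approx(np.exp(-130.0 / tissue.t2star[region]), rel=1e-9)

    def test_s0_scaling_invariance(self, phantom48):
        spec, labels, tissue, volume = phantom48
        scaled = TissueParams(
            t2star=dict(tissue.t2star), s0={k: 3.0 * v for k, v in tissue.s0.items()}
        )
        vol2 = render_multiecho(labels, scaled, AcquisitionSpec())
        assert np.allclose(vol2.data, 3.0 * volume.data, rtol=1e-12)

    def test_missing_tissue_parameters(self, phantom48):
        _, labels, tissue, _ = phantom48
        broken = TissueParams(
            t2star={k: v for k, v in tissue.t2star.items() if k != "brainstem"},
            s0=dict(tissue.s0),
        )
        with pytest.raises(KeyError, match="brainstem"):
            render_multiecho(labels, broken, AcquisitionSpec())


class TestSliceStack:
    def test_slice_count_is_dynamics_times_slices(self):
        # 90 mm of coverage at 3 mm thickness -> 30 slices; 15 dynamics -> 450
        spec = PhantomSpec(gestational_age=30, grid_shape=(48, 48, 75), seed=2)
        labels = build_label_volume(spec)
        volume = render_multiecho(labels, TissueParams.from_reference(30), AcquisitionSpec())
        stacks = sample_slice_stack(volume, AcquisitionSpec(n_dynamics=15), seed=2)
        assert len(stacks) == 3
        assert stacks[0].n_slices == 30
        assert stacks[0].n_dynamics * stacks[0].n_slices == 450

    def test_transforms_shared_across_echoes(self, phantom48):
        _, _, _, volume = phantom48
        stacks = sample_slice_stack(
            volume, AcquisitionSpec(n_dynamics=2), motion_amplitude=(4, 4), seed=9
        )
        assert np.array_equal(stacks[0].transforms, stacks[1].transforms)
        assert np.array_equal(stacks[0].transforms, stacks[2].transforms)

    def test_deterministic_given_seed(self, phantom48):
        _, _, _, volume = phantom48
        a = sample_slice_stack(volume, AcquisitionSpec(n_dynamics=1), (2, 2), seed=4, noise_sigma=5.0)
        b = sample_slice_stack(volume, AcquisitionSpec(n_dynamics=1), (2, 2), seed=4, noise_sigma=5.0)
        assert np.array_equal(a[0].data, b[0].data)

    def test_motion_free_interior_plateau(self, phantom48):
        """Deep inside a homogeneous region, PSF integration preserves the value."""
        from scipy.ndimage import binary_erosion

        _, labels, tissue, volume = phantom48
        acq = AcquisitionSpec(in_plane_resolution=1.2, slice_thickness=1.2, n_dynamics=1)
        stacks = sample_slice_stack(volume, acq, seed=0)
        stack = stacks[0]
        wm_value = simulate_signal(tissue.s0["white_matter"], tissue.t2star["white_matter"],
                                   [acq.echo_times[0]])[0]
        interior = binary_erosion(labels.region_mask("white_matter"), iterations=3)
        assert interior.any()
        i, j, k = (int(c[0]) for c in np.nonzero(interior))
        world = labels.affine[:3, :3] @ np.array([i, j, k], float) + labels.affine[:3, 3]
        px = int(np.argmin(np.abs(stack.pixel_x - world[0])))
        py = int(np.argmin(np.abs(stack.pixel_y - world[1])))
        pz = int(np.argmin(np.abs(stack.slice_z - world[2])))
        assert stack.data[0, pz, py, px] == pytest.approx(wm_value, rel=0.02)

    def test_negative_amplitude_rejected(self, phantom48):
        _, _, _, volume = phantom48
        with pytest.raises(ValueError):
            sample_slice_stack(volume, AcquisitionSpec(), motion_amplitude=(-1, 0), seed=0)

    def test_acquisition_cannot_be_finer_than_phantom(self, phantom48):
        _, _, _, volume = phantom48
        acq = AcquisitionSpec(in_plane_resolution=0.6, slice_thickness=0.6)
        with pytest.raises(ValueError):
            sample_slice_stack(volume, acq, seed=0)
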
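"""Generator ground truth: placement statistics, rendering, plate layout."""

import numpy as np
import pytest

from chinassay.image_io import read_zstack
from chinassay.synthetic_plate import (
    LarvaModel,
    PlateLayout,
    SceneParams,
    generate_larva,
    generate_plate,
    render_zstack,
    small_scene,
    well_rng,
)


def _point_larva(scene, pos, peak, sigma=3.0):
    h, w = scene.image_shape
    return LarvaModel(
        body_axis=((h / 2, 20.0), (h / 2, w - 20.0)),
        body_half_height=scene.body_half_height,
        neuromast_centers=[],
        neuromast_radius=scene.neuromast_radius,
        leukocytes=[(pos, peak, sigma)],
        orientation_ok=True,
        condition_label="control",
    )


class TestGenerateLarva:
    def test_zero_dose_gives_baseline_only(self):
        """At dose 0 no recruitment occurs: counts match the ventral baseline."""
        params = small_scene(baseline_count=10.0)
        totals, near = [], []
        for s in range(300):
            larva = generate_larva(params, "copper", well_rng(1, 1, s), dose=0.0)
            totals.append(larva.n_leukocytes)
            near.append(larva.leukocytes_near_neuromasts())
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 10.0) <= 3 * se
        # ventral cells sit below the myoseptum; near-neuromast hits are rare
        assert np.mean(near) < 0.15 * np.mean(totals)

    def test_poisson_recruitment_mean(self):
        """recruit_mean=5 over 7 neuromasts: empirical mean within 3 SE of 35."""
        params = small_scene(recruit_mean=5.0, baseline_count=0.0)
        totals = [
            generate_larva(params, "copper", well_rng(2, 1, s)).n_leukocytes
            for s in range(1000)
        ]
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 35.0) <= 3 * se

    def test_recruited_cells_near_neuromasts(self):
        params = small_scene(recruit_mean=5.0, baseline_count=0.0)
        larva = generate_larva(params, "copper", well_rng(3, 1, 0))
        assert larva.leukocytes_near_neuromasts() == larva.n_leukocytes

    @pytest.mark.parametrize("prob,expected", [(1.0, True), (0.0, False)])
    def test_degenerate_orientation_probability(self, prob, expected):
        params = small_scene(lateral_orientation_prob=prob)
        for s in range(20):
            larva = generate_larva(params, "control", well_rng(4, 1, s))
            assert larva.orientation_ok is expected

    def test_negative_dose_rejected(self):
        params = small_scene()
        with pytest.raises(ValueError, match="dose"):
            generate_larva(params, "copper", well_rng(5, 1, 0), dose=-1.0)

    def test_neuromasts_on_axis_ordered_and_spaced(self):
        params = small_scene()
        for s in range(20):
            larva = generate_larva(params, "copper", well_rng(6, 1, s), dose=10.0)
            p0 = np.array(larva.body_axis[0])
            p1 = np.array(larva.body_axis[1])
            u = (p1 - p0) / np.linalg.norm(p1 - p0)
            centers = np.array(larva.neuromast_centers)
            rel = centers - p0
            perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
            assert perp.max() <= 1.0
            t = rel @ u
            assert np.all(np.diff(t) >= 4 * params.neuromast_radius - 1e-9)
            h, w = params.image_shape
            assert np.all((centers >= 0) & (centers <= [h - 1, w - 1]))

    def test_all_positions_inside_frame(self):
        params = small_scene(lateral_orientation_prob=0.0)  # steep tilts
        h, w = params.image_shape
        for s in range(20):
            larva = generate_larva(params, "copper", well_rng(7, 1, s), dose=10.0)
            pts = np.array([p for p, _, _ in larva.leukocytes] + larva.neuromast_centers)
            assert np.all((pts >= 0) & (pts <= [h - 1, w - 1]))

    def test_dose_response_monotone(self):
        """Seed-averaged near-neuromast counts are non-decreasing in dose."""
        params = small_scene(baseline_count=0.0, rmax=8.0, k50=1.0)
        assert params.recruit_at(0.0) == 0.0
        means = []
        for dose in [0.0, 0.3, 1.0, 3.0, 10.0]:
            counts = [
                generate_larva(params, "copper", well_rng(8, 1, s), dose=dose)
                .leukocytes_near_neuromasts()
                for s in range(150)
            ]
            means.append(np.mean(counts))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


class TestRenderZstack:
    def test_no_noise_no_defocus_slices_identical(self, clean_scene):
        larva = generate_larva(clean_scene, "copper", well_rng(9, 1, 0), dose=10.0)
        stack = render_zstack(larva, clean_scene, well_rng(9, 1, 0))
        for ch in range(3):
            for k in range(1, stack.n_slices):
                np.testing.assert_array_equal(stack.data[ch, k], stack.data[ch, 0])

    def test_peak_readback(self):
        """A rendered spot of peak 1000 reads back within 1% on the focal slice."""
        scene = small_scene(noise_sd=0.0, defocus_sigma_per_slice=0.0, psf_sigma=0.0)
        larva = _point_larva(scene, (110.0, 180.0), 1000.0)
        stack = render_zstack(larva, scene, well_rng(10, 1, 0))
        central = stack.central_plane
        assert abs(float(stack.channel("red")[central].max()) - 1000.0) <= 10.0

    def test_spot_mass_conservation(self):
        """Noise-free photon mass integrates to peak * 2*pi*sigma^2."""
        scene = small_scene(noise_sd=0.0, defocus_sigma_per_slice=0.0, psf_sigma=1.0)
        peak, sigma = 1000.0, 3.0
        larva = _point_larva(scene, (110.0, 180.0), peak, sigma)
        stack = render_zstack(larva, scene, well_rng(11, 1, 0))
        mass = float(stack.channel("red")[stack.central_plane].sum())
        assert mass == pytest.approx(peak * 2 * np.pi * sigma**2, rel=0.01)

    def test_same_seed_bit_identical(self, scene):
        stacks = []
        for _ in range(2):
            rng = well_rng(12, 1, 0)
            larva = generate_larva(scene, "copper", rng, dose=10.0)
            stacks.append(render_zstack(larva, scene, rng).data)
        np.testing.assert_array_equal(stacks[0], stacks[1])

    @pytest.mark.parametrize("n_slices", [4, 3, 6])
    def test_bad_slice_count_rejected(self, scene, n_slices):
        larva = generate_larva(scene, "control", well_rng(13, 1, 0))
        with pytest.raises(ValueError, match="n_slices"):
            render_zstack(larva, scene, well_rng(13, 1, 0), n_slices=n_slices)

    def test_central_plane_recorded(self, rendered_larva):
        _, stack = rendered_larva
        assert stack.central_plane == stack.n_slices // 2


class TestGeneratePlate:
    def test_layout_arithmetic(self, tmp_path):
        """2 conditions x 24 wells x 3 replicates -> 144 manifest/truth rows."""
        layout = PlateLayout(
            conditions=(("control", 0.0), ("copper", 10.0)),
            larvae_per_condition_per_plate=24,
            replicates=3,
        )
        manifest, truth = generate_plate(
            layout, small_scene(), tmp_path, seed=1, write_images=False
        )
        assert len(manifest) == 144
        assert len(truth) == 144
        assert set(truth["condition"].value_counts()) == {72}

    def test_files_written_and_round_trip(self, tmp_path):
        layout = PlateLayout(
            conditions=(("control", 0.0), ("copper", 10.0)),
            larvae_per_condition_per_plate=2,
            replicates=2,
        )
        manifest, truth = generate_plate(layout, small_scene(), tmp_path, seed=2)
        tiffs = sorted(tmp_path.glob("*.tif"))
        assert len(tiffs) == 8
        stack = read_zstack(tiffs[0])
        assert stack.data.shape[:2] == (3, 5)

    def test_empty_plate(self, tmp_path):
        layout = PlateLayout(
            conditions=(("control", 0.0),),
            larvae_per_condition_per_plate=0,
            replicates=1,
        )
        manifest, truth = generate_plate(layout, small_scene(), tmp_path, seed=3)
        assert len(manifest) == 0 and len(truth) == 0
        assert (tmp_path / "manifest.csv").exists()

    def test_fixed_seed_reproducible(self, tmp_path):
        layout = PlateLayout(
            conditions=(("control", 0.0), ("copper", 10.0)),
            larvae_per_condition_per_plate=6,
            replicates=2,
        )
        _, t1 = generate_plate(layout, small_scene(), tmp_path / "a", seed=4,
                               write_images=False)
        _, t2 = generate_plate(layout, small_scene(), tmp_path / "b", seed=4,
                               write_images=False)
        assert t1.equals(t2)

    def test_adding_conditions_preserves_earlier_wells(self, tmp_path):
        """Per-well RNG streams: extending the layout never perturbs old wells."""
        base = PlateLayout(conditions=(("control", 0.0),),
                           larvae_per_condition_per_plate=4, replicates=1)
        ext = PlateLayout(conditions=(("control", 0.0), ("copper", 10.0)),
                          larvae_per_condition_per_plate=4, replicates=1)
        _, t1 = generate_plate(base, small_scene(), tmp_path / "a", seed=5,
                               write_images=False)
        _, t2 = generate_plate(ext, small_scene(), tmp_path / "b", seed=5,
                               write_images=False)
        merged = t2[t2["condition"] == "control"].reset_index(drop=True)
        assert t1.reset_index(drop=True).equals(merged)

    def test_overfull_layout_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            PlateLayout(conditions=tuple((f"c{i}", 1.0) for i in range(17)),
                        larvae_per_condition_per_plate=24)


class TestSceneParams:
    def test_dose_curve_saturates(self):
        p = small_scene(rmax=8.0, k50=1.0)
        doses = np.linspace(0, 50, 40)
        vals = [p.recruit_at(d) for d in doses]
        assert vals[0] == 0.0
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] <= 8.0

    @pytest.mark.parametrize("kwargs", [
        {"lateral_orientation_prob": 1.5},
        {"n_neuromasts": 3},
        {"noise_sd": -1.0},
        {"recruit_mean": -2.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SceneParams(**kwargs)
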
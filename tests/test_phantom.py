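import dataclasses

import numpy as np
import pytest

from petmrac import io, phantom
from petmrac.phantom import LABELS


class TestGeneratePhantom:
    def test_deterministic_for_fixed_seed(self, desk_conf):
        a = phantom.generate_phantom(desk_conf, 7)
        b = phantom.generate_phantom(desk_conf, 7)
        for attr in ("labels", "ct_hu", "mr", "activity"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))

    def test_different_seeds_differ(self, desk_conf):
        a = phantom.generate_phantom(desk_conf, 1)
        b = phantom.generate_phantom(desk_conf, 2)
        assert not np.array_equal(a.labels, b.labels)

    def test_noise_free_limit_is_piecewise_constant(self, noiseless_conf):
        ph = phantom.generate_phantom(noiseless_conf, 4)
        means = {props.ct_hu_mean for name, props in
                 noiseless_conf.tissue_table.items() if name not in
                 ("lesion", "implant")}
        assert set(np.unique(ph.ct_hu)).issubset(means)

    def test_lung_fraction_matches_ellipse_areas(self, desk_conf):
        conf = dataclasses.replace(desk_conf, jitter_fraction=0.0)
        ph = phantom.generate_phantom(conf, 0)
        lungs = ph.organs["right_lung"] | ph.organs["left_lung"]
        observed = lungs.sum() / ph.body_mask.sum()
        a_lung = 2 * np.pi * conf.lung_axes[0] * conf.lung_axes[1]
        arm_cx_area = np.pi * conf.arm_axes[0] * conf.arm_axes[1]
        a_body = np.pi * conf.body_axes[0] * conf.body_axes[1] + 2 * arm_cx_area
        expected = a_lung / a_body
        assert abs(observed - expected) / expected < 0.20

    def test_activity_zero_outside_body(self, desk_phantom):
        assert np.all(desk_phantom.activity[~desk_phantom.body_mask] == 0)

    def test_organ_masks_within_body(self, desk_phantom):
        for name, mask in desk_phantom.organs.items():
            assert not np.any(mask & ~desk_phantom.body_mask), name

    def test_grid_too_small_raises(self, desk_conf):
        tiny = dataclasses.replace(desk_conf, grid_shape=(1, 16, 16))
        with pytest.raises(ValueError, match="grid too small"):
            phantom.generate_phantom(tiny, 0)

    @pytest.mark.parametrize("field,value,msg", [
        ("voxel_spacing", (0.0, 2.0, 2.0), "spacing"),
        ("tissue_table", None, "lung CT mean"),
    ])
    def test_config_invariants(self, desk_conf, field, value, msg):
        if field == "tissue_table":
            value = dict(desk_conf.tissue_table)
            value["lung"] = dataclasses.replace(value["lung"], ct_hu_mean=-200.0)
        bad = dataclasses.replace(desk_conf, **{field: value})
        with pytest.raises(ValueError, match=msg):
            phantom.generate_phantom(bad, 0)


class TestTruncation:
    def test_zero_fraction_is_identity(self, desk_phantom):
        out = phantom.inject_truncation(desk_phantom, 0.0)
        assert np.array_equal(out.mr, desk_phantom.mr)

    def test_only_mr_changes(self, desk_phantom):
        out = phantom.inject_truncation(desk_phantom, 0.15)
        assert np.array_equal(out.ct_hu, desk_phantom.ct_hu)
        assert np.array_equal(out.labels, desk_phantom.labels)
        assert np.array_equal(out.activity, desk_phantom.activity)
        assert out.outliers_applied[-1]["type"] == "truncation"

    def test_mr_body_support_shrinks(self, desk_phantom):
        out = phantom.inject_truncation(desk_phantom, 0.15)
        air = desk_phantom.config.tissue_table["air"].mr_mean
        assert (out.mr > air + 0.1).sum() < (desk_phantom.mr > air + 0.1).sum()

    def test_zeroed_voxel_count_matches_mask_arithmetic(self, desk_phantom):
        frac = 0.15
        out = phantom.inject_truncation(desk_phantom, frac)
        nx = desk_phantom.mr.shape[-1]
        cut = int(round(frac * nx))
        outside = np.zeros(desk_phantom.mr.shape, bool)
        outside[..., :cut] = True
        outside[..., nx - cut:] = True
        expected = int((outside & desk_phantom.body_mask).sum())
        assert out.organs["truncation_affected"].sum() == expected

    def test_corruption_locality(self, desk_phantom):
        out = phantom.inject_truncation(desk_phantom, 0.12)
        changed = out.mr != desk_phantom.mr
        nx = desk_phantom.mr.shape[-1]
        cut = int(round(0.12 * nx))
        assert not changed[..., cut:nx - cut].any()

    @pytest.mark.parametrize("frac", [-0.1, 0.5, 0.9])
    def test_fraction_out_of_range_rejected(self, desk_phantom, frac):
        with pytest.raises(ValueError):
            phantom.inject_truncation(desk_phantom, frac)


class TestMetal:
    def test_void_count_matches_disk_area(self, noiseless_phantom):
        r = 14.0
        out = phantom.inject_metal(noiseless_phantom, (0.0, 8.0), r, 4.0)
        air = noiseless_phantom.config.tissue_table["air"].mr_mean
        n_void = ((out.mr == air) & noiseless_phantom.body_mask).sum()
        sy, sx = noiseless_phantom.spacing[1:]
        analytic = np.pi * r ** 2 / (sy * sx) * out.mr.shape[0]
        assert abs(n_void - analytic) / analytic < 0.20  # voxelized disk

    def test_idempotent_void(self, desk_phantom):
        once = phantom.inject_metal(desk_phantom, (0.0, 8.0), 14.0, 4.0)
        twice = phantom.inject_metal(once, (0.0, 8.0), 14.0, 4.0)
        assert np.array_equal(once.mr, twice.mr)

    def test_implant_hu(self, desk_phantom):
        out = phantom.inject_metal(desk_phantom, (0.0, 8.0), 14.0, 4.0)
        impl = out.labels == LABELS["implant"]
        assert impl.any() and out.ct_hu[impl].min() >= 3000.0

    def test_activity_unchanged(self, desk_phantom):
        out = phantom.inject_metal(desk_phantom, (0.0, 8.0), 14.0, 4.0)
        assert np.array_equal(out.activity, desk_phantom.activity)

    def test_center_outside_body_rejected(self, desk_phantom):
        with pytest.raises(ValueError, match="inside the body"):
            phantom.inject_metal(desk_phantom, (105.0, 100.0), 14.0, 4.0)

    def test_implant_not_smaller_than_void_rejected(self, desk_phantom):
        with pytest.raises(ValueError):
            phantom.inject_metal(desk_phantom, (0.0, 8.0), 10.0, 10.0)


class TestRemoveLung:
    def test_relabels_to_soft(self, desk_phantom):
        out = phantom.remove_lung(desk_phantom, "left")
        region = out.organs["removed_left_lung"]
        assert np.all(out.labels[region] == LABELS["soft"])
        soft = desk_phantom.config.tissue_table["soft"]
        assert abs(out.ct_hu[region].mean() - soft.ct_hu_mean) < 10
        assert np.allclose(out.activity[region], soft.activity_mean)

    def test_other_lung_intact(self, desk_phantom):
        out = phantom.remove_lung(desk_phantom, "left")
        assert "left_lung" not in out.organs
        assert np.array_equal(out.organs["right_lung"],
                              desk_phantom.organs["right_lung"])

    def test_class_hu_bands_after_corruption(self, desk_phantom):
        out = phantom.remove_lung(desk_phantom, "right")
        for name, props in out.config.tissue_table.items():
            if name == "implant":
                continue
            sel = out.ct_hu[out.labels == LABELS[name]]
            if sel.size:
                assert abs(sel.mean() - props.ct_hu_mean) < 4 * max(
                    props.ct_hu_sd, 1.0)


@pytest.fixture(scope="module")
def stack_phantom():
    return phantom.generate_phantom(phantom.PhantomConfig(), 0)


class TestLungNodule:

    def test_one_ml_sphere_voxel_count(self, stack_phantom):
        radius = (3.0 / (4 * np.pi) * 1000.0) ** (1 / 3)  # 1.0 mL
        out = phantom.add_lung_nodule(stack_phantom, (40.0, -14.0, 0.0), radius)
        n = out.outliers_applied[-1]["n_affected_voxels"]
        assert abs(n - 125) <= 15  # 2 mm voxels, +/- surface discretization

    def test_unit_uptake_matches_soft_tissue(self, stack_phantom):
        out = phantom.add_lung_nodule(stack_phantom, (40.0, -14.0, 0.0), 6.0,
                                      uptake_ratio=1.0)
        soft = stack_phantom.config.tissue_table["soft"].activity_mean
        assert np.allclose(out.activity[out.organs["lesion_1"]], soft)

    def test_center_in_soft_tissue_rejected(self, stack_phantom):
        with pytest.raises(ValueError, match="inside a lung"):
            phantom.add_lung_nodule(stack_phantom, (0.0, 0.0, 0.0), 6.0)

    def test_default_scenario_volume_in_reported_band(self):
        conf = phantom.desk_config(n_slices=5, slice_thickness=4.0)
        ph = phantom.generate_phantom(conf, 1)
        out = phantom.add_lung_nodule(ph, (34.0, -12.0, 0.0), 7.0)
        vol = out.outliers_applied[-1]["volume_ml"]
        assert 0.5 <= vol <= 1.9


class TestMisalignment:
    def test_deterministic_and_peak_magnitude(self, desk_phantom):
        mr1, f1 = phantom.simulate_session_misalignment(desk_phantom, 6.0, 11)
        mr2, f2 = phantom.simulate_session_misalignment(desk_phantom, 6.0, 11)
        assert np.array_equal(mr1, mr2)
        assert np.isclose(f1.magnitude_mm().max(), 6.0)
        assert not np.array_equal(mr1, desk_phantom.mr)


class TestIO:
    def test_config_yaml_roundtrip(self, desk_conf, tmp_path):
        desk_conf.to_yaml(tmp_path / "c.yaml")
        back = phantom.PhantomConfig.from_yaml(tmp_path / "c.yaml")
        assert back == desk_conf

    def test_phantom_nifti_roundtrip(self, desk_phantom, tmp_path):
        desk_phantom.save(tmp_path / "ph")
        arr, spacing = io.read_volume(tmp_path / "ph" / "ct_hu.nii.gz")
        assert np.allclose(arr, desk_phantom.ct_hu, atol=1e-4)
        assert np.allclose(spacing, desk_phantom.spacing)
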
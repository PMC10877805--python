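"""ALPS engine: ROI geometry, index formula, battery, QC rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glymph import (
    PhantomSpec,
    RoiSet,
    RoiSpec,
    TensorVolume,
    alps_battery,
    chin_up_excluded,
    compute_alps_side,
    generate_tensor_phantom,
    roi_mask,
)
from glymph.alps import DEFAULT_ROI_CENTERS


def _uniform_volume(value=1.0, shape=(20, 20, 20), voxel=2.0):
    aff = np.eye(4) * voxel
    aff[3, 3] = 1.0
    aff[:3, 3] = -voxel * (np.asarray(shape) // 2)
    d = np.full(shape, value, dtype=float)
    return TensorVolume(dxx=d.copy(), dyy=d.copy(), dzz=d.copy(), affine=aff)


class TestRoiMask:
    def test_six_mm_sphere_on_2mm_grid_has_19_voxels(self):
        """Brute-force enumeration: voxel centers within 3 mm of a voxel
        center on a 2-mm grid are the 19 offsets with i^2+j^2+k^2 <= 2."""
        vol = _uniform_volume()
        spec = RoiSpec(side="left", fiber_type="projection", center=(0.0, 0.0, 0.0), diameter=6.0)
        mask = roi_mask(spec, vol)
        # independent brute-force count over integer offsets
        expected = sum(
            1
            for i in range(-3, 4)
            for j in range(-3, 4)
            for k in range(-3, 4)
            if (2 * i) ** 2 + (2 * j) ** 2 + (2 * k) ** 2 <= 9
        )
        assert expected == 19
        assert mask.sum() == 19

    def test_tiny_sphere_is_single_voxel(self):
        vol = _uniform_volume()
        spec = RoiSpec(side="left", fiber_type="projection", center=(0.0, 0.0, 0.0), diameter=0.1)
        assert roi_mask(spec, vol).sum() == 1

    @pytest.mark.parametrize("shift", [-2, -1, 1, 2])
    def test_y_shift_is_voxel_translation(self, shift):
        vol = _uniform_volume()
        base = RoiSpec(side="left", fiber_type="projection", center=(0.0, 0.0, 0.0))
        shifted = RoiSpec(
            side="left", fiber_type="projection", center=(0.0, 0.0, 0.0), y_shift=shift
        )
        m0 = roi_mask(base, vol)
        m1 = roi_mask(shifted, vol)
        assert np.array_equal(np.roll(m0, shift, axis=1), m1)

    def test_sphere_outside_grid_raises(self):
        vol = _uniform_volume()
        spec = RoiSpec(side="left", fiber_type="projection", center=(500.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="left-projection"):
            roi_mask(spec, vol)

    def test_invalid_shift_rejected(self):
        with pytest.raises(ValueError, match="y_shift"):
            RoiSpec(side="left", fiber_type="projection", center=(0, 0, 0), y_shift=3)


class TestComputeAlpsSide:
    def test_arithmetic(self):
        assert compute_alps_side(1.2, 1.0, 0.6, 0.5) == pytest.approx(2.0)

    @given(st.floats(min_value=1e-3, max_value=10.0))
    def test_isotropy_gives_one(self, d):
        assert compute_alps_side(d, d, d, d) == pytest.approx(1.0)

    @given(
        st.floats(min_value=0.1, max_value=3.0),
        st.floats(min_value=0.1, max_value=3.0),
        st.floats(min_value=0.1, max_value=3.0),
        st.floats(min_value=0.1, max_value=3.0),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, a, b, c, d, k):
        base = compute_alps_side(a, b, c, d)
        scaled = compute_alps_side(k * a, k * b, k * c, k * d)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_monotone_in_dxx_proj(self):
        lo = compute_alps_side(1.0, 1.0, 0.7, 0.7)
        hi = compute_alps_side(1.1, 1.0, 0.7, 0.7)
        assert hi > lo

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_alps_side(1.0, 1.0, 0.0, 0.0)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError, match="dxx_proj"):
            compute_alps_side(-1.0, 1.0, 0.5, 0.5)


def _oracle_index(vol, rois, side, shift):
    """Independent loop implementation of one side's index."""
    import itertools

    means = {}
    for fiber in ("projection", "association"):
        center = np.asarray(rois.centers[(side, fiber)], dtype=float)
        center[1] += shift * vol.voxel_size[1]
        vals = {"dxx": [], "dyy": [], "dzz": []}
        for idx in itertools.product(*(range(s) for s in vol.shape)):
            mm = vol.affine @ np.array([*idx, 1.0])
            if np.sum((mm[:3] - center) ** 2) <= (3.0**2) + 1e-9:
                vals["dxx"].append(vol.dxx[idx])
                vals["dyy"].append(vol.dyy[idx])
                vals["dzz"].append(vol.dzz[idx])
        for key, v in vals.items():
            means[f"{key}_{fiber}"] = float(np.mean(v))
    return (means["dxx_projection"] + means["dxx_association"]) / (
        means["dyy_projection"] + means["dzz_association"]
    )


class TestAlpsBattery:
    def test_oracle_equivalence_on_noisy_phantom(self):
        """Battery indices agree with a brute-force voxel-loop oracle."""
        spec = PhantomSpec(alps_truth=1.3, noise_sd=0.05, seed=11, shape=(44, 28, 28),
                           offset=(-44.0, -28.0, 14.0))
        vol, _ = generate_tensor_phantom(spec)
        rois = RoiSet()
        res = alps_battery(vol, rois)
        for side in ("left", "right"):
            for shift in (-2, 0, 2):
                oracle = _oracle_index(vol, rois, side, shift)
                got = res.left[shift] if side == "left" else res.right[shift]
                assert got == pytest.approx(oracle, abs=1e-12)

    def test_noiseless_phantom_all_shifts_exact(self, noiseless_phantom):
        vol, truth = noiseless_phantom
        res = alps_battery(vol)
        for shift in (-2, -1, 0, 1, 2):
            for table in (res.left, res.right, res.average):
                assert table[shift] == pytest.approx(truth["alps_truth"], abs=1e-10)

    def test_symmetric_phantom_left_equals_right(self, noiseless_phantom):
        vol, _ = noiseless_phantom
        res = alps_battery(vol)
        assert res.left[0] == pytest.approx(res.right[0], abs=1e-12)
        assert res.average[0] == pytest.approx((res.left[0] + res.right[0]) / 2, abs=1e-15)

    def test_default_analysis_shift_is_middle(self, noiseless_phantom):
        vol, _ = noiseless_phantom
        res = alps_battery(vol)
        assert res.index() == res.average[0]

    def test_noise_unbiased(self):
        """Index estimates from noisy phantoms are unbiased within MC error."""
        truths = []
        for seed in range(100):
            spec = PhantomSpec(alps_truth=1.2, noise_sd=0.02, seed=seed)
            vol, _ = generate_tensor_phantom(spec)
            truths.append(alps_battery(vol).average[0])
        assert np.mean(truths) == pytest.approx(1.2, abs=0.02)

    def test_row_flattening_has_15_indices(self, noiseless_phantom):
        vol, _ = noiseless_phantom
        row = alps_battery(vol).to_row()
        assert len(row) == 15
        assert row["alps_mean_shift+0"] == pytest.approx(1.355)


class TestChinUp:
    @pytest.mark.parametrize("angle,expected", [(25.0, True), (20.0, False), (0.0, False)])
    def test_threshold_strict(self, angle, expected):
        assert chin_up_excluded(angle) is expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            chin_up_excluded(float("nan"))


def test_tensor_volume_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shapes differ"):
        TensorVolume(
            dxx=np.zeros((4, 4, 4)), dyy=np.zeros((4, 4, 4)), dzz=np.zeros((4, 4, 5)),
            affine=np.eye(4),
        )


def test_roi_config_roundtrip(tmp_path):
    import yaml

    cfg = {
        "diameter": 6.0,
        "centers": {
            side: {fiber: list(DEFAULT_ROI_CENTERS[(side, fiber)]) for fiber in
                   ("projection", "association")}
            for side in ("left", "right")
        },
    }
    path = tmp_path / "rois.yaml"
    path.write_text(yaml.safe_dump(cfg))
    from glymph.alps import load_roi_config

    rois = load_roi_config(path)
    assert rois.centers[("left", "projection")] == DEFAULT_ROI_CENTERS[("left", "projection")]
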
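import json

import numpy as np
import pytest

import rlfocus as rf
from rlfocus.simulate import TEXTURE_FAMILIES, FormatError


class TestMakeTexture:
    def test_same_seed_is_bit_identical(self):
        a = rf.make_texture("speckle", 224, 0.5, seed=1)
        b = rf.make_texture("speckle", 224, 0.5, seed=1)
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self):
        a = rf.make_texture("speckle", 64, 0.5, seed=1)
        b = rf.make_texture("speckle", 64, 0.5, seed=2)
        assert not np.array_equal(a, b)

    @pytest.mark.parametrize("family", TEXTURE_FAMILIES)
    @pytest.mark.parametrize("contrast", [0.5, 0.9])
    def test_michelson_contrast_within_ten_percent(self, family, contrast):
        img = rf.make_texture(family, 224, contrast, seed=7)
        mc = (img.max() - img.min()) / (img.max() + img.min())
        assert abs(mc - contrast) <= 0.1 * contrast

    def test_range_and_shape(self):
        for family in TEXTURE_FAMILIES:
            img = rf.make_texture(family, 32, 0.7, seed=0)
            assert img.shape == (32, 32)
            assert img.min() >= 0.0 and img.max() <= 1.0

    def test_degenerate_size_rejected(self):
        with pytest.raises(ValueError):
            rf.make_texture("regular_grid", 4, 0.9, seed=1)

    @pytest.mark.parametrize("contrast", [0.0, -0.2, 1.5])
    def test_bad_contrast_rejected(self, contrast):
        with pytest.raises(ValueError):
            rf.make_texture("regular_grid", 64, contrast, seed=1)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            rf.make_texture("marble", 64, 0.5, seed=1)


class TestRenderStack:
    def test_default_voltage_grid_spans_9_9_volts(self):
        tex = rf.make_texture("bar_target", 32, 0.5, seed=2)
        stack = rf.render_stack(tex, n_frames=100, focus_index=50, v_step=0.1)
        assert stack.n_frames == 100
        assert stack.voltage_grid[-1] - stack.voltage_grid[0] == pytest.approx(9.9)
        assert np.allclose(np.diff(stack.voltage_grid), 0.1)

    def test_noiseless_energy_peaks_at_focus(self, small_noiseless_stack):
        curve = rf.sharpness_curve(small_noiseless_stack, "energy")
        assert curve.argmax == small_noiseless_stack.focus_index

    def test_noiseless_sharpness_strictly_decreases_away_from_focus(
        self, small_noiseless_stack
    ):
        for name in rf.MEASURES:
            vals = rf.sharpness_curve(small_noiseless_stack, name).values
            f = small_noiseless_stack.focus_index
            left = vals[: f + 1]
            right = vals[f:]
            assert np.all(np.diff(left) > 0), name
            assert np.all(np.diff(right) < 0), name

    def test_out_of_range_focus_rejected(self):
        tex = rf.make_texture("speckle", 16, 0.5, seed=0)
        with pytest.raises(ValueError):
            rf.render_stack(tex, n_frames=100, focus_index=120)

    def test_too_few_frames_rejected(self):
        tex = rf.make_texture("speckle", 16, 0.5, seed=0)
        with pytest.raises(ValueError):
            rf.render_stack(tex, n_frames=2, focus_index=0)

    def test_astigmatism_breaks_left_right_symmetry(self):
        tex = rf.make_texture("regular_grid", 32, 0.9, seed=4)
        iso = rf.render_stack(tex, n_frames=21, focus_index=10, noise_sd=0.0)
        astig = rf.render_stack(
            tex, n_frames=21, focus_index=10, noise_sd=0.0, astigmatism=0.4
        )
        # isotropic: frames equidistant from focus are identical
        assert np.allclose(iso.frames[6], iso.frames[14])
        # astigmatic: the same pair differs (the directional cue)
        assert not np.allclose(astig.frames[6], astig.frames[14])


class TestAugmentStack:
    def test_hflip_is_involution(self, small_noiseless_stack):
        once = rf.augment_stack(small_noiseless_stack, ["hflip"])
        twice = rf.augment_stack(once, ["hflip"])
        assert np.array_equal(twice.frames, small_noiseless_stack.frames)

    def test_gamma_one_is_identity(self, small_noiseless_stack):
        out = rf.augment_stack(small_noiseless_stack, [("gamma", 1.0)])
        assert np.allclose(out.frames, small_noiseless_stack.frames)

    def test_crop_reproducible_and_preserves_metadata(self, small_noiseless_stack):
        a = rf.augment_stack(small_noiseless_stack, ["crop"], seed=5)
        b = rf.augment_stack(small_noiseless_stack, ["crop"], seed=5)
        assert np.array_equal(a.frames, b.frames)
        assert a.focus_index == small_noiseless_stack.focus_index
        assert a.n_frames == small_noiseless_stack.n_frames
        assert np.array_equal(a.voltage_grid, small_noiseless_stack.voltage_grid)

    def test_unknown_op_rejected(self, small_noiseless_stack):
        with pytest.raises(ValueError):
            rf.augment_stack(small_noiseless_stack, ["rotate45"])

    def test_crop_below_half_rejected(self, small_noiseless_stack):
        with pytest.raises(ValueError):
            rf.augment_stack(small_noiseless_stack, [("crop", 0.3)])


class TestBuildDatasetList:
    def test_single_family_count(self):
        lst = rf.build_dataset_list(5, ["speckle"], n_frames=12, seed=0, size=16)
        assert len(lst) == 5
        assert lst.family_counts == {"speckle": 5}

    def test_two_families_split_evenly(self):
        lst = rf.build_dataset_list(
            20, ["regular_grid", "bar_target"], n_frames=12, seed=0, size=16
        )
        assert lst.family_counts == {"regular_grid": 10, "bar_target": 10}

    def test_singleton(self):
        lst = rf.build_dataset_list(1, ["speckle"], n_frames=12, seed=0, size=16)
        assert len(lst) == 1

    def test_deterministic_regeneration(self):
        a = rf.build_dataset_list(4, TEXTURE_FAMILIES, n_frames=10, seed=9, size=16)
        b = rf.build_dataset_list(4, TEXTURE_FAMILIES, n_frames=10, seed=9, size=16)
        for sa, sb in zip(a.stacks, b.stacks):
            assert np.array_equal(sa.frames, sb.frames)
            assert sa.focus_index == sb.focus_index

    def test_focus_indices_in_central_80_percent(self):
        lst = rf.build_dataset_list(30, ["speckle"], n_frames=20, seed=1, size=16)
        for s in lst.stacks:
            assert 2 <= s.focus_index < 18

    def test_empty_family_list_rejected(self):
        with pytest.raises(ValueError):
            rf.build_dataset_list(3, [], n_frames=10, seed=0)


class TestStackIO:
    def test_roundtrip_exact_metadata_and_quantized_pixels(self, tmp_path, small_noiseless_stack):
        rf.write_stack(small_noiseless_stack, tmp_path / "s")
        back = rf.read_stack(tmp_path / "s")
        assert back.focus_index == small_noiseless_stack.focus_index
        assert back.texture_family == small_noiseless_stack.texture_family
        assert np.allclose(back.voltage_grid, small_noiseless_stack.voltage_grid)
        assert np.max(np.abs(back.frames - small_noiseless_stack.frames)) <= 1.0 / 255.0 + 1e-12

    def test_missing_frame_file_names_index(self, tmp_path, small_noiseless_stack):
        rf.write_stack(small_noiseless_stack, tmp_path / "s")
        victims = sorted((tmp_path / "s").glob("frame_007_*.png"))
        victims[0].unlink()
        with pytest.raises(FormatError, match="index 7"):
            rf.read_stack(tmp_path / "s")

    def test_malformed_sidecar_rejected(self, tmp_path, small_noiseless_stack):
        rf.write_stack(small_noiseless_stack, tmp_path / "s")
        (tmp_path / "s" / "stack.json").write_text("{not json")
        with pytest.raises(FormatError):
            rf.read_stack(tmp_path / "s")

    def test_read_orders_frames_by_sidecar_not_disk(self, tmp_path, small_noiseless_stack):
        out = tmp_path / "s"
        rf.write_stack(small_noiseless_stack, out)
        # shuffle names on disk; the sidecar keeps the voltage order
        sidecar = json.loads((out / "stack.json").read_text())
        names = sidecar["frames"]
        for old, tag in [(names[0], "zz_a.png"), (names[5], "aa_b.png")]:
            (out / old).rename(out / tag)
        names[0], names[5] = "zz_a.png", "aa_b.png"
        (out / "stack.json").write_text(json.dumps(sidecar))
        back = rf.read_stack(out)
        assert np.max(np.abs(back.frames - small_noiseless_stack.frames)) <= 1.0 / 255.0 + 1e-12
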
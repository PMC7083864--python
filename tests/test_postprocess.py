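import numpy as np
import pytest
from scipy import ndimage

from astroseg.postprocess import (OrientationProfile, ShapeClass,
                                  classify_star_string, keep_central_component,
                                  orientation_profile, reassemble)


def profile(values, n=20):
    values = np.asarray(values, dtype=float)
    return OrientationProfile(values=values, angle_step=180.0 / len(values))


class TestKeepCentralComponent:
    def test_central_blob_kept_corner_blob_dropped(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:48, 20:48] = True          # ~800 px central blob
        mask[0:8, 0:8] = True              # 64 px corner blob
        out = keep_central_component(mask, (32.0, 32.0), min_size=100)
        assert out[32, 32]
        assert not out[2, 2]
        assert out.sum() == 28 * 28

    def test_single_component_unchanged(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:20, 10:20] = True
        out = keep_central_component(mask, (15.0, 15.0), min_size=10)
        np.testing.assert_array_equal(out, mask)

    def test_centroid_on_background_nearest_component_kept(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5:15, 5:15] = True       # near blob (distance ~ 24 from center)
        mask[50:60, 50:60] = True     # far blob
        out = keep_central_component(mask, (32.0, 32.0), min_size=10)
        assert out[10, 10]
        assert not out[55, 55]

    def test_large_noncentral_component_removed(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[28:36, 28:36] = True     # central, 64 px
        mask[0:20, 44:64] = True      # large neighbor fragment, 400 px
        out = keep_central_component(mask, (32.0, 32.0), min_size=10)
        assert out.sum() == 64

    def test_empty_mask_stays_empty(self):
        out = keep_central_component(np.zeros((16, 16), dtype=bool),
                                     (8.0, 8.0))
        assert not out.any()

    def test_undersized_central_component_dropped(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[15:17, 15:17] = True
        out = keep_central_component(mask, (16.0, 16.0), min_size=100)
        assert not out.any()


class TestOrientationProfile:
    def test_horizontal_bar_single_peak_at_zero(self, profile_bank):
        img = np.zeros((128, 128))
        img[62:66, 10:118] = 1.0
        prof = orientation_profile(img, profile_bank)
        assert len(prof.values) == 20
        assert prof.values.max() == 1.0
        peak = int(np.argmax(prof.values))
        assert peak in (0, 1, 19)  # aligned with the bar (0 degrees)

    def test_cross_two_peaks_90_apart(self, profile_bank):
        img = np.zeros((128, 128))
        img[62:66, 14:114] = 1.0
        img[14:114, 62:66] = 1.0
        prof = orientation_profile(img, profile_bank)
        cls = classify_star_string(prof)
        assert cls.label == "star"
        assert cls.n_prominent == 2
        a, b = cls.peak_angles
        assert abs(abs(a - b) - 90.0) <= prof.angle_step

    def test_five_armed_star_at_least_two_peaks(self, profile_bank):
        from astroseg.synthgen import SceneConfig, generate_star

        rng = np.random.default_rng(3)
        cfg = SceneConfig(n_processes_range=(5, 5))
        mask, _, _ = generate_star((128, 128), cfg, rng, shape=(256, 256))
        prof = orientation_profile(mask.astype(float), profile_bank)
        above = prof.values >= 0.5
        assert classify_star_string(prof).n_prominent >= 2
        assert above.sum() >= 2

    def test_empty_object_all_zero(self, profile_bank):
        prof = orientation_profile(np.zeros((64, 64)), profile_bank)
        assert np.all(prof.values == 0.0)


class TestClassifyStarString:
    def test_cross_profile_fixture(self):
        values = np.zeros(20)
        values[0] = 1.0
        values[10] = 0.9   # 90 degrees away
        cls = classify_star_string(profile(values))
        assert cls.label == "star"
        assert cls.n_prominent == 2

    def test_single_bar_profile_fixture(self):
        values = np.zeros(20)
        values[4] = 0.4
        values[5] = 1.0
        values[6] = 0.5
        cls = classify_star_string(profile(values))
        assert cls.label == "string"
        assert cls.n_prominent == 1

    def test_uniform_profile_tie_rule_star(self):
        cls = classify_star_string(profile(np.ones(20)))
        assert cls.label == "star"
        assert cls.n_prominent >= 2

    def test_all_zero_profile_degenerates_to_string(self):
        cls = classify_star_string(profile(np.zeros(20)))
        assert cls.label == "string"
        assert cls.n_prominent == 0

    def test_close_peaks_collapsed(self):
        values = np.zeros(20)
        values[5] = 1.0
        values[7] = 0.95   # 18 degrees away < 20 separation guard
        cls = classify_star_string(profile(values), min_separation_deg=20.0)
        assert cls.label == "string"

    def test_invalid_prominence(self):
        with pytest.raises(ValueError):
            classify_star_string(profile(np.ones(20)), prominence_frac=1.5)

    def test_circular_wraparound_peak(self):
        values = np.zeros(20)
        values[0] = 1.0
        values[19] = 0.3
        values[1] = 0.3
        values[9] = 0.8
        cls = classify_star_string(profile(values))
        assert cls.n_prominent == 2
        assert cls.label == "star"

    def test_rotation_equivariance_all_orientations(self, profile_bank):
        # rotating a bar by k*angle_step shifts the peak by k slots and
        # never flips the label
        base = np.zeros((160, 160))
        base[78:82, 20:140] = 1.0
        labels = []
        peaks = []
        for k in range(20):
            img = ndimage.rotate(base, -profile_bank.angle_step * k,
                                 reshape=False, order=1)
            prof = orientation_profile(img, profile_bank)
            cls = classify_star_string(prof)
            labels.append(cls.label)
            peaks.append(int(np.argmax(prof.values)))
        assert set(labels) == {"string"}
        expected = [(peaks[0] + k) % 20 for k in range(20)]
        off = np.abs((np.array(peaks) - np.array(expected) + 10) % 20 - 10)
        assert off.max() <= 1

    def test_rotation_equivariance_cross(self, profile_bank):
        base = np.zeros((160, 160))
        base[78:82, 20:140] = 1.0
        base[20:140, 78:82] = 1.0
        for k in range(0, 20, 4):
            img = ndimage.rotate(base, -profile_bank.angle_step * k,
                                 reshape=False, order=1)
            cls = classify_star_string(orientation_profile(img, profile_bank))
            assert cls.label == "star"


class TestReassemble:
    def star(self, n=2):
        return ShapeClass(label="star", n_prominent=n, peak_angles=())

    def string(self):
        return ShapeClass(label="string", n_prominent=1, peak_angles=())

    def test_two_disjoint_patches(self):
        m1 = np.zeros((16, 16), dtype=bool)
        m1[4:8, 4:8] = True
        m2 = np.zeros((16, 16), dtype=bool)
        m2[2:6, 2:6] = True
        seg = reassemble([(m1, (0, 0, 16)), (m2, (40, 40, 16))], (64, 64),
                         [self.star(), self.star()])
        got = set(np.unique(seg.labels)) - {0}
        assert got == {1, 2}
        assert (seg.labels == 1).sum() == 16
        assert (seg.labels == 2).sum() == 16

    def test_overlap_gets_ambiguous_label(self):
        m = np.zeros((16, 16), dtype=bool)
        m[:, :] = True
        # two full patches overlapping on a 16x8 strip
        seg = reassemble([(m, (0, 0, 16)), (m, (0, 8, 16))], (32, 32),
                         [self.star(), self.star()])
        overlap = seg.labels[0:16, 8:16]
        assert (overlap == seg.ambiguous_label).all()
        assert (seg.labels[0:16, 0:8] == 1).all()
        assert (seg.labels[0:16, 16:24] == 2).all()

    def test_strings_excluded(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:6, 2:6] = True
        patches = [(m, (0, 0, 8)), (m, (20, 20, 8)), (m, (40, 40, 8)),
                   (m, (9, 30, 8)), (m, (30, 9, 8))]
        classes = [self.star(), self.star(), self.star(),
                   self.string(), self.string()]
        seg = reassemble(patches, (64, 64), classes)
        assert len(seg.cell_ids) == 3
        assert set(np.unique(seg.labels)) - {0} == {1, 2, 3}

    def test_foreground_conserved(self, rng):
        patches = []
        for i in range(4):
            m = rng.random((12, 12)) > 0.6
            patches.append((m, (i * 10, i * 7, 12)))
        seg = reassemble(patches, (64, 64), [self.star()] * 4)
        total_fg = np.zeros((64, 64), dtype=int)
        for m, (t, l, s) in patches:
            total_fg[t:t + s, l:l + s] += m
        covered = (seg.labels > 0)
        assert np.array_equal(covered, total_fg > 0)

    def test_duplicates_merged_with_warning(self, caplog):
        m = np.zeros((8, 8), dtype=bool)
        m[1:4, 1:4] = True
        import logging

        with caplog.at_level(logging.WARNING, logger="astroseg.postprocess"):
            seg = reassemble([(m, (0, 0, 8)), (m, (0, 0, 8))], (16, 16),
                             [self.star(), self.star()])
        assert len(seg.cell_ids) == 1
        assert "duplicate" in caplog.text

    def test_class_length_mismatch(self):
        with pytest.raises(ValueError):
            reassemble([(np.zeros((4, 4), dtype=bool), (0, 0, 4))], (8, 8), [])
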
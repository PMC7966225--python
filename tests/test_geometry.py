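"""Geometric measurement: reorientation, sections, widths, bridge detection."""

import numpy as np
import pytest

import graftscore as g
from graftscore import geometry, phantom
from graftscore.core import GeometryError, LandmarkRequiredError, OutOfBoundsError

from conftest import SMALL_SHAPE, slab_section

BONE = g.LABELS["bone"]
INC = g.LABELS["incisor_root"]
CAN = g.LABELS["canine_root"]


def brute_force_min_width(section, bone_mask=None):
    """Independent oracle: exhaustive column scan of an axis-aligned section.

    Assumes roots are separated along the second (column) axis and bone
    thickness is read along the first (row) axis, as in the constructed
    fixtures.
    """
    img = section.image
    bone = (img == BONE) if bone_mask is None else bone_mask
    mes_cols = np.where((img == INC).any(axis=0))[0]
    dis_cols = np.where((img == CAN).any(axis=0))[0]
    best = np.inf
    for col in range(mes_cols.max() + 1, dis_cols.min()):
        column = bone[:, col]
        runs, current = [], 0
        for v in column:
            current = current + 1 if v else 0
            runs.append(current)
        longest = max(runs) if runs else 0
        best = min(best, longest)
    return float(best) * section.spacing_mm


class TestReorient:
    def test_identity_axis_returns_volume_unchanged(self, default_phantom):
        _, volume, landmarks, _ = default_phantom
        out = geometry.reorient_to_tooth_axis(volume, landmarks["incisor"])
        assert (out.voxels == volume.voxels).all()
        assert "cej_index" in out.meta

    def test_rotated_phantom_matches_unrotated_twin(self):
        base = phantom.config_for_scores((2, 2, 2, 2), seed=3)
        tilted = phantom.config_for_scores((2, 2, 2, 2), seed=3, axis_tilt_deg=90.0)
        v0, lm0, _ = phantom.generate_phantom(base)
        v1, lm1, _ = phantom.generate_phantom(tilted)
        r1 = geometry.reorient_to_tooth_axis(v1, lm1["incisor"])
        rlm = r1.meta["landmarks"]["incisor"]
        for depth in g.ASSESSMENT_LEVELS_MM:
            w0 = geometry.measure_min_bridge_width(
                geometry.extract_level_section(v0, lm0["incisor"], depth)
            )
            w1 = geometry.measure_min_bridge_width(
                geometry.extract_level_section(r1, rlm, depth)
            )
            assert w1 == pytest.approx(w0, abs=v0.spacing_mm)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError, match="non-degenerate"):
            g.ToothLandmarks((1, 1, 1), (1, 1, 5), (0.0, 0.0, 0.0))

    def test_landmark_outside_volume_rejected(self, default_phantom):
        _, volume, _, _ = default_phantom
        bad = g.ToothLandmarks((-5.0, 1.0, 1.0), (-5.0, 1.0, 6.0), (0.0, 0.0, 1.0))
        with pytest.raises(OutOfBoundsError):
            geometry.reorient_to_tooth_axis(volume, bad)


class TestLocateCej:
    def _volume_with_cap(self, dip_voxels=()):
        vox = np.zeros((32, 32, 40), np.int16)
        vox[10:21, 10:21, 20:35] = INC          # root, apical of CEJ plane z=20
        vox[10:21, 10:21, 14:20] = g.LABELS["enamel"]
        for dv in dip_voxels:
            vox[dv] = g.LABELS["enamel"]        # enamel dipping one voxel apically
        return g.LabeledVolume(vox, 0.2)

    def test_unique_most_apical_enamel_voxel(self):
        vol = self._volume_with_cap(dip_voxels=[(15, 15, 20)])
        got = geometry.locate_cej(vol, INC)
        assert np.allclose(got / 0.2, (15, 15, 20))

    def test_tie_broken_toward_root_centroid(self):
        # two equally apical dips on the midsagittal plane (centroid row 15)
        vol = self._volume_with_cap(dip_voxels=[(11, 15, 20), (15, 15, 20)])
        got = geometry.locate_cej(vol, INC)
        assert np.allclose(got / 0.2, (15, 15, 20))

    def test_missing_enamel_raises_landmark_required(self):
        vox = np.zeros((20, 20, 20), np.int16)
        vox[5:10, 5:10, 5:15] = INC
        with pytest.raises(LandmarkRequiredError):
            geometry.locate_cej(g.LabeledVolume(vox, 0.2), INC)


class TestLevelSections:
    def test_section_empty_where_bridge_starts_deeper(self):
        cfg = phantom.between_level_config((3.8, 4.4), 1.2)
        volume, lm, _ = phantom.generate_phantom(cfg)
        section = geometry.extract_level_section(volume, lm["incisor"], 3.0)
        assert geometry.measure_min_bridge_width(section) == 0.0

    def test_out_of_bounds_depth_raises(self, default_phantom):
        _, volume, landmarks, _ = default_phantom
        with pytest.raises(OutOfBoundsError):
            geometry.extract_level_section(volume, landmarks["incisor"], 500.0)

    def test_plane_normal_is_tooth_axis(self, default_phantom):
        _, volume, landmarks, _ = default_phantom
        section = geometry.extract_level_section(volume, landmarks["incisor"], 5.0)
        assert np.allclose(section.axis, landmarks["incisor"].axis, atol=1e-6)


class TestMinBridgeWidth:
    @pytest.mark.parametrize("width_mm", [0.6, 1.0, 2.0, 3.4])
    def test_uniform_slab_recovers_thickness(self, width_mm):
        section = slab_section(width_mm)
        got = geometry.measure_min_bridge_width(section)
        assert got == pytest.approx(width_mm, abs=section.spacing_mm)

    def test_interrupted_station_gives_zero(self):
        profile = np.full(39, 10)
        profile[17] = 0
        section = slab_section(2.0, thickness_profile=profile)
        assert geometry.measure_min_bridge_width(section) == 0.0

    def test_stepped_profile_returns_minimum(self):
        profile = np.concatenate([np.full(20, 12), np.full(19, 5)])
        section = slab_section(2.0, thickness_profile=profile)
        assert geometry.measure_min_bridge_width(section) == pytest.approx(
            5 * 0.2, abs=0.2
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan_exactly(self, seed):
        rng = np.random.default_rng(seed)
        profile = rng.integers(0, 15, size=39)
        section = slab_section(2.0, thickness_profile=profile)
        expected = brute_force_min_width(
            section,
            bone_mask=geometry._spanning_bone(section.image, BONE, INC, CAN),
        )
        assert geometry.measure_min_bridge_width(section) == expected

    def test_disjoint_islands_do_not_count_as_bridge(self):
        # two half-span slabs overlapping mid-gap but 8-disconnected
        img_section = slab_section(2.0)
        img = img_section.image.copy()
        img[img == BONE] = 0
        cx = img.shape[0] // 2
        img[cx - 8 : cx - 2, 21:42] = BONE    # mesial island, rows < cx
        img[cx + 2 : cx + 8, 40:60] = BONE    # distal island, rows > cx
        sec = g.LevelSection(5.0, img, 0.2, (0.0, 0.0, 1.0))
        assert geometry.measure_min_bridge_width(sec) == 0.0

    def test_missing_root_region_raises(self):
        section = slab_section(2.0)
        img = section.image.copy()
        img[img == CAN] = 0
        sec = g.LevelSection(5.0, img, 0.2, (0.0, 0.0, 1.0))
        with pytest.raises(GeometryError):
            geometry.measure_min_bridge_width(sec)

    def test_monotone_under_dilation(self):
        from scipy import ndimage

        rng = np.random.default_rng(4)
        profile = rng.integers(1, 10, size=39)
        section = slab_section(2.0, thickness_profile=profile)
        w0 = geometry.measure_min_bridge_width(section)
        img = section.image.copy()
        grown = ndimage.binary_dilation(img == BONE, np.ones((3, 3)))
        img[grown & (img == 0)] = BONE
        w1 = geometry.measure_min_bridge_width(
            g.LevelSection(5.0, img, 0.2, (0.0, 0.0, 1.0))
        )
        assert w1 >= w0


class TestRootWidth:
    def test_tapered_cone_width_at_levels(self, default_phantom):
        cfg, volume, landmarks, _ = default_phantom
        lm = landmarks["incisor"]
        got = geometry.measure_root_width(volume, lm, 3.0)
        assert got == pytest.approx(float(cfg.incisor_profile(3.0)), abs=0.2)

    def test_beyond_apex_signals_absent_root(self, default_phantom):
        cfg, volume, landmarks, _ = default_phantom
        lm = landmarks["incisor"]
        assert geometry.measure_root_width(volume, lm, cfg.incisor_root_length_mm + 1.0) is None

    def test_near_apex_width_for_resorption_rule(self):
        cfg = phantom.config_for_scores((1, 1, 1, 1), resorbed=True)
        volume, lm, _ = phantom.generate_phantom(cfg)
        depth = cfg.incisor_root_length_mm - 0.5
        got = geometry.measure_root_width(volume, lm["incisor"], depth)
        assert got == pytest.approx(float(cfg.incisor_profile(depth)), abs=0.2)


class TestDetectBridge:
    def test_continuous_slab_detected_with_mid_depth(self, reoriented_default):
        vol, lm = reoriented_default
        present, depth = geometry.detect_bridge(vol, lm)
        assert present
        assert 1.0 < depth < 9.0

    def test_empty_bone_mask_returns_false(self):
        cfg = phantom.PhantomConfig(
            volume_shape=SMALL_SHAPE, bridge_profile=phantom.no_bridge()
        )
        volume, lm, _ = phantom.generate_phantom(cfg)
        assert geometry.detect_bridge(volume, lm["incisor"]) == (False, None)

    def test_disjoint_flank_islands_not_a_bridge(self, default_phantom):
        _, volume, landmarks, _ = default_phantom
        vox = volume.voxels.copy()
        # cut the bridge mid-gap with an empty mesiodistal plane
        y_mid = vox.shape[1] // 2
        vox[:, y_mid, :][vox[:, y_mid, :] == BONE] = 0
        cut = g.LabeledVolume(vox, volume.spacing_mm)
        present, _ = geometry.detect_bridge(cut, landmarks["incisor"])
        assert not present

    def test_between_level_bridge_depth_recovered(self):
        cfg = phantom.between_level_config((3.8, 4.4), 1.2)
        volume, lm, _ = phantom.generate_phantom(cfg)
        present, depth = geometry.detect_bridge(volume, lm["incisor"])
        assert present
        assert depth == pytest.approx(4.1, abs=0.2)
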
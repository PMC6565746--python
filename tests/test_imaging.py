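"""Segmentation, marker rules, widest-plane ROI and the FI statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from ploidykit.imaging import (
    ImageStack,
    fi_statistic,
    integrated_intensity_3d,
    match_labels,
    measure_nuclei,
    segment_nuclei,
    select_cells,
    widest_plane,
)
from ploidykit.ploidy import kde_mode
from ploidykit.synth import Nucleus, simulate_confocal_scene

from conftest import grid_ploidy_scene, small_scene_spec


def _stack_from(arr, **kw):
    return ImageStack(channels={"dapi": np.asarray(arr, dtype=float)}, **kw)


class TestSegmentation:
    def test_all_background_zero_nuclei(self):
        stack = _stack_from(np.zeros((6, 20, 20)), voxel_size_um=(0.4, 0.2, 0.2))
        assert segment_nuclei(stack).max() == 0

    def test_missing_channel_errors(self, two_nucleus_scene):
        stack, _, _ = two_nucleus_scene
        with pytest.raises(KeyError):
            segment_nuclei(stack, dapi_channel="nope")

    def test_noiseless_two_ellipsoids_centroids(self, noiseless_scene):
        stack, true_labels, truth = noiseless_scene
        seg = segment_nuclei(stack)
        assert seg.max() == 2
        for tid in (1, 2):
            true_c = np.array(ndimage.center_of_mass(true_labels == tid))
            match = match_labels(seg, true_labels)
            sid = match.loc[match["true_id"] == tid, "seg_id"].item()
            seg_c = np.array(ndimage.center_of_mass(seg == sid))
            assert np.all(np.abs(true_c - seg_c) <= 1.0)

    def test_minimum_volume_filter_removes_specks(self, noiseless_scene):
        stack, _, _ = noiseless_scene
        dapi = stack.channels["dapi"].copy()
        dapi[0, 0, 0] = dapi.max()  # bright single-voxel artefact
        speckled = ImageStack(
            channels={"dapi": dapi}, voxel_size_um=stack.voxel_size_um
        )
        seg = segment_nuclei(speckled)
        assert seg.max() == 2
        assert seg[0, 0, 0] == 0

    def test_iou_against_truth_at_default_noise(self, two_nucleus_scene):
        stack, true_labels, _ = two_nucleus_scene
        seg = segment_nuclei(stack)
        match = match_labels(seg, true_labels)
        assert len(match) == 2
        assert (match["iou"] >= 0.8).all()


class TestMarkerRules:
    def test_rule_true_includes_all(self, two_nucleus_scene):
        stack, _, _ = two_nucleus_scene
        seg = segment_nuclei(stack)
        flags = select_cells(seg, stack, rule="true")
        assert all(flags.values())

    def test_unknown_channel_rejected(self, two_nucleus_scene):
        stack, _, _ = two_nucleus_scene
        seg = segment_nuclei(stack)
        with pytest.raises(KeyError):
            select_cells(seg, stack, rule="notachannel+")

    def test_mast_cell_exclusion_rule(self):
        """One ckit+/tryptase- and one ckit+/tryptase+ nucleus under the
        rule 'ckit+ AND tryptase-': only the first survives."""
        spec = small_scene_spec()
        spec.nuclei[0].markers.update({"ckit": True, "tryptase": False})
        spec.nuclei[1].markers.update({"ckit": True, "tryptase": True})
        stack, true_labels, truth = simulate_confocal_scene(spec)
        seg = segment_nuclei(stack)
        match = match_labels(seg, true_labels).set_index("true_id")["seg_id"]
        flags = select_cells(seg, stack, rule="ckit+ AND tryptase-")
        assert flags[int(match[1])] is True
        assert flags[int(match[2])] is False

    def test_marker_flags_recovered_from_planted_truth(self):
        rng = np.random.default_rng(0)
        flags = [
            {"ckit": bool(rng.random() < 0.5), "tryptase": bool(rng.random() < 0.5)}
            for _ in range(24)
        ]
        spec = grid_ploidy_scene([2] * 24, seed=1, markers=flags)
        stack, true_labels, truth = simulate_confocal_scene(spec)
        seg = segment_nuclei(stack)
        meas = measure_nuclei(stack, seg, marker_channels=("ckit", "tryptase"))
        match = match_labels(seg, true_labels)
        merged = meas.merge(match, left_on="nucleus_id", right_on="seg_id").merge(
            truth, left_on="true_id", right_on="nucleus_id", suffixes=("", "_true")
        )
        assert (merged["ckit"] == merged["ckit_true"]).all()
        assert (merged["tryptase"] == merged["tryptase_true"]).all()


class TestWidestPlane:
    def test_sphere_equatorial_plane(self):
        z, y, x = np.ogrid[:15, :15, :15]
        sphere = ((z - 7) ** 2 + (y - 7) ** 2 + (x - 7) ** 2 <= 36).astype(np.int32)
        plane, roi = widest_plane(sphere, 1)
        assert plane == 7
        assert roi.sum() == (sphere[7] > 0).sum()

    def test_tilted_ellipsoid_matches_exhaustive_scan(self):
        spec = small_scene_spec(noiseless=True)
        spec.nuclei[0].rotation_deg = 30.0
        _, labels, _ = simulate_confocal_scene(spec)
        z, roi = widest_plane(labels, 1)
        # oracle: independent exhaustive scan over all planes
        areas = [(labels[k] == 1).sum() for k in range(labels.shape[0])]
        assert z == int(np.argmax(areas))
        assert roi.sum() == max(areas)

    def test_tie_breaks_to_smaller_z(self):
        labels = np.zeros((5, 4, 4), dtype=np.int32)
        labels[1, :2, :2] = 1
        labels[3, :2, :2] = 1  # same in-plane area
        z, _ = widest_plane(labels, 1)
        assert z == 1

    def test_absent_id_errors(self):
        with pytest.raises(KeyError):
            widest_plane(np.zeros((3, 3, 3), dtype=np.int32), 5)


class TestFIStatistic:
    def test_uniform_intensity_is_c_times_area(self):
        stack = _stack_from(np.full((4, 8, 8), 3.5))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:6] = True
        assert fi_statistic(stack, "dapi", mask, 1) == pytest.approx(3.5 * 12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_fi_equals_pixel_sum(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.gamma(2.0, 10.0, size=(3, 10, 10))
        mask = rng.random((10, 10)) < 0.4
        if not mask.any():
            mask[0, 0] = True
        stack = _stack_from(img)
        assert fi_statistic(stack, "dapi", mask, 2) == pytest.approx(
            img[2][mask].sum(), rel=1e-12
        )

    def test_empty_mask_errors(self):
        stack = _stack_from(np.ones((2, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            fi_statistic(stack, "dapi", np.zeros((4, 4), dtype=bool), 0)

    def test_invariant_to_pixels_outside_roi(self):
        rng = np.random.default_rng(1)
        img = rng.random((3, 8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[3:5, 3:5] = True
        before = fi_statistic(_stack_from(img), "dapi", mask, 1)
        img2 = img.copy()
        img2[1][~mask] += 100.0
        assert fi_statistic(_stack_from(img2), "dapi", mask, 1) == before

    def test_nested_rois_linear_in_area(self):
        img = np.full((1, 20, 20), 2.0)
        stack = _stack_from(img)
        areas, fis = [], []
        for r in (2, 4, 6, 8):
            mask = np.zeros((20, 20), dtype=bool)
            mask[:r, :r] = True
            areas.append(mask.sum())
            fis.append(fi_statistic(stack, "dapi", mask, 0))
        assert np.allclose(np.array(fis) / np.array(areas), 2.0)


class TestIntegrated3D:
    def test_single_voxel(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[1, 1, 1] = 1
        img = np.zeros((3, 3, 3))
        img[1, 1, 1] = 7.25
        assert integrated_intensity_3d(_stack_from(img), "dapi", labels, 1) == 7.25

    def test_equals_brute_force_loop(self):
        rng = np.random.default_rng(2)
        img = rng.random((10, 10, 10)) * 50
        labels = (rng.random((10, 10, 10)) < 0.3).astype(np.int32)
        total = 0.0
        for z in range(10):
            for y in range(10):
                for x in range(10):
                    if labels[z, y, x] == 1:
                        total += img[z, y, x]
        got = integrated_intensity_3d(_stack_from(img), "dapi", labels, 1)
        assert got == pytest.approx(total, rel=1e-12)

    def test_volume_mode_3d_vs_widest_plane_ratios(self):
        """Volume mode: 3-D ratio 4n/2n stays 2 while the widest-plane FI
        ratio drops to 2^(2/3) (the documented bias of the 2-D statistic)."""
        spec = small_scene_spec(signal_model="volume", seed=13)
        stack, labels, truth = simulate_confocal_scene(spec)
        by = truth.set_index("nucleus_id")["ploidy"]
        vals3d, fi = {}, {}
        for nid, p in by.items():
            vals3d[p] = integrated_intensity_3d(stack, "dapi", labels, nid)
            z, roi = widest_plane(labels, nid)
            fi[p] = fi_statistic(stack, "dapi", roi, z)
        assert vals3d[4] / vals3d[2] == pytest.approx(2.0, rel=0.02)
        assert fi[4] / fi[2] == pytest.approx(2 ** (2 / 3), rel=0.02)


def test_density_mode_expected_fi_ratio_monte_carlo():
    """E[FI(4n)] / E[FI(2n)] = 2 within 2 % over >= 100 nuclei in density
    mode (background-subtracted; the flat background otherwise shifts the
    ratio toward 1 by a predictable amount)."""
    spec = grid_ploidy_scene([2, 4] * 50, seed=21)
    stack, labels, truth = simulate_confocal_scene(spec)
    meas = measure_nuclei(stack, labels, background_subtract=True)
    merged = meas.merge(truth, on="nucleus_id", suffixes=("", "_t"))
    mean_fi = merged.groupby("ploidy")["fi"].mean()
    assert mean_fi[4] / mean_fi[2] == pytest.approx(2.0, rel=0.02)
    # without subtraction the ratio is diluted to (2s+b)/(s+b)
    raw = measure_nuclei(stack, labels).merge(truth, on="nucleus_id", suffixes=("", "_t"))
    raw_ratio = raw.groupby("ploidy")["fi"].mean()
    s, b = spec.photon_scale, spec.background_rate
    assert raw_ratio[4] / raw_ratio[2] == pytest.approx((2 * s + b) / (s + b), rel=0.02)


def test_end_to_end_bimodal_fi_mode_ratio():
    """A 60/40 2n/4n density-mode scene of 60 nuclei yields a bimodal FI
    distribution whose KDE mode ratio is 2 within 5 %."""
    ploidies = [2] * 36 + [4] * 24
    rng = np.random.default_rng(3)
    rng.shuffle(ploidies)
    spec = grid_ploidy_scene(ploidies, seed=3)
    stack, _, _ = simulate_confocal_scene(spec)
    seg = segment_nuclei(stack)
    meas = measure_nuclei(stack, seg)
    fi = meas["fi"].to_numpy()
    lo = kde_mode(fi[fi < np.median(fi) * 1.45])
    hi = kde_mode(fi[fi >= np.median(fi) * 1.45])
    assert hi / lo == pytest.approx(2.0, rel=0.05)
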
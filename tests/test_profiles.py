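"""Line-profile extraction, membrane detection and the RME statistic."""

import math

import numpy as np
import pandas as pd
import pytest
from skimage.morphology import dilation, disk

from rmekit import profiles as P
from rmekit.profiles import (
    LineProfile,
    aggregate_rme,
    cell_span,
    compute_rme,
    detect_membrane,
    detect_membrane_bruteforce,
    measure_scene_rme,
    place_profiles,
    sample_profile,
)


def _profile_from_values(values, step_um=0.1):
    values = np.asarray(values, dtype=float)
    pos = np.arange(len(values)) * step_um
    return LineProfile(endpoints=((0.0, 0.0), (0.0, len(values) - 1.0)),
                       positions=pos, intensities=values)


class TestSampleProfile:
    def test_constant_image(self):
        img = np.full((32, 32), 7.25)
        prof = sample_profile(img, ((4, 4), (20, 28)))
        assert np.allclose(prof.intensities, 7.25)

    def test_axis_aligned_integer_steps_hit_pixel_values(self):
        img = np.arange(64, dtype=float).reshape(8, 8)
        prof = sample_profile(img, ((3, 0), (3, 7)))
        # samples at 0.5-px steps: integer positions equal pixel values
        assert np.allclose(prof.intensities[::2], img[3, :])

    def test_diagonal_midpoint_of_checkerboard_is_four_pixel_mean(self):
        img = np.array([[1.0, 0.0], [0.0, 1.0]])
        # segment starting at the image centre: first sample sits exactly at
        # the point equidistant from all four pixels
        prof = sample_profile(img, ((0.5, 0.5), (1.0, 1.0)))
        assert prof.intensities[0] == pytest.approx(img.mean())

    def test_positions_in_micrometres(self):
        img = np.zeros((16, 16))
        prof = sample_profile(img, ((0, 0), (0, 10)), pixel_size=0.2)
        assert prof.positions[0] == 0.0
        assert prof.positions[-1] == pytest.approx(10 * 0.2, abs=0.1)

    def test_identical_endpoints_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            sample_profile(np.zeros((8, 8)), ((2, 2), (2, 2)))


def _disk_mask(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius


class TestPlaceProfiles:
    def test_no_nucleus_gives_default_angle_sweep(self):
        mask = _disk_mask((96, 96), (48, 48), 30)
        eps = place_profiles(mask, None, n_lines=3)
        angles = []
        for (p0, p1) in eps:
            d = np.subtract(p1, p0)
            angles.append(math.degrees(math.atan2(d[0], d[1])) % 180)
        assert sorted(round(a) for a in angles) == [0, 60, 120]

    def test_lines_extend_beyond_cell(self):
        mask = _disk_mask((96, 96), (48, 48), 30)
        for p0, p1 in place_profiles(mask, None):
            assert not mask[int(round(p0[0])), int(round(p0[1]))]
            assert not mask[int(round(p1[0])), int(round(p1[1]))]

    @pytest.mark.parametrize("nuc_center", [(48, 48), (48, 40)])
    def test_lines_avoid_dilated_nucleus(self, nuc_center):
        """Brute-force check: no returned line crosses the perinuclear mask."""
        mask = _disk_mask((96, 96), (48, 48), 30)
        nucleus = _disk_mask((96, 96), nuc_center, 8)
        avoid = dilation(nucleus, disk(2))
        eps = place_profiles(mask, nucleus, n_lines=3)
        assert len(eps) == 3
        for p0, p1 in eps:
            n = 500
            t = np.linspace(0, 1, n)
            rr = np.rint(p0[0] + t * (p1[0] - p0[0])).astype(int)
            cc = np.rint(p0[1] + t * (p1[1] - p0[1])).astype(int)
            assert not avoid[rr, cc].any()

    def test_impossible_placement_raises(self):
        # nucleus almost as large as the cell: no admissible chord anywhere
        mask = _disk_mask((96, 96), (48, 48), 20)
        nucleus = _disk_mask((96, 96), (48, 48), 18)
        with pytest.raises(ValueError, match="no admissible"):
            place_profiles(mask, nucleus)


class TestDetectMembrane:
    def test_half_height_rule_arithmetic(self):
        """Peaks 100 over baseline 20: segments are the samples >= 60."""
        v = np.full(40, 20.0)
        v[2:5] = [60, 100, 60]
        v[35:38] = [60, 100, 60]
        prof = _profile_from_values(v)
        segs = detect_membrane(prof, (0, 40))
        assert not segs.flat
        assert segs.baseline == 20.0
        assert segs.peak_heights == (100.0, 100.0)
        assert segs.entry == (2, 5)
        assert segs.exit == (35, 38)

    def test_flat_profile_triggers_flat_rule(self):
        prof = _profile_from_values(np.full(30, 12.0))
        segs = detect_membrane(prof, (0, 30))
        assert segs.flat
        assert segs.peak_heights == (12.0, 12.0)

    def test_short_span_rejected(self):
        prof = _profile_from_values(np.arange(10.0))
        with pytest.raises(ValueError, match="8 samples"):
            detect_membrane(prof, (0, 7))

    def test_agrees_with_bruteforce_oracle(self, rng):
        """Vectorized detection equals the naive scan on random profiles."""
        for _ in range(200):
            n = int(rng.integers(8, 50))
            v = rng.normal(50, 20, n)
            if rng.random() < 0.5:  # add membrane-like peaks
                v[int(rng.integers(0, max(n // 4, 1)))] += rng.uniform(0, 150)
                v[-1 - int(rng.integers(0, max(n // 4, 1)))] += rng.uniform(0, 150)
            prof = _profile_from_values(v)
            a = detect_membrane(prof, (0, n))
            b = detect_membrane_bruteforce(prof, (0, n))
            assert a.flat == b.flat
            assert a.entry == b.entry and a.exit == b.exit
            assert a.baseline == pytest.approx(b.baseline, rel=1e-12)
            assert a.peak_heights == pytest.approx(b.peak_heights, rel=1e-12)


class TestComputeRME:
    def test_direct_formula(self):
        """Entry peak 100, exit peak 60, intracellular 20: M=80, I_max=100."""
        v = np.full(60, 20.0)
        v[3:6] = [60, 100, 60]
        v[54:57] = [40, 60, 40]
        prof = _profile_from_values(v)
        segs = detect_membrane(prof, (0, 60))
        res = compute_rme(prof, segs, (0, 60))
        assert res.M == pytest.approx(80.0)
        assert res.C == pytest.approx(20.0)
        assert res.I_max == pytest.approx(100.0)
        assert res.rme == pytest.approx(100 * (80 - 20) / 100)

    def test_identity_invariant_and_bounds(self, single_cell_scene):
        for f in (0.0, 0.3, 0.7, 1.0):
            df = measure_scene_rme(single_cell_scene(f))
            for _, row in df.iterrows():
                assert row.rme == pytest.approx(
                    100 * (row.M - row.C) / row.I_max, rel=1e-9
                )
                assert row.I_max >= max(row.M, row.C) - 1e-9

    def test_background_subtraction_keeps_anchor(self, single_cell_scene):
        """The fully-membrane anchor survives a nonzero background level."""
        scene = single_cell_scene(1.0)
        for name in scene.channels:
            scene.channels[name] = scene.channels[name] + 25.0
        df = measure_scene_rme(scene)
        assert df.rme.mean() == pytest.approx(100.0, abs=2.0)

    def test_negative_rme_reported_and_flagged(self):
        """Boundary peaks dimmer than the intracellular mean give RME < 0."""
        v = np.full(40, 10.0)
        v[3] = 30.0
        v[36] = 30.0
        v[16:20] = 200.0  # bright intracellular structure
        prof = _profile_from_values(v)
        segs = detect_membrane(prof, (0, 40))
        res = compute_rme(prof, segs, (0, 40))
        assert res.rme < 0
        assert "negative" in res.flags

    def test_empty_cell_rejected(self):
        v = np.zeros(40)
        prof = _profile_from_values(v)
        segs = detect_membrane(prof, (0, 40))
        with pytest.raises(ValueError, match="I_max"):
            compute_rme(prof, segs, (0, 40))


class TestERExclusion:
    def test_no_er_is_identity(self, single_cell_scene):
        scene = single_cell_scene(0.3)
        plain = measure_scene_rme(scene).rme.mean()
        corrected = measure_scene_rme(scene, er_exclusion=True).rme.mean()
        assert corrected == pytest.approx(plain, abs=1e-9)

    def test_er_mask_covering_cytoplasm_rejected(self, single_cell_scene):
        scene = single_cell_scene(0.3)
        t = scene.truth[0]
        ep = place_profiles(t.cell, t.nucleus)[0]
        prof = sample_profile(scene.channels["protein"], ep, pixel_size=0.2)
        span = cell_span(prof, t.cell)
        segs = detect_membrane(prof, span)
        all_er = np.ones(len(prof.intensities), dtype=bool)
        with pytest.raises(ValueError, match="ER exclusion"):
            compute_rme(prof, segs, span, er_samples=all_er)


class TestAggregateRME:
    def test_constant_profiles(self):
        df = pd.DataFrame(
            dict(rme=[25.0] * 9, cell_id=[0, 0, 0, 1, 1, 1, 2, 2, 2],
                 repeat=[1, 1, 1, 2, 2, 2, 3, 3, 3])
        )
        agg = aggregate_rme(df)
        assert agg["mean"] == 25.0
        assert agg["sem"] == 0.0

    def test_repeat_sem_hand_value(self):
        """Repeat means {20, 30, 40}: SEM = SD/sqrt(3) = 5.7735."""
        df = pd.DataFrame(
            dict(rme=[20.0, 30.0, 40.0], cell_id=[0, 0, 0], repeat=[1, 2, 3])
        )
        agg = aggregate_rme(df)
        assert agg["mean"] == pytest.approx(30.0)
        assert agg["sem"] == pytest.approx(5.773503, abs=1e-5)

    def test_unbalanced_nesting_matches_bruteforce(self, rng):
        """Hierarchical mean equals the nested loop, not the pooled mean."""
        rows = []
        for rep in (1, 2, 3):
            for cell in range(int(rng.integers(2, 6))):
                for _ in range(int(rng.integers(1, 5))):
                    rows.append(dict(rme=float(rng.normal(30, 10)),
                                     cell_id=cell, repeat=rep))
        df = pd.DataFrame(rows)
        agg = aggregate_rme(df)
        # brute-force nested mean
        rep_means = []
        for rep, sub in df.groupby("repeat"):
            cellm = [g["rme"].mean() for _, g in sub.groupby("cell_id")]
            rep_means.append(np.mean(cellm))
        assert agg["mean"] == pytest.approx(np.mean(rep_means), rel=1e-12)
        assert agg["mean"] != pytest.approx(df["rme"].mean(), abs=1e-6)

    def test_single_repeat_flagged(self):
        df = pd.DataFrame(dict(rme=[10.0, 12.0], cell_id=[0, 1]))
        agg = aggregate_rme(df)
        assert math.isnan(agg["sem"])
        assert "fewer than 2 repeats" in agg["flag"]
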
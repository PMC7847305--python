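"""Contact classification: segmentation, profiles, overlap scoring, census."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kisspulse import (
    Apposition,
    ImageScene,
    IntensityProfile,
    MorphThresholds,
    SceneParams,
    classify_apposition,
    classify_contacts,
    contact_census,
    detect_boutons,
    extract_profile,
    match_boutons,
    overlap_length,
    pair_appositions,
    segment_dendrons,
    simulate_exm_scene,
)
from kisspulse.contacts import DendronSegment

from conftest import mixed_scene_params


def blank_scene(shape=(10, 40, 40)):
    chans = {c: np.zeros(shape, dtype=np.float32) for c in ("gfp", "kisspeptin", "synaptophysin")}
    return ImageScene(channels=chans, voxel_xy=0.1, voxel_z=0.3, expansion_factor=4.0)


class TestSegmentDendrons:
    def test_single_tube_length_recovered_pre_expansion(self):
        p = SceneParams(n_dendrons=1, dendron_length=60.0, n_boutons=0,
                        gap_distribution=[], expansion_factor=4.0, seed=1)
        scene, _ = simulate_exm_scene(p)
        thr = MorphThresholds(min_length_pre=10.0)
        segs = segment_dendrons(scene, thr)
        assert len(segs) == 1
        assert segs[0].length_pre == pytest.approx(15.0, rel=0.05)
        assert segs[0].length_post == pytest.approx(60.0, rel=0.05)
        assert segs[0].mean_radius == pytest.approx(p.dendron_radius, rel=0.15)

    def test_blank_volume_gives_no_segments(self):
        assert segment_dendrons(blank_scene()) == []

    def test_parallel_tubes_resolved(self, mixed_scene):
        scene, _ = mixed_scene
        segs = segment_dendrons(scene)
        assert len(segs) == 3
        for s in segs:
            assert s.length_post == pytest.approx(72.0, rel=0.05)

    def test_short_segments_discarded(self):
        p = SceneParams(n_dendrons=1, dendron_length=70.0, n_boutons=0,
                        gap_distribution=[], expansion_factor=4.17, seed=1)
        scene, _ = simulate_exm_scene(p)
        assert segment_dendrons(scene, MorphThresholds(min_length_pre=30.0)) == []


class TestDetectBoutons:
    def test_min_diameter_filter(self):
        # five 0.6 um and two 0.3 um puncta: only those above 0.4 um survive
        p = SceneParams(n_dendrons=1, dendron_length=70.0, n_boutons=7,
                        bouton_diameter_mean=0.6, bouton_diameter_sd=0.0,
                        gap_distribution=[(0.5, 5 / 7, None, 0.6), (0.5, 2 / 7, None, 0.3)],
                        voxel_xy=0.1, voxel_z=0.1, psf_sigma_xy=0.05, psf_sigma_z=0.05,
                        noise_snr=20.0, seed=2)
        scene, _ = simulate_exm_scene(p)
        boutons = detect_boutons(scene)
        assert len(boutons) == 5
        for b in boutons:
            assert b.equivalent_diameter == pytest.approx(0.6, abs=0.1)

    def test_empty_channels_give_no_boutons(self):
        assert detect_boutons(blank_scene()) == []

    def test_require_cochannel_excludes_kisspeptin_only(self):
        p = mixed_scene_params(seed=8, n_dendrons=1, n_boutons=10)
        p.cochannel_fraction = 0.5
        scene, gt = simulate_exm_scene(p)
        dual = detect_boutons(scene, require_cochannel=True)
        allb = detect_boutons(scene, require_cochannel=False)
        assert len(allb) == 10
        assert len(dual) == gt.has_synaptophysin.sum() == 5


class TestPairAndProfiles:
    def test_orientation_and_gap(self, mixed_scene):
        scene, gt = mixed_scene
        thr = MorphThresholds()
        segs = segment_dendrons(scene, thr)
        boutons = detect_boutons(scene, thr)
        apps = pair_appositions(boutons, segs, scene, thr)
        mapping = match_boutons(boutons, gt)
        n_checked = 0
        for a in apps:
            row = gt[gt.bouton_id == mapping[a.bouton_id]].iloc[0]
            assert a.orientation == row.orientation
            assert a.gap == pytest.approx(max(row.signed_gap, 0.0), abs=0.35)
            n_checked += 1
        assert n_checked == len(gt)

    def test_profile_peak_at_planted_bouton(self, mixed_scene):
        scene, gt = mixed_scene
        thr = MorphThresholds()
        segs = segment_dendrons(scene, thr)
        boutons = detect_boutons(scene, thr)
        apps = pair_appositions(boutons, segs, scene, thr)
        side = next(a for a in apps if a.orientation == "side" and a.gap > 1.5)
        prof = extract_profile(scene, side, thr)
        # bouton channel peaks where the bouton centre projects onto the scan
        peak_pos = prof.positions[np.argmax(prof.values["synaptophysin"])]
        expected = 3.5 + float(np.linalg.norm(side.bouton_centroid - side.anchor))
        assert peak_pos == pytest.approx(expected, abs=2 * scene.voxel_xy)
        assert prof.positions.shape == prof.values["gfp"].shape

    def test_constant_channel_profile_normalizes_to_one(self):
        scene = blank_scene()
        scene.channels["gfp"][:] = 1.0
        scene.channels["synaptophysin"][:] = 1.0
        app = Apposition(
            bouton_id=0, dendron_id=1, orientation="side", gap=0.0,
            bouton_centroid=np.array([1.5, 2.0, 2.0]),
            bouton_diameter=1.0, anchor=np.array([1.5, 1.0, 2.0]),
        )
        prof = extract_profile(scene, app, smooth_sigma=0.0)
        np.testing.assert_allclose(prof.values["gfp"], 1.0)


class TestOverlapLength:
    def test_identical_rectangles_give_their_width(self):
        x = np.arange(0.0, 5.0, 0.1)
        rect = ((x >= 1.0) & (x <= 3.0)).astype(float)
        prof = IntensityProfile(positions=x, values={"a": rect, "b": rect.copy()})
        assert overlap_length(prof, "a", "b") == pytest.approx(2.0, abs=0.1)

    def test_disjoint_supports_give_zero(self):
        x = np.arange(0.0, 5.0, 0.1)
        a = ((x >= 0.5) & (x <= 1.5)).astype(float)
        b = ((x >= 3.0) & (x <= 4.0)).astype(float)
        prof = IntensityProfile(positions=x, values={"a": a, "b": b})
        assert overlap_length(prof, "a", "b") == 0.0

    def test_gaussian_pair_matches_brute_force(self):
        # two unit Gaussians (sigma 0.3 um) 0.8 um apart, sampled at 0.1 um
        pitch, sigma, sep = 0.1, 0.3, 0.8
        x = np.arange(0.0, 6.0, pitch)
        a = np.exp(-((x - 2.6) ** 2) / (2 * sigma ** 2))
        b = np.exp(-((x - 2.6 - sep) ** 2) / (2 * sigma ** 2))
        prof = IntensityProfile(positions=x, values={"a": a, "b": b})
        xf = np.arange(0.0, 6.0, 0.001)
        af = np.exp(-((xf - 2.6) ** 2) / (2 * sigma ** 2))
        bf = np.exp(-((xf - 2.6 - sep) ** 2) / (2 * sigma ** 2))
        joint = np.minimum(af, bf) >= 0.5
        oracle = joint.sum() * 0.001
        assert overlap_length(prof, "a", "b") == pytest.approx(oracle, abs=pitch)

    @given(
        c1=st.floats(1.0, 5.0), c2=st.floats(1.0, 5.0),
        s1=st.floats(0.15, 0.8), s2=st.floats(0.15, 0.8),
        level=st.floats(0.2, 0.8),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_monotone_in_level(self, c1, c2, s1, s2, level):
        x = np.arange(0.0, 6.0, 0.1)
        a = np.exp(-((x - c1) ** 2) / (2 * s1 ** 2))
        b = np.exp(-((x - c2) ** 2) / (2 * s2 ** 2))
        pab = IntensityProfile(positions=x, values={"a": a, "b": b})
        pba = IntensityProfile(positions=x, values={"a": b, "b": a})
        assert overlap_length(pab, "a", "b", level) == pytest.approx(
            overlap_length(pba, "a", "b", level)
        )
        assert overlap_length(pab, "a", "b", level) >= overlap_length(
            pab, "a", "b", min(level + 0.1, 0.95)
        ) - 1e-9


class TestClassifyApposition:
    @pytest.mark.parametrize(
        "orientation,overlap,gap,expected",
        [
            ("side", 1.2, 0.0, "synapse"),
            ("side", 0.95, 0.0, "close_nonsynaptic"),  # strict inequality at threshold
            ("face", 1.8, 0.0, "synapse"),
            ("face", 1.75, 0.0, "close_nonsynaptic"),
            ("side", 0.0, 0.5, "close_nonsynaptic"),
            ("side", 0.0, 2.5, "separate"),
        ],
    )
    def test_threshold_rule(self, orientation, overlap, gap, expected):
        cand = Apposition(bouton_id=0, dendron_id=0, orientation=orientation, gap=gap)
        out = classify_apposition(cand, overlap)
        assert out.label == expected

    def test_rescaled_coordinates_and_thresholds_agree(self):
        # classification depends only on ratios: scaling lengths and thresholds
        # by the same factor leaves every label unchanged
        rng = np.random.default_rng(0)
        base = MorphThresholds()
        k = 2.7
        scaled = MorphThresholds(theta_side=k * base.theta_side,
                                 theta_face=k * base.theta_face,
                                 close_gap=k * base.close_gap)
        for _ in range(200):
            ori = "side" if rng.random() < 0.5 else "face"
            ov, gap = rng.uniform(0, 3), rng.uniform(0, 3)
            l1 = classify_apposition(
                Apposition(0, 0, ori, gap), ov, base).label
            l2 = classify_apposition(
                Apposition(0, 0, ori, k * gap), k * ov, scaled).label
            assert l1 == l2

    def test_class_invariant_holds_on_pipeline_output(self, mixed_scene):
        scene, _ = mixed_scene
        thr = MorphThresholds()
        apps, _, _ = classify_contacts(scene, thr)
        for a in apps:
            theta = thr.theta_side if a.orientation == "side" else thr.theta_face
            assert (a.label == "synapse") == (a.overlap > theta)


class TestConfocalMode:
    def test_touching_is_close_apposition_gap_is_separate(self):
        labels = {}
        for gap, expected in [(0.05, "close_nonsynaptic"), (1.5, "separate")]:
            p = SceneParams(n_dendrons=1, dendron_length=20.0, n_boutons=2,
                            gap_distribution=[(gap, 1.0, "side", 1.0)],
                            dendron_radius=1.0, voxel_xy=0.1, voxel_z=0.38,
                            expansion_factor=1.0, modality="confocal",
                            noise_snr=15.0, seed=3)
            scene, _ = simulate_exm_scene(p)
            apps, _, _ = classify_contacts(scene, MorphThresholds(min_length_pre=10.0))
            assert apps, f"no appositions at gap={gap}"
            labels[gap] = {a.label for a in apps}
            assert labels[gap] == {expected}


class TestContactCensus:
    def _seg(self, length_pre):
        return DendronSegment(dendron_id=1, skeleton=np.zeros((2, 3)),
                              mean_radius=1.0, length_post=4 * length_pre,
                              length_pre=length_pre)

    def test_density_arithmetic(self):
        apps = [Apposition(i, 1, "side", 0.2, label="close_nonsynaptic") for i in range(8)]
        stats = contact_census(apps, [self._seg(200.0)], 4.0)
        assert stats.appositions_per_100um == pytest.approx(4.0)

    def test_zero_synapses_reported_as_zero_density(self):
        apps = [Apposition(i, 1, "side", 0.5, label="close_nonsynaptic") for i in range(5)]
        stats = contact_census(apps, [self._seg(100.0)], 4.0)
        assert stats.n_synapses == 0
        assert stats.synapses_per_10um == 0.0

    def test_zero_length_raises(self):
        with pytest.raises(ValueError, match="zero"):
            contact_census([], [], 4.0)

    def test_fiber_divergence_recovered(self):
        p = SceneParams(n_dendrons=5, dendron_length=72.0, n_boutons=40,
                        gap_distribution=[(-1.6, 0.5, "side", 2.0), (0.4, 0.5, "side", 2.0)],
                        fiber_divergence=4.0, noise_snr=8.0, seed=21)
        scene, gt = simulate_exm_scene(p)
        apps, dendrons, boutons = classify_contacts(scene)
        mapping = match_boutons(boutons, gt)
        gt_fibers = dict(zip(gt.bouton_id, gt.fiber_id))
        fibers = {bid: gt_fibers[gid] for bid, gid in mapping.items()}
        stats = contact_census(apps, dendrons, scene.expansion_factor, fiber_ids=fibers)
        planted = gt.groupby("fiber_id").dendron_id.nunique().mean()
        assert stats.dendrons_per_fiber == pytest.approx(planted, rel=0.10)
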
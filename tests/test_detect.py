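"""Seeding, region growing, border acceptance and the whole-volume scan."""

import numpy as np
import pytest

from faupa.core_stats import Thresholds
from faupa.detect import (DetectionConfig, _CourseCache, border_check,
                          detect_faupas, grow_roi, make_seed, verify_faupa)
from faupa.synth import SyntheticSpec, recovery_metrics, simulate
from faupa.volume_io import GridGeometry, border_layer, connected_components

from conftest import SMALL_GEO, make_noise_volume, plant_block

CFG = DetectionConfig()
RNG = np.random.default_rng(5)


def _course(T=160, seed=0):
    rng = np.random.default_rng(seed)
    # smooth band-limited-ish course with unit variance
    g = np.cumsum(rng.standard_normal(T))
    g = g - np.polyval(np.polyfit(np.arange(T), g, 3), np.arange(T))
    return g / g.std()


class TestMakeSeed:
    def test_noise_free_block_seeds_with_r_one(self):
        block = {(x, y, z) for x in (4, 5, 6) for y in (4, 5, 6) for z in (4, 5, 6)}
        vol = plant_block(SMALL_GEO, block, _course(), noise_sd=1.0, seed=1)
        seed = make_seed((5, 5, 5), vol, CFG)
        assert seed is not None and len(seed) == CFG.seed_size
        assert seed <= block - {(5, 5, 5)}

    def test_white_noise_never_seeds(self):
        # Monte-Carlo null: at 160 points the chance of 4 neighbours above
        # r=0.9 is astronomically small
        geo = GridGeometry((5, 5, 5), (3.5,) * 3, 2.5, 160)
        hits = 0
        for rep in range(500):
            vol = make_noise_volume(geo, seed=rep)
            if make_seed((2, 2, 2), vol, CFG) is not None:
                hits += 1
        assert hits == 0

    def test_three_neighbours_above_threshold_is_not_enough(self):
        g = _course()
        members = {(5, 5, 5), (4, 5, 5), (6, 5, 5), (5, 4, 5)}  # centre + 3
        vol = plant_block(SMALL_GEO, members, g, noise_sd=1.0, seed=2)
        assert make_seed((5, 5, 5), vol, CFG) is None

    def test_degenerate_centre_returns_none(self):
        vol = make_noise_volume(SMALL_GEO, seed=3)
        vol.data[5, 5, 5, :] = 0.0
        assert make_seed((5, 5, 5), vol, CFG) is None


class TestGrowRoi:
    def test_noise_free_cross_recovered_exactly(self):
        cross = {(5, 5, 5), (4, 5, 5), (6, 5, 5), (5, 4, 5), (5, 6, 5)}
        vol = plant_block(SMALL_GEO, cross, _course(), noise_sd=1.0, seed=4)
        seed = make_seed((5, 5, 5), vol, CFG)
        assert seed is not None
        grown = grow_roi(seed, (5, 5, 5), vol, CFG)
        assert grown is not None
        assert set(grown.voxels) == cross
        assert grown.n_iterations <= 3
        assert np.all(grown.r_values == 1.0)

    def test_oversized_block_fails_by_cap(self):
        block = {(x, y, z) for x in range(3, 8) for y in range(3, 7)
                 for z in range(3, 5)}  # 40 voxels > 29
        vol = plant_block(SMALL_GEO, block, _course(), noise_sd=1.0, seed=5)
        seed = make_seed((5, 5, 4), vol, CFG)
        assert seed is not None
        assert grow_roi(seed, (5, 5, 4), vol, CFG) is None

    def test_white_noise_volume_yields_nothing(self):
        for rep in range(5):
            vol = make_noise_volume(SMALL_GEO, seed=400 + rep)
            faupas, _ = detect_faupas(vol, CFG)
            assert faupas == []


class TestBorderCheck:
    def _roi_volume(self):
        g = _course(T=SMALL_GEO.n_timepoints, seed=9)
        roi = {(x, y, z) for x in (8, 9) for y in (8, 9) for z in (4, 5)}
        vol = plant_block(SMALL_GEO, roi, g, noise_sd=1.0, seed=6)
        return vol, roi, g

    def test_independent_noise_border_accepted(self):
        vol, roi, _ = self._roi_volume()
        th = Thresholds(th1=0.9, th2=0.85)
        check = border_check(roi, th, vol, CFG)
        assert check.k_total == 56
        assert check.l_count == 0
        assert check.accepted

    def test_planted_band_correlations_force_rejection(self):
        vol, roi, g = self._roi_volume()
        cache = _CourseCache(vol)
        arr = np.asarray(sorted(roi))
        mean_course = cache.data[arr[:, 0], arr[:, 1], arr[:, 2], :].mean(axis=0)
        zm = (mean_course - mean_course.mean())
        zm /= np.linalg.norm(zm)
        # give 10% of the border (6 of 56) a course with r = 0.875 in (th2, th1)
        border = sorted(border_layer(roi, vol.mask))
        rng = np.random.default_rng(12)
        target_r = 0.875
        for v in border[:6]:
            u = rng.standard_normal(SMALL_GEO.n_timepoints)
            u -= u.mean()
            u -= (u @ zm) * zm
            u /= np.linalg.norm(u)
            vol.data[v[0], v[1], v[2], :] = (
                target_r * zm + np.sqrt(1 - target_r ** 2) * u)
        th = Thresholds(th1=0.9, th2=0.85)
        check = border_check(roi, th, vol, CFG)
        assert check.l_count == 6
        assert check.k_crit == pytest.approx(0.04 * 56)
        assert not check.accepted

    def test_empty_border_accepted(self):
        geo = GridGeometry((2, 2, 2), (3.5,) * 3, 2.5, 20)
        roi = {(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)}
        vol = plant_block(geo, roi, _course(T=20, seed=1), noise_sd=0.0, seed=0)
        check = border_check(roi, Thresholds(0.9, 0.85), vol, CFG)
        assert check.k_total == 0 and check.accepted


class TestDetectFaupas:
    def test_planted_cluster_recovery_low_noise(self):
        # oracle-derived regime: at noise sd 0.15 most planted clusters are
        # found as cores; no detection strays off the planted truth
        sens, fps, dices = [], [], []
        for seed in (1, 2, 3):
            spec = SyntheticSpec(geometry=SMALL_GEO, n_clusters=5,
                                 noise_sd=0.15, rng_seed=seed)
            vol, truth = simulate(spec)
            faupas, labelmap = detect_faupas(vol, CFG)
            rep = recovery_metrics(faupas, truth)
            sens.append(rep.sensitivity)
            fps.append(rep.n_false_positives)
            dices += list(rep.dice_values)
        assert np.mean(sens) >= 0.6
        assert fps == [0, 0, 0]
        assert np.median(dices) >= 0.5

    def test_noise_free_recovery_is_exact_with_r_bar_one(self):
        spec = SyntheticSpec(geometry=SMALL_GEO, n_clusters=4, noise_sd=0.0,
                             rng_seed=8)
        vol, truth = simulate(spec)
        faupas, _ = detect_faupas(vol, CFG)
        rep = recovery_metrics(faupas, truth)
        assert rep.sensitivity == 1.0
        assert np.all(rep.dice_values == 1.0)
        assert all(f.r_bar == 1.0 for f in faupas)

    def test_output_contract(self):
        spec = SyntheticSpec(geometry=SMALL_GEO, n_clusters=5, noise_sd=0.2,
                             rng_seed=3)
        vol, _ = simulate(spec)
        faupas, labelmap = detect_faupas(vol, CFG)
        assert len(faupas) > 0
        seen = set()
        for f in faupas:
            assert CFG.min_voxels <= f.n_voxels <= CFG.max_voxels
            assert len(connected_components(set(f.voxels))) == 1
            assert not seen & set(f.voxels)         # pairwise disjoint
            seen |= set(f.voxels)
            assert np.all(f.r_values >= f.th1)      # final-threshold membership
            assert f.r_bar == pytest.approx(np.mean(f.r_values))
            assert np.allclose(f.mean_course,
                               vol.courses(f.voxels).mean(axis=0))
        for f in faupas:
            assert labelmap.voxels_of(f.id) == set(f.voxels)

    def test_determinism(self):
        spec = SyntheticSpec(geometry=SMALL_GEO, n_clusters=5, noise_sd=0.25,
                             rng_seed=5)
        vol, _ = simulate(spec)
        a, _ = detect_faupas(vol, CFG)
        b, _ = detect_faupas(vol, CFG)
        assert [f.voxels for f in a] == [f.voxels for f in b]
        assert all(np.array_equal(x.r_values, y.r_values) for x, y in zip(a, b))

    def test_self_consistency(self):
        spec = SyntheticSpec(geometry=SMALL_GEO, n_clusters=5, noise_sd=0.2,
                             rng_seed=4)
        vol, _ = simulate(spec)
        faupas, _ = detect_faupas(vol, CFG)
        assert faupas and all(verify_faupa(f, vol, CFG) for f in faupas)

    def test_r_bar_decreases_with_noise(self):
        means = []
        for sd in (0.05, 0.2, 0.35):
            spec = SyntheticSpec(noise_sd=sd, rng_seed=2)
            vol, _ = simulate(spec)
            faupas, _ = detect_faupas(vol, CFG)
            assert faupas
            means.append(np.mean([f.r_bar for f in faupas]))
        assert means[0] > means[1] > means[2]
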
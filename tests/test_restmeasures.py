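import numpy as np
import pytest

import neurofuse as nf
from neurofuse import restmeasures as rm
from neurofuse.errors import ContractError
from conftest import correlated_series
from oracles import fcd_bruteforce


class TestStaticFCD:
    def test_line_of_four_voxels_counts(self, rng):
        # voxels on a 1x4x1 line at y = 0..3: A=0, B=1 (adjacent to A),
        # D=2, C=3 (C is NOT adjacent to A); r to A: B=.9, C=.9, D=.1
        series = correlated_series(rng, 50, np.array([0.9, 0.1, 0.9]))
        a, b, d, c = series
        data = np.stack([a, b, d, c])[None, :, None, :]
        vol = nf.Volume4D(data, 2.0, (3, 3, 3), np.eye(4))
        mask = nf.BrainMask(np.ones((1, 4, 1), bool))
        maps = nf.compute_fcd(vol, mask, nf.FCDParams((0.6,)))
        A = (0, 0, 0)
        assert maps.gfcd[0.6][A] == 2
        assert maps.lfcd[0.6][A] == 1
        assert maps.lrfcd[0.6][A] == 1

    def test_identical_series_fully_connected(self):
        base = np.sin(np.arange(30))
        data = np.tile(base, (3, 3, 3, 1))
        vol = nf.Volume4D(data, 2.0, (3, 3, 3), np.eye(4))
        mask = nf.BrainMask(np.ones((3, 3, 3), bool))
        maps = nf.compute_fcd(vol, mask, nf.FCDParams((0.5,)))
        assert np.all(maps.gfcd[0.5][mask.flags] == 26)
        assert np.allclose(maps.normalized[("gfcd", 0.5)][mask.flags], 1.0)

    def test_gfcd_monotone_in_threshold(self, rng):
        vol, mask, _ = nf.simulate_bold((5, 5, 5), T=60, seed=21)
        maps = nf.compute_fcd(vol, mask, nf.FCDParams())
        thr = maps.thresholds
        for lo, hi in zip(thr, thr[1:]):
            diff = maps.gfcd[lo][mask.flags] - maps.gfcd[hi][mask.flags]
            assert np.all(diff >= 0)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_bruteforce_oracle(self, connectivity):
        vol, mask, _ = nf.simulate_bold(
            (5, 5, 5), T=40, seed=31 + connectivity,
            hub_voxels=[[(1, 1, 1), (1, 1, 2), (1, 2, 1), (3, 3, 3)]],
            hub_target_r=0.7)
        params = nf.FCDParams((0.2, 0.4, 0.6), connectivity)
        maps = nf.compute_fcd(vol, mask, params)
        for th in params.thresholds:
            lref, gref = fcd_bruteforce(vol.data, mask.flags, th, connectivity)
            assert np.array_equal(maps.gfcd[th][mask.flags],
                                  gref[mask.flags])
            assert np.array_equal(maps.lfcd[th][mask.flags],
                                  lref[mask.flags])

    def test_lrfcd_identity_and_bounds(self):
        vol, mask, _ = nf.simulate_bold((5, 5, 5), T=50, seed=41)
        maps = nf.compute_fcd(vol, mask, nf.FCDParams((0.3, 0.6)))
        for th in (0.3, 0.6):
            lf, gf = maps.lfcd[th][mask.flags], maps.gfcd[th][mask.flags]
            assert np.array_equal(maps.lrfcd[th][mask.flags], gf - lf)
            assert np.all(lf <= gf)
            assert np.all(gf <= mask.count - 1)

    def test_normalized_mean_is_one(self):
        vol, mask, _ = nf.simulate_bold((5, 5, 5), T=50, seed=42)
        maps = nf.compute_fcd(vol, mask, nf.FCDParams((0.3,)))
        for key, m in maps.normalized.items():
            assert np.nanmean(m[mask.flags]) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_voxel_warned_and_zero(self):
        vol, mask, _ = nf.simulate_bold((4, 4, 4), T=40, seed=43)
        data = vol.data.copy()
        data[0, 0, 0] = 5.0  # flat series
        vol = vol.with_data(data)
        with pytest.warns(UserWarning, match="zero temporal variance"):
            maps = nf.compute_fcd(vol, mask, nf.FCDParams((0.3,)))
        assert maps.gfcd[0.3][0, 0, 0] == 0
        assert maps.zero_variance[0, 0, 0]


class TestDynamicFCD:
    def test_single_window_equals_static(self):
        vol, mask, _ = nf.simulate_bold((4, 4, 4), T=40, seed=51)
        params = nf.FCDParams((0.4,), window_trs=40, step_trs=10)
        dyn = nf.compute_dynamic_fcd(vol, mask, params)
        static = nf.compute_fcd(vol, mask, nf.FCDParams((0.4,)))
        assert len(dyn) == 1
        assert np.array_equal(dyn[0].gfcd[0.4][mask.flags],
                              static.gfcd[0.4][mask.flags])

    def test_window_count_formula(self):
        vol, mask, _ = nf.simulate_bold((4, 4, 4), T=100, seed=52)
        dyn = nf.compute_dynamic_fcd(
            vol, mask, nf.FCDParams((0.4,), window_trs=40, step_trs=20))
        assert len(dyn) == (100 - 40) // 20 + 1 == 4

    def test_window_longer_than_run_rejected(self):
        vol, mask, _ = nf.simulate_bold((4, 4, 4), T=30, seed=53)
        with pytest.raises(ContractError):
            nf.compute_dynamic_fcd(
                vol, mask, nf.FCDParams((0.4,), window_trs=50))

    def test_nonstationary_volume_varies_more_across_windows(self):
        hub = [(1, 1, 1), (1, 1, 2), (1, 2, 1), (2, 1, 1)]
        vol_s, mask, _ = nf.simulate_bold((4, 4, 4), T=120, seed=7,
                                          hub_voxels=[hub], hub_target_r=0.6)
        # nonstationary: hub coupling present only in the second half
        vol_n0, _, _ = nf.simulate_bold((4, 4, 4), T=60, seed=8)
        vol_n1, _, _ = nf.simulate_bold((4, 4, 4), T=60, seed=9,
                                        hub_voxels=[hub], hub_target_r=0.9)
        vol_n = vol_s.with_data(
            np.concatenate([vol_n0.data, vol_n1.data], axis=3))
        params = nf.FCDParams((0.4,), window_trs=40, step_trs=20)

        def window_sd(vol):
            windows = nf.compute_dynamic_fcd(vol, mask, params)
            series = np.stack([w.gfcd[0.4][hub[0]] for w in windows])
            return series.std()

        assert window_sd(vol_n) > window_sd(vol_s)


class TestFOCA:
    def test_perfect_consistency_scores_one(self):
        T = 30
        f = 2.0 + np.sin(np.arange(T) * 0.7) + np.arange(T) * 0.01
        amps = np.linspace(1.0, 3.0, 27)
        data = np.einsum("v,t->vt", amps, f).reshape(3, 3, 3, T)
        vol = nf.Volume4D(data, 2.0, (3, 3, 3), np.eye(4))
        mask = nf.BrainMask(np.ones((3, 3, 3), bool))
        foca = nf.compute_foca(vol, mask)
        assert foca.raw[1, 1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_scores_near_zero(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((7, 7, 7, 200))
        vol = nf.Volume4D(data, 2.0, (3, 3, 3), np.eye(4))
        mask = nf.BrainMask(np.ones((7, 7, 7), bool))
        foca = nf.compute_foca(vol, mask)
        interior = foca.raw[1:-1, 1:-1, 1:-1]
        assert interior.size >= 100
        assert interior.mean() < 0.05

    def test_values_in_unit_interval_and_norm_mean_one(self):
        vol, mask, _ = nf.simulate_bold((5, 5, 5), T=40, seed=61)
        foca = nf.compute_foca(vol, mask)
        vals = foca.raw[mask.flags]
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.nanmean(foca.normalized[mask.flags & ~foca.flagged]) == \
            pytest.approx(1.0, abs=1e-9)

    def test_affine_rescaling_invariance(self):
        vol, mask, _ = nf.simulate_bold((4, 4, 4), T=40, seed=62)
        a = nf.compute_foca(vol, mask)
        b = nf.compute_foca(vol.with_data(3.0 * vol.data + 11.0), mask)
        assert np.allclose(a.raw[mask.flags], b.raw[mask.flags], atol=1e-10)

    def test_small_neighborhood_flagged(self):
        vol, _, _ = nf.simulate_bold((4, 4, 4), T=40, seed=63)
        flags = np.zeros((4, 4, 4), bool)
        flags[0, 0, :] = True  # corner line: every neighborhood < 9 members
        foca = nf.compute_foca(vol, nf.BrainMask(flags))
        assert foca.flagged[0, 0, 0]
        assert foca.raw[0, 0, 0] == 0.0


class TestDynamicSeriesStats:
    def test_constant_series(self):
        out = rm.dynamic_series_stats(np.full(6, 4.2))
        assert out["mean"] == pytest.approx(4.2)
        assert out["sd"] == 0 and out["cov"] == 0
        assert out["mean_point_change"] == 0
        assert out["mean_relative_ratio"] == 1

    def test_two_point_series(self):
        out = rm.dynamic_series_stats(np.array([1.0, 2.0]))
        assert out["mean_point_change"] == pytest.approx(1.0)
        assert out["mean_relative_ratio"] == pytest.approx(2.0)

    def test_cov_is_sd_over_mean(self, rng):
        x = rng.random(50) + 0.5
        out = rm.dynamic_series_stats(x)
        assert out["cov"] == pytest.approx(out["sd"] / out["mean"],
                                           abs=1e-12)

    def test_zero_predecessor_flags_ratio_indices_only(self):
        out = rm.dynamic_series_stats(np.array([0.0, 1.0, 2.0]))
        assert np.isnan(out["mean_relative_ratio"])
        assert np.isnan(out["mean_point_change"])
        assert np.isfinite(out["mean"]) and np.isfinite(out["sd"])

    def test_elementwise_over_map_series(self, rng):
        maps = rng.random((5, 3, 3)) + 1.0
        out = rm.dynamic_series_stats(maps)
        assert out["mean"].shape == (3, 3)
        one = rm.dynamic_series_stats(maps[:, 1, 2])
        assert out["cov"][1, 2] == pytest.approx(one["cov"])

    def test_too_short_rejected(self):
        with pytest.raises(ContractError):
            rm.dynamic_series_stats(np.array([1.0]))
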
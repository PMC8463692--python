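import numpy as np
import pandas as pd
import pytest

import lfpspike as lp
from lfpspike.analyses import SubsetCurve, heatmap_to_table
from lfpspike.features import FeatureColumn, FeatureMatrix, TargetColumn, TargetMatrix


def _channel_features(values, feature="lmp"):
    cols = tuple(FeatureColumn(ch + 1, feature) for ch in range(values.shape[1]))
    return FeatureMatrix(values, cols)


def _esa_targets(values):
    cols = tuple(TargetColumn("esa", ch + 1) for ch in range(values.shape[1]))
    return TargetMatrix(values, cols)


class TestFeatureInformativeness:
    def test_identical_feature_types_score_identically(self, rng):
        X = rng.standard_normal((300, 4))
        Y = _esa_targets(X[:, :2] + 0.1 * rng.standard_normal((300, 2)))
        by_type = {
            "lmp": _channel_features(X, "lmp"),
            "copy": _channel_features(X.copy(), "delta"),
        }
        # the combined model's design is rank-deficient by construction
        with pytest.warns(RuntimeWarning, match="rank"):
            cc, _ = lp.feature_informativeness(by_type, Y, lp.partition_blocks(300, 10))
        vals = cc.set_index("feature_type")["mean_cc"]
        assert vals["lmp"] == pytest.approx(vals["copy"], abs=1e-9)

    def test_uncoupled_feature_gets_small_weights(self):
        g = np.random.default_rng(8)
        n = 2000
        latent = g.standard_normal((n, 3))
        coupled = latent + 0.1 * g.standard_normal((n, 3))
        noise = g.standard_normal((n, 3))
        Y = _esa_targets(latent @ g.standard_normal((3, 2)))
        by_type = {
            "lmp": _channel_features(coupled, "lmp"),
            "alpha": _channel_features(noise, "alpha"),
        }
        cc, coef = lp.feature_informativeness(by_type, Y, lp.partition_blocks(n, 10))
        w = coef.set_index("feature_type")["mean_abs_coef"]
        assert w["lmp"] >= 5 * w["alpha"]
        c = cc.set_index("feature_type")["mean_cc"]
        assert c["lmp"] > c["alpha"]

    def test_missing_expected_type_rejected(self, rng):
        by_type = {"lmp": _channel_features(rng.standard_normal((100, 2)))}
        with pytest.raises(ValueError, match="missing"):
            lp.feature_informativeness(
                by_type, _esa_targets(rng.standard_normal((100, 1))),
                lp.partition_blocks(100, 10), expected_types=("lmp", "gamma"),
            )


class TestSubsetCurve:
    def _data(self, seed, n=600, n_ch=8):
        g = np.random.default_rng(seed)
        latent = g.standard_normal(n)
        X = latent[:, None] + 0.8 * g.standard_normal((n, n_ch))
        Y = latent[:, None] + 0.5 * g.standard_normal((n, 1))
        return _channel_features(X), _esa_targets(Y)

    def test_full_subset_matches_direct_cross_validation(self):
        X, Y = self._data(0)
        part = lp.partition_blocks(X.n, 10)
        curve = lp.channel_subset_curve(X, Y, part, p_grid=[8], iterations=5, seed=1)
        direct = lp.cross_validate(X, Y, part).mean_cc
        assert curve.mean_cc[0] == pytest.approx(direct, abs=1e-12)
        assert curve.ci_low[0] == curve.ci_high[0] == pytest.approx(direct, abs=1e-12)

    def test_fixed_seed_reproducible(self):
        X, Y = self._data(1)
        part = lp.partition_blocks(X.n, 10)
        c1 = lp.channel_subset_curve(X, Y, part, p_grid=[2, 4], iterations=5, seed=3)
        c2 = lp.channel_subset_curve(X, Y, part, p_grid=[2, 4], iterations=5, seed=3)
        np.testing.assert_array_equal(c1.per_iteration, c2.per_iteration)

    def test_more_redundant_channels_do_not_hurt(self):
        wins = 0
        for seed in range(20):
            X, Y = self._data(100 + seed)
            part = lp.partition_blocks(X.n, 10)
            curve = lp.channel_subset_curve(X, Y, part, p_grid=[2, 6], iterations=8, seed=seed)
            wins += curve.mean_cc[1] >= curve.mean_cc[0]
        assert wins > 10

    def test_oversized_subset_rejected(self):
        X, Y = self._data(2)
        with pytest.raises(ValueError):
            lp.channel_subset_curve(X, Y, lp.partition_blocks(X.n, 10), p_grid=[99])


class TestChannelsToFraction:
    def _curve(self, p, m):
        p = np.asarray(p, float)
        m = np.asarray(m, float)
        return SubsetCurve(p, m, m, m, np.tile(m[:, None], 2), 2, 0)

    def test_interpolated_crossing_bracketed(self):
        p = np.array([1, 5, 10, 20, 30, 35, 96])
        m = np.array([0.1, 0.3, 0.5, 0.7, 0.85, 0.93, 1.0])
        out = lp.channels_to_fraction(self._curve(p, m), 0.9)
        assert 30 < out <= 35

    def test_constant_curve_returns_smallest_count(self):
        out = lp.channels_to_fraction(self._curve([1, 5, 10], [0.5, 0.5, 0.5]), 0.9)
        assert out == 1

    def test_hand_interpolated_example(self):
        out = lp.channels_to_fraction(self._curve([1, 5, 10], [0.2, 0.8, 1.0]), 0.9)
        assert out == 8

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lp.channels_to_fraction(self._curve([1], [1.0]), 0.0)


class TestInterchannelCorrelation:
    def test_identical_channels_fully_correlated(self):
        x = np.tile(np.sin(np.linspace(0, 20, 5000)), (4, 1))
        corr, mean_off = lp.interchannel_correlation(x)
        np.testing.assert_allclose(corr, 1.0)
        assert mean_off == pytest.approx(1.0)

    def test_independent_channels_near_zero(self, rng):
        x = rng.standard_normal((20, 60000))
        corr, mean_off = lp.interchannel_correlation(x)
        assert abs(mean_off) < 0.02
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_constant_channel_flagged_nan(self, rng):
        x = rng.standard_normal((3, 1000))
        x[1] = 5.0
        with pytest.warns(RuntimeWarning, match="constant"):
            corr, _ = lp.interchannel_correlation(x)
        assert np.isnan(corr[1]).all() and np.isnan(corr[:, 1]).all()


class TestChannelImportance:
    def _session(self, seed=0, n=2000, n_ch=6, driver=2):
        """Output driven solely by channel ``driver`` (1-based id driver+1)."""
        g = np.random.default_rng(seed)
        X = g.standard_normal((n, n_ch))
        y = X[:, [driver]] + 0.05 * g.standard_normal((n, 1))
        amap = lp.grid_for_channels(n_ch)
        return _channel_features(X), _esa_targets(y), amap

    @pytest.mark.parametrize("metric", ["cc", "coef"])
    def test_driving_channel_ranks_first(self, metric):
        X, Y, amap = self._session()
        part = lp.partition_blocks(X.n, 10)
        table = lp.channel_importance(X, Y, part, amap, metric=metric)
        top = table.loc[table["score"].idxmax(), "input_channel"]
        assert top == 3  # channel id of the driving column

    def test_noise_channel_weight_small_relative_to_coupled(self):
        X, Y, amap = self._session(seed=5)
        part = lp.partition_blocks(X.n, 10)
        table = lp.channel_importance(X, Y, part, amap, metric="coef")
        scores = table.set_index("input_channel")["score"]
        assert scores.drop(3).max() <= 0.2 * scores[3]

    def test_single_channel_cc_is_definitional(self):
        """With p=1 the importance equals the cross-validated CC of that
        channel's own model, pooled over folds."""
        X, Y, amap = self._session(seed=7, n=500)
        part = lp.partition_blocks(X.n, 10)
        table = lp.channel_importance(X, Y, part, amap, metric="cc")
        ch1 = X.select(channels=[1])
        direct = lp.cross_validate(ch1, Y, part).records["cc"].mean()
        row = table[(table["input_channel"] == 1)]
        assert row["score"].iloc[0] == pytest.approx(direct, abs=1e-12)

    def test_sua_units_on_one_channel_are_averaged(self, rng):
        X = _channel_features(rng.standard_normal((300, 4)))
        vals = rng.standard_normal((300, 3))
        cols = (
            TargetColumn("sua", 2, 0),
            TargetColumn("sua", 2, 1),
            TargetColumn("sua", 3, 5),
        )
        Y = TargetMatrix(vals, cols)
        amap = lp.grid_for_channels(4)
        table = lp.channel_importance(X, Y, lp.partition_blocks(300, 10), amap, metric="cc")
        # 4 inputs x 2 distinct output channels
        assert len(table) == 8

    def test_unknown_metric_rejected(self, rng):
        X, Y, amap = self._session(n=200)
        with pytest.raises(ValueError, match="metric"):
            lp.channel_importance(X, Y, lp.partition_blocks(200, 10), amap, metric="auc")


class TestDistanceTrend:
    def test_planted_negative_trend_detected(self, rng):
        d = np.linspace(0, 4000, 200)
        noise_sd = 0.02
        k = 10 * noise_sd / 4000  # slope 10x the noise scale over the range
        s = -k * d + noise_sd * rng.standard_normal(200)
        table = pd.DataFrame({"distance_um": d, "score": s})
        slope, p = lp.distance_trend(table)
        assert slope < 0 and p < 0.001

    def test_constant_scores_flat_trend(self):
        table = pd.DataFrame({"distance_um": [0.0, 400.0, 800.0], "score": [0.5] * 3})
        slope, p = lp.distance_trend(table)
        assert abs(slope) < 1e-12 and p == pytest.approx(1.0)

    def test_hand_computed_slope(self):
        table = pd.DataFrame(
            {"distance_um": [0.0, 400.0, 800.0], "score": [1.0, 0.9, 0.8]}
        )
        slope, _ = lp.distance_trend(table)
        assert slope == pytest.approx(-0.00025)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            lp.distance_trend(pd.DataFrame({"distance_um": [1.0], "score": [1.0]}))
        with pytest.raises(ValueError, match="variance"):
            lp.distance_trend(
                pd.DataFrame({"distance_um": [1.0] * 5, "score": np.arange(5.0)})
            )


class TestImportanceHeatmap:
    def _table(self, amap, scores):
        return pd.DataFrame(
            {
                "output_type": "esa",
                "output_channel": 5,
                "input_channel": list(amap.channel_ids),
                "score": scores,
            }
        )

    def test_utah_grid_has_exactly_four_flagged_sites(self, utah_map, rng):
        table = self._table(utah_map, rng.uniform(size=96))
        grid, connected = lp.importance_heatmap(table, utah_map)
        assert (~connected).sum() == 4
        assert np.isnan(grid[~connected]).all()
        assert np.isfinite(grid[connected]).all()

    def test_uniform_scores_give_uniform_grid(self, utah_map):
        grid, connected = lp.importance_heatmap(self._table(utah_map, np.full(96, 0.7)), utah_map)
        np.testing.assert_allclose(grid[connected], 0.7)

    def test_grid_round_trips_to_table(self, utah_map, rng):
        scores = rng.uniform(size=96)
        table = self._table(utah_map, scores)
        grid, _ = lp.importance_heatmap(table, utah_map)
        back = heatmap_to_table(grid, utah_map)
        np.testing.assert_allclose(back["score"].to_numpy(), scores)

    def test_multiple_outputs_rejected(self, utah_map, rng):
        t1 = self._table(utah_map, rng.uniform(size=96))
        t2 = t1.copy()
        t2["output_channel"] = 6
        with pytest.raises(ValueError, match="one output"):
            lp.importance_heatmap(pd.concat([t1, t2]), utah_map)

    def test_missing_channel_rejected(self, utah_map, rng):
        table = self._table(utah_map, rng.uniform(size=96)).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            lp.importance_heatmap(table, utah_map)
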
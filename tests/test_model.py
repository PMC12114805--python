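import numpy as np
import pandas as pd
import pytest

import specphos as sp
from specphos.dataset import SpectraError
from specphos.model import _metrics


def _planted_setup(seed=11):
    s = sp.generate_planted(sp.SynthConfig(mode="planted", seed=seed))
    orders = (0.0, 1.0, 1.6, 2.0)
    frs = sp.fod_sweep(s, sp.FODConfig(orders=orders))
    scans = [
        sp.scan_pairs(fr.matrix, s.lpc, "DSI", fr.wavelengths, source_order=fr.order)
        for fr in frs
    ]
    return s, frs, scans


class TestMakeSplit:
    def test_sixty_forty_counts(self):
        split = sp.make_split(60, 0.6, seed=0)
        assert len(split.calibration_ids) == 36
        assert len(split.validation_ids) == 24
        assert not set(split.calibration_ids) & set(split.validation_ids)

    def test_reproducible_from_seed(self):
        a = sp.make_split(60, 0.6, seed=5)
        b = sp.make_split(60, 0.6, seed=5)
        assert a.calibration_ids == b.calibration_ids

    def test_half_split_of_ten(self):
        split = sp.make_split(10, 0.5, seed=1)
        assert len(split.calibration_ids) == 5 and len(split.validation_ids) == 5

    def test_degenerate_splits_rejected(self):
        with pytest.raises(SpectraError):
            sp.make_split(60, 0.001, seed=0)
        with pytest.raises(SpectraError):
            sp.make_split(4, 0.5, seed=0)


class TestBuildFeatures:
    def test_four_orders_four_columns(self):
        s, frs, scans = _planted_setup()
        feats = sp.build_features(frs, scans, "DSI")
        assert feats.shape == (60, 4)
        assert list(feats.columns) == ["DSI_v0", "DSI_v1", "DSI_v1.6", "DSI_v2"]

    def test_planted_order0_column_tracks_lpc(self):
        s, frs, scans = _planted_setup()
        feats = sp.build_features(frs, scans, "DSI")
        r2 = np.corrcoef(feats["DSI_v0"], s.lpc)[0, 1] ** 2
        assert r2 > 0.85  # signal-to-noise ~5 puts the planted pair near 0.96

    def test_recompute_identical(self):
        s, frs, scans = _planted_setup()
        a = sp.build_features(frs, scans, "DSI")
        b = sp.build_features(frs, scans, "DSI")
        pd.testing.assert_frame_equal(a, b)

    def test_missing_order_rejected_by_name(self):
        s, frs, scans = _planted_setup()
        with pytest.raises(SpectraError, match="1.6"):
            sp.build_features([f for f in frs if f.order != 1.6], scans, "DSI")

    def test_kind_mismatch_rejected(self):
        s, frs, scans = _planted_setup()
        with pytest.raises(SpectraError):
            sp.build_features(frs, scans, "NDSI")


class TestMetrics:
    def test_perfect_prediction(self):
        obs = np.array([0.08, 0.09, 0.10])
        r2, r2r, rmse = _metrics(obs, obs.copy())
        assert r2 == 1.0 and r2r == pytest.approx(1.0) and rmse == 0.0

    def test_hand_computed_rmse(self):
        obs = np.array([0.08, 0.09, 0.10])
        pred = np.array([0.09, 0.09, 0.09])
        _, _, rmse = _metrics(obs, pred)
        assert rmse == pytest.approx(np.sqrt(2 * 0.0001 / 3), abs=1e-12)

    def test_evaluate_predictions_wrapper(self):
        obs = np.array([0.08, 0.09, 0.10])
        r2, rmse = sp.evaluate_predictions(obs, obs)
        assert r2 == 1.0 and rmse == 0.0


class TestFitAndEvaluate:
    def test_report_metrics_match_stored_predictions(self):
        s, frs, scans = _planted_setup()
        feats = sp.build_features(frs, scans, "DSI")
        split = sp.make_split(60, 0.6, seed=4, sample_ids=s.sample_ids)
        rep = sp.fit_and_evaluate(feats, s.lpc, split, sample_ids=s.sample_ids,
                                  index_kind="DSI")
        for label, r2, rmse in (
            ("calibration", rep.r2_cal, rep.rmse_cal),
            ("validation", rep.r2_val, rep.rmse_val),
        ):
            sub = rep.predictions[rep.predictions["split"] == label]
            r2_chk, rmse_chk = sp.evaluate_predictions(
                sub["observed_lpc"], sub["predicted_lpc"]
            )
            assert r2 == pytest.approx(r2_chk, abs=1e-10)
            assert rmse == pytest.approx(rmse_chk, abs=1e-10)
        assert sorted(rep.predictions["sample_id"]) == sorted(s.sample_ids)

    def test_validation_rows_never_seen_in_training(self):
        """Dropping validation rows entirely reproduces their predictions."""
        s, frs, scans = _planted_setup()
        feats = sp.build_features(frs, scans, "DSI")
        split = sp.make_split(60, 0.6, seed=4, sample_ids=s.sample_ids)
        rep = sp.fit_and_evaluate(feats, s.lpc, split, sample_ids=s.sample_ids)

        from sklearn.ensemble import RandomForestRegressor

        rows = {sid: i for i, sid in enumerate(s.sample_ids)}
        cal = [rows[i] for i in split.calibration_ids]
        val = [rows[i] for i in split.validation_ids]
        rf = RandomForestRegressor(n_estimators=500, max_features=1.0,
                                   random_state=rep.rf_config.seed)
        rf.fit(feats.to_numpy()[cal], s.lpc[cal])
        expect = rf.predict(feats.to_numpy()[val])
        got = rep.predictions.set_index("sample_id").loc[
            split.validation_ids, "predicted_lpc"
        ].to_numpy()
        np.testing.assert_array_equal(got, expect)

    def test_missing_values_rejected(self):
        s, frs, scans = _planted_setup()
        feats = sp.build_features(frs, scans, "DSI")
        feats.iloc[0, 0] = np.nan
        split = sp.make_split(60, 0.6, seed=4, sample_ids=s.sample_ids)
        with pytest.raises(SpectraError):
            sp.fit_and_evaluate(feats, s.lpc, split, sample_ids=s.sample_ids)


class TestCompareModels:
    def _report(self, kind, r2_val, rmse_val):
        return sp.ModelReport(index_kind=kind, feature_defs=[], r2_cal=0.9,
                              r2_val=r2_val, rmse_cal=0.005, rmse_val=rmse_val,
                              r2_residual_cal=0.9, r2_residual_val=r2_val,
                              predictions=pd.DataFrame())

    def test_sorted_by_validation_r2(self):
        table = sp.compare_models([
            self._report("NDSI", 0.81, 0.009),
            self._report("DSI", 0.85, 0.007),
            self._report("RSI", 0.68, 0.010),
        ])
        assert list(table["index_kind"]) == ["DSI", "NDSI", "RSI"]

    def test_tie_broken_by_smaller_rmse(self):
        table = sp.compare_models([
            self._report("NDSI", 0.80, 0.009),
            self._report("DSI", 0.80, 0.007),
        ])
        assert list(table["index_kind"]) == ["DSI", "NDSI"]

    def test_single_report_rejected(self):
        with pytest.raises(SpectraError):
            sp.compare_models([self._report("DSI", 0.8, 0.008)])
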
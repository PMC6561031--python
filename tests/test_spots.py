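"""Focus thresholding, calibration sweep, and image-based detection."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icetrack.config import OpticsConfig
from icetrack.render import render_frame
from icetrack.spots import (CalibrationError, ThresholdConfig,
                            apply_thresholds, calibrate_thresholds,
                            calibration_fixture, detect_foci, segmentation_qc)


def _counts(foci):
    if len(foci) == 0:
        return pd.Series(dtype=int)
    return foci.groupby(["cell_id", "frame"]).size()


class TestApplyThresholds:
    def test_permissive_thresholds_are_identity(self, make_foci):
        foci = make_foci([dict(score=s, intensity=i, axial=0.1 * s)
                          for s in range(1, 8) for i in (1, 4, 7)][:8])
        out = apply_thresholds(foci, ThresholdConfig(1, 1))
        assert len(out) == len(foci)

    def test_cap_at_eight_foci(self, make_foci):
        foci = make_foci([dict(axial=0.1 * k) for k in range(10)])
        out = apply_thresholds(foci, ThresholdConfig(6, 6, max_foci=8))
        assert len(out) == 8

    def test_low_score_removed(self, make_foci):
        foci = make_foci([dict(score=5, intensity=7)])
        assert len(apply_thresholds(foci, ThresholdConfig(6, 6))) == 0

    def test_truncation_keeps_best_by_score_then_intensity(self, make_foci):
        rows = ([dict(score=7, intensity=6, axial=0.9)]
                + [dict(score=6, intensity=7, axial=0.5)]
                + [dict(score=6, intensity=6, axial=0.1 * k) for k in range(8)])
        out = apply_thresholds(make_foci(rows), ThresholdConfig(6, 6))
        assert len(out) == 8
        assert out.iloc[0]["score"] == 7
        assert out.iloc[1]["intensity"] == 7

    @given(st.lists(st.tuples(st.integers(1, 7), st.integers(1, 7)),
                    min_size=0, max_size=14),
           st.integers(1, 7), st.integers(1, 7))
    def test_monotone_in_thresholds(self, scored, s, i):
        foci = pd.DataFrame([{"cell_id": 0, "frame": 0, "channel": "CFP",
                              "axial_um": 0.1 + 0.05 * k,
                              "transverse_um": 0.0,
                              "score": sc, "intensity": ic}
                             for k, (sc, ic) in enumerate(scored)])
        base = len(apply_thresholds(foci, ThresholdConfig(s, i)))
        if s < 7:
            assert len(apply_thresholds(foci, ThresholdConfig(s + 1, i))) <= base
        if i < 7:
            assert len(apply_thresholds(foci, ThresholdConfig(s, i + 1))) <= base
        assert base <= 8


class TestCalibration:
    def test_packaged_fixture_selects_six_six(self):
        cfg, diagnostics = calibrate_thresholds(calibration_fixture())
        assert (cfg.score_threshold, cfg.intensity_threshold) == (6, 6)
        below = diagnostics[(diagnostics["score"] < 6)]
        assert (below["no_array_foci"] > 0).all()

    def test_blank_controls_select_lowest_setting(self, make_foci):
        blank = make_foci([])
        cfg, _ = calibrate_thresholds({"no_array": blank,
                                       "excision_locked": blank,
                                       "experimental": blank})
        assert (cfg.score_threshold, cfg.intensity_threshold) == (1, 1)

    def test_only_strictest_setting_can_win(self, make_foci):
        # no-array artifacts at (7,6) and (6,7): only (7,7) removes both
        controls = {
            "no_array": make_foci([dict(score=7, intensity=6),
                                   dict(score=6, intensity=7)]),
            "excision_locked": make_foci([dict(score=7, intensity=7)]),
            "experimental": make_foci([dict(score=7, intensity=7)]),
        }
        cfg, _ = calibrate_thresholds(controls)
        assert (cfg.score_threshold, cfg.intensity_threshold) == (7, 7)

    def test_unsatisfiable_criterion_reports_diagnostics(self, make_foci):
        controls = {
            "no_array": make_foci([dict(score=7, intensity=7)]),
            "excision_locked": make_foci([]),
            "experimental": make_foci([]),
        }
        with pytest.raises(CalibrationError) as err:
            calibrate_thresholds(controls)
        assert err.value.diagnostics is not None

    def test_missing_control_set_rejected(self, make_foci):
        with pytest.raises(ValueError):
            calibrate_thresholds({"no_array": make_foci([])})


class TestSegmentationQC:
    def test_flags_length_jumps(self):
        t = pd.DataFrame({
            "cell_id": [1, 1, 1, 2, 2, 2],
            "frame": [0, 1, 2, 0, 1, 2],
            "length_um": [2.0, 2.1, 2.2, 2.0, 3.0, 2.0],  # cell 2 jumps 50%
        })
        flagged = segmentation_qc(t)
        assert not flagged[1]
        assert flagged[2]


class TestDetectFoci:
    def test_blank_cell_yields_nothing(self, single_cell_frame):
        empty = pd.DataFrame(columns=["cell_id", "frame", "channel",
                                      "axial_um", "transverse_um"])
        miss = 0
        for seed in range(5):
            img, labels, _ = render_frame(single_cell_frame, empty,
                                          OpticsConfig(), seed=seed)
            miss += len(detect_foci(img.astype(float), labels == 1))
        assert miss == 0

    def test_single_spot_localized_within_one_pixel(self, single_cell_frame):
        foci = pd.DataFrame([{"cell_id": 0, "frame": 0, "channel": "CFP",
                              "axial_um": 0.9, "transverse_um": 0.05}])
        img, labels, truth = render_frame(single_cell_frame, foci,
                                          OpticsConfig(), seed=10)
        det = detect_foci(img.astype(float), labels == 1)
        assert len(det) == 1
        err = np.hypot(det["row"][0] - truth["row"][0],
                       det["col"][0] - truth["col"][0])
        assert err <= 1.0

    def test_recovery_of_separated_spots(self, single_cell_frame):
        """>=90% of true foci >=4 PSF sigma apart localize within 1 px."""
        hits = total = 0
        for seed in range(12):
            foci = pd.DataFrame([
                {"cell_id": 0, "frame": 0, "channel": "CFP",
                 "axial_um": 0.5, "transverse_um": 0.0},
                {"cell_id": 0, "frame": 0, "channel": "CFP",
                 "axial_um": 1.8, "transverse_um": 0.1},
            ])
            img, labels, truth = render_frame(single_cell_frame, foci,
                                              OpticsConfig(), seed=200 + seed)
            det = detect_foci(img.astype(float), labels == 1)
            for _, t in truth.iterrows():
                total += 1
                if len(det) and np.hypot(det["row"] - t["row"],
                                         det["col"] - t["col"]).min() <= 1.0:
                    hits += 1
        assert hits / total >= 0.9

    def test_at_most_nine_candidates_brightest_kept(self):
        # one long synthetic cell with 12 well-separated spots of
        # decreasing brightness: exactly 9 survive, the 9 brightest
        cell = pd.DataFrame([{
            "cell_id": 0, "frame": 0, "mother_id": -1, "length_um": 13.0,
            "width_um": 0.7, "x_um": 8.0, "y_um": 8.0, "angle_rad": 0.0,
            "echerry": 100.0, "is_recipient": False}])
        foci = pd.DataFrame([
            {"cell_id": 0, "frame": 0, "channel": "CFP",
             "axial_um": 0.6 + 1.0 * k, "transverse_um": 0.0,
             "photons": 9000.0 * 0.8 ** k}
            for k in range(12)])
        img, labels, truth = render_frame(cell, foci, OpticsConfig(), seed=3)
        det = detect_foci(img.astype(float), labels == 1)
        assert len(det) == 9
        # the dimmest three spots (largest axial positions) are the ones lost
        kept_cols = np.sort(det["col"].to_numpy())
        bright9 = np.sort(truth["col"].to_numpy()[:9])
        assert np.all(np.abs(kept_cols - bright9) <= 1.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            detect_foci(np.zeros((10, 10)), np.zeros((10, 10), dtype=bool))

    def test_saturated_spot_flagged(self, single_cell_frame):
        foci = pd.DataFrame([{"cell_id": 0, "frame": 0, "channel": "CFP",
                              "axial_um": 1.2, "transverse_um": 0.0}])
        optics = OpticsConfig(spot_photons=5e6)
        img, labels, _ = render_frame(single_cell_frame, foci, optics, seed=4)
        det = detect_foci(img.astype(float), labels == 1,
                          saturation=optics.saturation)
        assert len(det) >= 1 and det["saturated"].any()
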
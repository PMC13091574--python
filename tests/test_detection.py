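import dataclasses

import numpy as np
import pandas as pd
import pytest

from sotrains.detection import DetectionParams, detect_sos, so_summary
from sotrains.io import Hypnogram, Recording, analysis_mask
from sotrains.simulate import match_events, simulate_subject, young_like

from conftest import make_canonical_wave_night


class TestCanonicalWave:
    def test_single_clean_wave_detected_with_expected_features(self):
        rec, h, t_true = make_canonical_wave_night(n_waves=1)
        ev = detect_sos(rec, analysis_mask(h))
        assert len(ev) == 1
        e = ev.iloc[0]
        # construction: 0.5 s + 0.5 s wave, −80 µV trough, +40 µV crest
        assert abs(e.t_negpeak - t_true[0]) < 0.05
        assert 0.8 < e.A < 1.3
        assert e.C < -60 and e.D > 25
        assert e.ptp > 100
        assert e.freq == pytest.approx(1.0 / e.A)
        assert e.t_start < e.t_negpeak < e.t_mid < e.t_pospeak < e.t_end

    def test_subthreshold_wave_rejected(self):
        # trough −30 µV is above the −40 µV criterion: no event
        rec, h, _ = make_canonical_wave_night(n_waves=3)
        rec = Recording(rec.samples * (30.0 / 80.0), rec.rate)
        ev = detect_sos(rec, analysis_mask(h))
        assert len(ev) == 0

    def test_sparse_night_recall_one_no_false_positives(self, canonical_night):
        rec, h, t_true = canonical_night
        ev = detect_sos(rec, analysis_mask(h))
        m = match_events(ev["t_negpeak"].to_numpy(), t_true)
        assert m["t_det"].notna().all()
        assert len(ev) == len(t_true)
        assert (m["err"].abs() < 0.05).all()

    def test_events_outside_mask_rejected(self):
        rec, h, t_true = make_canonical_wave_night(n_waves=5)
        # waves at 30, 42, 54 s all touch epoch 1 ([30, 60)); flagging it as
        # artifact must drop exactly those three
        art = np.zeros(h.n_epochs, dtype=bool)
        art[1] = True
        h2 = Hypnogram(h.stages, artifact=art)
        ev = detect_sos(rec, analysis_mask(h2))
        assert len(ev) == 2
        assert ev["t_negpeak"].min() > 60.0

    def test_empty_mask_returns_empty(self, canonical_night):
        rec, _, _ = canonical_night
        h_wake = Hypnogram(np.array(["W"] * 10))
        ev = detect_sos(rec, analysis_mask(h_wake))
        assert len(ev) == 0


class TestThresholdContracts:
    def test_ptp_threshold_monotone(self, young_night, young_night_mask):
        rec, _, _ = young_night
        counts = []
        for thr in (40.0, 60.0, 75.0, 90.0, 100.0):
            ev = detect_sos(rec, young_night_mask,
                            DetectionParams(ptp_min=thr))
            counts.append(len(ev))
        assert counts == sorted(counts, reverse=True)

    def test_75_set_is_subset_of_60_set(self, young_night, young_night_mask):
        rec, _, _ = young_night
        t75 = detect_sos(rec, young_night_mask,
                         DetectionParams(ptp_min=75.0))["t_negpeak"]
        t60 = detect_sos(rec, young_night_mask,
                         DetectionParams(ptp_min=60.0))["t_negpeak"]
        assert set(np.round(t75, 6)).issubset(set(np.round(t60, 6)))

    def test_events_sorted_and_nonoverlapping(self, young_night, young_night_mask):
        rec, _, _ = young_night
        ev = detect_sos(rec, young_night_mask)
        assert ev["t_negpeak"].is_monotonic_increasing
        assert (ev["t_start"].to_numpy()[1:] >= ev["t_end"].to_numpy()[:-1]).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(ptp_min=-5)
        with pytest.raises(ValueError):
            DetectionParams(neg_peak_max=10.0)


class TestGroundTruthRecovery:
    def test_noise_free_recall_and_timing(self, young_night, young_night_mask):
        rec, _, gt = young_night
        ev = detect_sos(rec, young_night_mask)
        m = match_events(ev["t_negpeak"].to_numpy(), gt.times)
        assert m["t_det"].notna().mean() >= 0.9
        assert m["err"].abs().median() < 0.05

    def test_feature_invariants_hold(self, young_night, young_night_mask):
        rec, _, _ = young_night
        ev = detect_sos(rec, young_night_mask)
        assert (ev["C"] <= -40.0).all()
        assert (ev["ptp"] >= 75.0).all()
        assert np.allclose(ev["A"], ev["t_end"] - ev["t_start"])
        assert np.allclose(ev["ptp"], ev["D"] - ev["C"])
        assert np.allclose(ev["freq"], 1.0 / ev["A"])
        assert ((ev["t_mid"] - ev["t_start"]).between(0.3, 1.5)).all()
        assert ((ev["t_end"] - ev["t_mid"]).between(0.1, 1.0)).all()


class TestSummary:
    def _h(self, n_s2, n_sws):
        return Hypnogram(np.array(["S2"] * n_s2 + ["SWS"] * n_sws))

    def _events(self, stages):
        n = len(stages)
        return pd.DataFrame({
            "t_negpeak": np.arange(n) * 5.0, "stage": stages,
            **{f: np.ones(n) for f in ["A", "B", "C", "D", "ptp", "slope", "freq"]},
        })

    def test_density_ratio(self):
        ev = self._events(["S2"] * 120)
        s = so_summary(ev, self._h(120, 0))  # 60 artifact-free S2 minutes
        assert s["density_S2"] == pytest.approx(2.0)

    def test_stage_proportions(self):
        ev = self._events(["S2"] * 30 + ["SWS"] * 90)
        s = so_summary(ev, self._h(100, 100))
        assert s["prop_S2"] == pytest.approx(0.25)
        assert s["prop_SWS"] == pytest.approx(0.75)

    def test_no_events_flagged(self):
        s = so_summary(self._events([])[:0], self._h(10, 10))
        assert s["density_nrem"] == 0.0
        assert np.isnan(s["mean_ptp"])

    def test_events_without_stage_time_is_error(self):
        ev = self._events(["SWS"] * 5)
        with pytest.raises(ValueError):
            so_summary(ev, self._h(10, 0))
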
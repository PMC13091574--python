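import dataclasses

import numpy as np
import pytest

from sotrains.io import analysis_mask, read_edf, read_hypnogram
from sotrains.nulls import FeasibilityError
from sotrains.simulate import (SynthParams, _train_length_pmf, elderly_like,
                               generate_night, match_events, render_signal,
                               simulate_subject, write_night, young_like)


class TestGenerateNight:
    def test_train_fraction_zero_all_isolated(self):
        p = dataclasses.replace(young_like(seed=1, night_len_h=2.0),
                                train_fraction=0.0)
        _, gt = generate_night(p)
        assert (gt.events["label"] == "isolated").all()
        assert (gt.events["train_id"] == -1).all()

    def test_all_train_mean_length_matches_truncated_geometric(self):
        p = dataclasses.replace(young_like(seed=2, night_len_h=8.0),
                                train_fraction=1.0)
        lengths, pmf = _train_length_pmf(p.train_q, p.train_len_max)
        expected = float((lengths * pmf).sum())
        means = []
        for seed in range(5):
            _, gt = generate_night(dataclasses.replace(p, seed=seed))
            assert (gt.events["label"] == "consecutive").all()
            tl = gt.events.groupby("train_id")["t"].size()
            means.append(tl.mean())
        assert abs(np.mean(means) - expected) / expected < 0.10

    def test_realized_density_within_ten_percent(self):
        realized = {stage: [] for stage in ("S2", "SWS")}
        p = young_like(seed=0, night_len_h=8.0)  # ≥ 2 h per stage
        for seed in (0, 1, 2):
            h, gt = generate_night(dataclasses.replace(p, seed=seed))
            mask = analysis_mask(h)
            for stage in realized:
                minutes = mask.stage_seconds(stage) / 60.0
                realized[stage].append(
                    (gt.events["stage"] == stage).sum() / minutes)
        for stage, target in p.density.items():
            assert abs(np.mean(realized[stage]) / target - 1) < 0.10

    def test_labels_consistent_with_delta(self):
        _, gt = generate_night(young_like(seed=3, night_len_h=3.0))
        t = gt.times
        gaps = np.diff(t)
        near = np.concatenate([[False], gaps <= 2.0]) | \
            np.concatenate([gaps <= 2.0, [False]])
        expected = np.where(near, "consecutive", "isolated")
        assert list(gt.events["label"]) == list(expected)

    def test_events_inside_artifact_free_nrem(self):
        h, gt = generate_night(young_like(seed=4, night_len_h=3.0))
        mask = analysis_mask(h)
        idx = mask.merged().contains(gt.times, gt.times)
        assert (idx >= 0).all()

    def test_epoch_index_from_time(self):
        _, gt = generate_night(young_like(seed=5, night_len_h=2.0))
        assert (gt.events["epoch"] == (gt.events["t"] // 30).astype(int)).all()

    def test_infeasible_density_rejected(self):
        p = dataclasses.replace(young_like(seed=6, night_len_h=2.0),
                                density={"S2": 40.0})
        with pytest.raises(FeasibilityError):
            generate_night(p)

    def test_seeded_reproducibility(self):
        p = young_like(seed=11, night_len_h=2.0)
        _, a = generate_night(p)
        _, b = generate_night(p)
        assert a.events.equals(b.events)


class TestRenderSignal:
    def test_trough_at_event_time(self):
        p = dataclasses.replace(young_like(seed=7, night_len_h=2.0),
                                noise_rms=0.0)
        h, gt = generate_night(p)
        rec = render_signal(h, gt)
        for t in gt.times[:50]:
            i = int(round(t * rec.rate))
            w = rec.samples[i - 10 : i + 11]
            # trough anchored at the event time; superposition with a
            # neighbour's rebound may shift the flat minimum by ≤ 30 ms
            assert abs(int(np.argmin(w)) - 10) <= 3
            assert w.min() < -40.0

    def test_noise_rms_close_to_requested(self):
        p = dataclasses.replace(young_like(seed=8, night_len_h=2.0),
                                density={"S2": 0.0, "SWS": 0.0}, noise_rms=10.0)
        h, gt = generate_night(p)
        rec = render_signal(h, gt)
        assert rec.samples.std() == pytest.approx(10.0, rel=0.01)

    def test_edf_round_trip(self, tmp_path):
        p = dataclasses.replace(young_like(seed=9, night_len_h=1.0))
        rec, h, gt = simulate_subject(p)
        paths = write_night(tmp_path, rec, h, gt)
        back = read_edf(paths["edf"], rec.channel)
        assert back.rate == rec.rate
        n = rec.samples.size
        assert np.abs(back.samples[:n] - rec.samples).max() < 0.02
        h2 = read_hypnogram(paths["hypnogram"])
        assert list(h2.stages) == list(h.stages)


class TestPresets:
    def test_presets_contrast(self):
        y = young_like(seed=0)
        e = elderly_like(seed=0)
        assert sum(y.density.values()) > sum(e.density.values())
        assert y.train_fraction > e.train_fraction

    def test_full_pipeline_recall_on_noisy_night(self):
        from sotrains.detection import DetectionParams, detect_sos

        p = young_like(seed=12, night_len_h=3.0)  # default 10 µV 1/f noise
        rec, h, gt = simulate_subject(p)
        ev = detect_sos(rec, analysis_mask(h), DetectionParams())
        m = match_events(ev["t_negpeak"].to_numpy(), gt.times)
        assert m["t_det"].notna().mean() >= 0.9
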
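import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sotrains.classification import (Classification, classify_events,
                                     compute_isoi, delta_sweep, isoi_histogram,
                                     mean_isoi_histogram,
                                     mean_train_length_density,
                                     train_length_density)


def brute_force_labels(times: np.ndarray, delta: float) -> np.ndarray:
    """O(n²) oracle: an event is consecutive iff any other event lies within δ."""
    n = times.size
    out = np.empty(n, dtype="<U11")
    for i in range(n):
        near = np.abs(np.delete(times, i) - times[i]) <= delta
        out[i] = "consecutive" if near.any() else "isolated"
    return out


def event_times(seed, n_max=300):
    """Clustered random event sets mimicking trains plus isolated events."""
    rng = np.random.default_rng(seed)
    t, cur = [], 0.0
    while len(t) < rng.integers(2, n_max):
        cur += rng.choice([rng.uniform(0.5, 2.0), rng.uniform(2.1, 60.0)],
                          p=[0.6, 0.4])
        t.append(cur)
    return np.array(t)


class TestISOI:
    def test_differences(self):
        assert compute_isoi(np.array([10.0, 11.5, 13.0, 20.0])).tolist() == \
            [1.5, 1.5, 7.0]

    def test_single_event_empty(self):
        assert compute_isoi(np.array([5.0])).size == 0

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            compute_isoi(np.array([3.0, 1.0, 2.0]))

    def test_accepts_event_table(self):
        df = pd.DataFrame({"t_negpeak": [1.0, 2.0, 4.0]})
        assert compute_isoi(df).tolist() == [1.0, 2.0]


class TestClassify:
    def test_forced_example(self):
        c = classify_events(np.array([10.0, 11.5, 13.0, 20.0]), delta=2.0)
        assert list(c.labels) == ["consecutive"] * 3 + ["isolated"]
        assert c.train_lengths.tolist() == [3]
        assert c.p_isolated == pytest.approx(0.25)

    def test_delta_below_smallest_gap_all_isolated(self):
        t = np.array([0.0, 3.0, 6.0, 9.0])
        c = classify_events(t, delta=1.0)
        assert (c.labels == "isolated").all()
        assert c.train_lengths.size == 0

    def test_tie_at_delta_counts_consecutive(self):
        c = classify_events(np.array([0.0, 2.0]), delta=2.0)
        assert (c.labels == "consecutive").all()

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            classify_events(np.array([0.0, 1.0]), delta=0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        t = event_times(seed)
        c = classify_events(t, delta=2.0)
        assert list(c.labels) == list(brute_force_labels(t, 2.0))

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_conservation_identities(self, seed):
        t = event_times(seed, n_max=120)
        c = classify_events(t, delta=2.0)
        assert c.n_isolated + c.n_consecutive == c.n_events
        assert c.train_lengths.sum() == c.n_consecutive
        assert (c.train_lengths >= 2).all()
        # train members are contiguous with within-train gaps ≤ δ
        for tid in range(c.train_lengths.size):
            idx = np.nonzero(c.train_id == tid)[0]
            assert (np.diff(idx) == 1).all()
            assert (np.diff(t[idx]) <= 2.0).all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_delta(self, seed):
        t = event_times(seed, n_max=80)
        c1 = classify_events(t, delta=1.0)
        c2 = classify_events(t, delta=3.0)
        consec1 = c1.labels == "consecutive"
        consec2 = c2.labels == "consecutive"
        assert (consec2 | ~consec1).all()


class TestTrainLengthDensity:
    def _cls(self, lengths):
        labels = np.array(["consecutive"] * sum(lengths), dtype="<U11")
        tid = np.repeat(np.arange(len(lengths)), lengths)
        return Classification(labels, tid, np.array(lengths), 2.0)

    def test_density_values(self):
        d = train_length_density(self._cls([2, 2, 3]))
        assert d[2] == pytest.approx(2 / 3)
        assert d[3] == pytest.approx(1 / 3)

    def test_single_train(self):
        d = train_length_density(self._cls([5]))
        assert d[5] == 1.0

    def test_zero_trains_empty(self):
        c = classify_events(np.array([0.0, 10.0]), delta=2.0)
        assert train_length_density(c).empty

    def test_group_mean_zero_pads(self):
        a = pd.Series({2: 1.0})
        b = pd.Series({2: 0.5, 3: 0.5})
        m = mean_train_length_density([a, b])
        assert m[2] == pytest.approx(0.75)
        assert m[3] == pytest.approx(0.25)


class TestISOIHistogram:
    def test_peak_bin(self):
        h = isoi_histogram([1.2, 1.3, 3.0], bin_width=0.5)
        edge, dens = h.peak_bin()
        assert edge == 1.0
        assert dens == pytest.approx((2 / 3) / 0.5)

    def test_density_integrates_to_one(self):
        h = isoi_histogram(np.random.default_rng(0).uniform(0, 40, 500))
        assert np.sum(h.density * 0.5) == pytest.approx(1.0)

    def test_empty(self):
        h = isoi_histogram([])
        assert h.n == 0 and h.density.sum() == 0

    def test_lognormal_mode_within_one_bin(self):
        # analytic mode of lognormal(μ, σ) is exp(μ − σ²)
        mu, sigma = 0.3, 1.45
        x = np.random.default_rng(1).lognormal(mu, sigma, 100_000)
        h = isoi_histogram(x, bin_width=0.5, max_isoi=30.0)
        edge, _ = h.peak_bin()
        mode = np.exp(mu - sigma ** 2)
        assert abs(edge + 0.25 - mode) <= 0.5

    def test_mean_histogram(self):
        h1 = isoi_histogram([1.0, 1.1], max_isoi=5.0)
        h2 = isoi_histogram([3.0, 3.2], max_isoi=5.0)
        m = mean_isoi_histogram([h1, h2])
        assert np.allclose(m.density, (h1.density + h2.density) / 2)


class TestDeltaSweep:
    def test_forced_grid(self):
        sw = delta_sweep(np.array([0.0, 3.0, 6.0, 9.0]), grid=[1.0, 2.0, 4.0])
        assert sw["p_consecutive"].tolist() == [0.0, 0.0, 1.0]

    def test_delta_beyond_span_all_consecutive(self):
        sw = delta_sweep(np.array([0.0, 5.0]), grid=[100.0])
        assert sw["p_consecutive"].iloc[0] == 1.0

    def test_sums_to_one_and_monotone(self):
        t = event_times(42)
        sw = delta_sweep(t)
        assert np.allclose(sw["p_isolated"] + sw["p_consecutive"], 1.0)
        assert (np.diff(sw["p_consecutive"]) >= -1e-12).all()

    def test_equals_pointwise_reruns(self):
        t = event_times(13, n_max=200)
        grid = np.arange(0.5, 10.1, 0.5)
        sw = delta_sweep(t, grid)
        for _, row in sw.iloc[::4].iterrows():
            c = classify_events(t, delta=row["delta"])
            assert c.p_consecutive == pytest.approx(row["p_consecutive"])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            delta_sweep(np.array([0.0, 1.0]), grid=[])
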
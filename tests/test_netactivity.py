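"""Population-structure contracts: rates, bursts, synchrony, classes."""

import numpy as np
import pytest

from neuroculture.containers import RateSeries, SpikeTrain
from neuroculture.mea import compute_rate
from neuroculture.netactivity import (
    ACTIVITY_CLASSES,
    classification_summary,
    classify_activity,
    detect_network_bursts,
    inter_burst_intervals,
    population_rate,
    synchrony,
)
from conftest import truth_to_trains


def _jaccard(a, b):
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


class TestPopulationRate:
    def test_singleton_mean_is_identity(self):
        train = SpikeTrain(np.array([0.05, 0.15, 0.25]), duration=1.0, channel_id="a")
        pop = population_rate([train])
        np.testing.assert_array_equal(pop.series.values, compute_rate(train).values)

    def test_arithmetic_mean_of_constant_channels(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 10, 0.5)  # 2 Hz deterministic
        t2 = np.arange(0, 10, 0.25)  # 4 Hz
        pop = population_rate(
            [SpikeTrain(t, 10.0, channel_id="a"), SpikeTrain(t2, 10.0, channel_id="b")],
            bin_width=0.5,
        )
        np.testing.assert_allclose(pop.series.values.mean(), 3.0, atol=0.01)

    def test_burster_rate_inside_vs_outside_windows(self, burster_truth):
        trains = truth_to_trains(burster_truth)
        pop = population_rate(trains)
        mids = pop.series.bin_midpoints()
        inside = np.zeros(mids.size, dtype=bool)
        for s, e in burster_truth.burst_windows:
            inside |= (mids >= s) & (mids <= e)
        mean_in = pop.series.values[inside].mean()
        mean_out = pop.series.values[~inside].mean()
        assert mean_in >= 10 * max(mean_out, 1e-12)

    def test_no_active_channels_rejected(self):
        silent = SpikeTrain(np.empty(0), duration=10.0)
        with pytest.raises(ValueError):
            population_rate([silent])


class TestDetectNetworkBursts:
    def test_silent_input_no_bursts(self):
        from neuroculture.netactivity import PopulationRate

        pop = PopulationRate(
            series=RateSeries(np.zeros(1000), 0.1),
            active_channels=["a"],
            activity_threshold=0.1,
        )
        assert detect_network_bursts(pop) == []

    def test_burster_jaccard_against_ground_truth(self, burster_truth):
        trains = truth_to_trains(burster_truth)
        pop = population_rate(trains)
        bursts = detect_network_bursts(pop, trains=trains)
        assert len(bursts) == len(burster_truth.burst_windows)
        for w in burster_truth.burst_windows:
            best = max(_jaccard(w, (b.start, b.end)) for b in bursts)
            assert best >= 0.9

    def test_tonic_culture_zero_bursts(self, tonic_truth):
        trains = truth_to_trains(tonic_truth)
        pop = population_rate(trains)
        assert detect_network_bursts(pop, trains=trains) == []

    def test_bursts_disjoint_after_merge(self, burster_truth):
        trains = truth_to_trains(burster_truth)
        bursts = detect_network_bursts(population_rate(trains), trains=trains)
        for b1, b2 in zip(bursts, bursts[1:]):
            assert b2.start > b1.end

    def test_participation_high_for_default_burster(self, burster_truth):
        trains = truth_to_trains(burster_truth)
        bursts = detect_network_bursts(population_rate(trains), trains=trains)
        assert np.mean([b.participation for b in bursts]) > 0.7

    def test_interval_conventions(self, burster_truth):
        trains = truth_to_trains(burster_truth)
        bursts = detect_network_bursts(population_rate(trains), trains=trains)
        e2s = inter_burst_intervals(bursts, "end_to_start")
        s2s = inter_burst_intervals(bursts, "start_to_start")
        assert np.all(s2s > e2s)  # start-to-start includes the burst itself


class TestSynchrony:
    def test_identical_series_correlation_one(self):
        rng = np.random.default_rng(1)
        v = rng.poisson(3, 300).astype(float)
        pair = [RateSeries(v, 0.1, channel_id="a"), RateSeries(v.copy(), 0.1, channel_id="b")]
        m = synchrony(pair)
        assert m.matrix[0, 1] == pytest.approx(1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(2)
        a = RateSeries(rng.poisson(3, 1200).astype(float), 0.1, channel_id="a")
        b = RateSeries(rng.poisson(3, 1200).astype(float), 0.1, channel_id="b")
        assert abs(synchrony([a, b]).matrix[0, 1]) < 0.1

    def test_delayed_series_peak_lag(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(3, 1200).astype(float)
        shift = 5  # 0.5 s at 0.1 s bins
        delayed = np.roll(base, shift)
        m = synchrony(
            [RateSeries(base, 0.1, channel_id="a"),
             RateSeries(delayed, 0.1, channel_id="b")],
            max_lag=1.0,
        )
        assert m.lags[0, 1] == pytest.approx(0.5)
        assert m.matrix[0, 1] > 0.9

    def test_bounds_symmetry_and_diagonal(self, burster_truth):
        trains = truth_to_trains(burster_truth)
        series = [compute_rate(tr) for tr in trains[:6]]
        m = synchrony(series).matrix
        finite = m[np.isfinite(m)]
        assert np.all(finite >= -1 - 1e-12) and np.all(finite <= 1 + 1e-12)
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_constant_series_flagged_nan(self):
        a = RateSeries(np.ones(100), 0.1, channel_id="a")
        rng = np.random.default_rng(4)
        b = RateSeries(rng.poisson(3, 100).astype(float), 0.1, channel_id="b")
        m = synchrony([a, b])
        assert np.isnan(m.matrix[0, 1])

    def test_phenotype_contrast(self, burster_truth, tonic_truth):
        def mean_corr(truth):
            series = [compute_rate(tr) for tr in truth_to_trains(truth)]
            return synchrony(series).mean_pairwise

        assert mean_corr(burster_truth) - mean_corr(tonic_truth) >= 0.5


class TestClassifyActivity:
    def test_silent_cell_is_none(self, burster_truth):
        trains = truth_to_trains(burster_truth)
        bursts = detect_network_bursts(population_rate(trains), trains=trains)
        classes = classify_activity({"cell": np.empty(0)}, bursts)
        assert classes["cell"] == "none"

    def test_burst_confined_cell_is_bursting(self, burster_truth):
        trains = truth_to_trains(burster_truth)
        bursts = detect_network_bursts(population_rate(trains), trains=trains)
        times = np.array([0.5 * (b.start + b.end) for b in bursts])
        classes = classify_activity({"cell": times}, bursts)
        assert classes["cell"] == "bursting"

    def test_coculture_recovery_against_phenotypes(self, coculture_truth):
        trains = [tr for tr in truth_to_trains(coculture_truth) if tr.n_spikes > 0]
        bursts = detect_network_bursts(population_rate(trains), trains=trains)
        events = {f"u{i}": t for i, t in enumerate(coculture_truth.unit_times)}
        classes = classify_activity(events, bursts)
        expected = {"burster": "bursting", "tonic": "spiking_and_bursting",
                    "silent": "none"}
        hits = [
            classes[f"u{i}"] == expected[p]
            for i, p in enumerate(coculture_truth.phenotypes)
        ]
        assert np.mean(hits) >= 0.95

    def test_class_counts_sum_to_cells(self, coculture_truth):
        trains = [tr for tr in truth_to_trains(coculture_truth) if tr.n_spikes > 0]
        bursts = detect_network_bursts(population_rate(trains), trains=trains)
        events = {f"u{i}": t for i, t in enumerate(coculture_truth.unit_times)}
        classes = classify_activity(events, bursts)
        table = classification_summary(classes_by_group={"coculture": classes})
        row = table.iloc[0]
        assert sum(row[c] for c in ACTIVITY_CLASSES) == row["total"] == len(events)


class TestClassificationSummary:
    # printed activity-overview counts per culture condition
    COUNTS = {
        "Chx10 (co-culture)": dict(spiking=16, bursting=64,
                                   spiking_and_bursting=17, none=28),
        "Chx10 (alone)": dict(spiking=0, bursting=312,
                              spiking_and_bursting=7, none=164),
        "HB9 (co-culture)": dict(spiking=13, bursting=13,
                                 spiking_and_bursting=29, none=12),
        "HB9 (alone)": dict(spiking=81, bursting=0,
                            spiking_and_bursting=2, none=93),
    }

    def test_totals(self):
        table = classification_summary(counts=self.COUNTS).set_index("group")
        assert table.loc["Chx10 (co-culture)", "total"] == 125
        assert table.loc["Chx10 (alone)", "total"] == 483
        assert table.loc["HB9 (co-culture)", "total"] == 67
        assert table.loc["HB9 (alone)", "total"] == 176

    @pytest.mark.parametrize(
        "group,cls,pct",
        [
            ("Chx10 (co-culture)", "spiking", 13),
            ("Chx10 (co-culture)", "bursting", 51),
            ("Chx10 (co-culture)", "spiking_and_bursting", 14),
            ("Chx10 (co-culture)", "none", 22),
            ("Chx10 (alone)", "bursting", 65),
            ("Chx10 (alone)", "spiking_and_bursting", 1),
            ("Chx10 (alone)", "none", 34),
            ("HB9 (co-culture)", "spiking_and_bursting", 43),
            ("HB9 (co-culture)", "none", 18),
            ("HB9 (alone)", "spiking", 46),
            ("HB9 (alone)", "spiking_and_bursting", 1),
            ("HB9 (alone)", "none", 53),
        ],
    )
    def test_percentages_match_printed_table(self, group, cls, pct):
        table = classification_summary(counts=self.COUNTS).set_index("group")
        assert table.loc[group, f"{cls}_pct"] == pct
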
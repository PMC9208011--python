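"""Preprocessing, template-matching detection, pruning, and rate summaries."""

import numpy as np
import pytest

from nanet.synthetic import generate_population, simulate_traces
from nanet.traces import (
    EventTrain,
    detect_events,
    detect_events_traceset,
    event_rate_summary,
    preprocess_trace,
    prune_inactive,
)
from nanet.types import ASTRO, NEURON, ConditionSpec
from nanet.waveforms import TemplateLibrary, calcium_template


class TestPreprocess:
    def test_constant_trace_maps_to_zeros(self):
        out = preprocess_trace(np.full(100, 7.3), 20.0)
        assert np.array_equal(out, np.zeros(100))

    def test_output_standardized(self):
        rng = np.random.default_rng(0)
        out = preprocess_trace(rng.normal(5, 2, 500), 20.0)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1) < 1e-9

    def test_stopband_attenuation(self):
        """5 Hz sine through the 2 Hz low-pass loses >= 10x power at 5 Hz."""
        fs = 20.0
        t = np.arange(0, 30, 1 / fs)
        x = np.sin(2 * np.pi * 5 * t)
        raw = (x - x.mean()) / x.std()
        filt = preprocess_trace(x, fs, cutoff=2.0)
        f = np.fft.rfftfreq(len(t), 1 / fs)
        band = np.abs(f - 5.0) < 0.2
        p_raw = (np.abs(np.fft.rfft(raw)) ** 2)[band].sum()
        p_filt = (np.abs(np.fft.rfft(filt)) ** 2)[band].sum()
        assert p_raw / max(p_filt, 1e-300) >= 10

    def test_detrending_removes_ramp(self):
        x = np.linspace(0, 10, 400)
        out = preprocess_trace(x + 0.001 * np.random.default_rng(1).normal(size=400),
                               20.0)
        # a pure ramp is mostly removed: remaining correlation with time is low
        assert abs(np.corrcoef(out, np.arange(400))[0, 1]) < 0.2

    @pytest.mark.parametrize("bad", [np.r_[np.ones(50), np.nan],
                                     np.r_[np.ones(50), np.inf]])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError, match="non-finite"):
            preprocess_trace(bad, 20.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            preprocess_trace(np.ones(5), 20.0)


def _insert(template, onsets, n, noise=0.0, seed=0):
    x = np.zeros(n)
    for t in onsets:
        seg = template[: n - t]
        x[t : t + len(seg)] += seg
    if noise:
        x += np.random.default_rng(seed).normal(0, noise, n)
    return x


class TestDetectEvents:
    def test_clean_insertions_recovered_exactly(self, library):
        w = library.templates[NEURON][0]
        onsets = [50, 300, 700]
        x = _insert(w, onsets, 1000)
        train = detect_events(x, library, 20.0, cell_type=NEURON)
        assert len(train) == 3
        det = (train.times * 20.0).round().astype(int)
        assert all(abs(d - o) <= 1 for d, o in zip(det, onsets))

    def test_noisy_insertions_recovered(self, library):
        """SNR 10: all 3 events found within 2 samples of the true onsets."""
        w = library.templates[NEURON][0]
        onsets = [80, 400, 820]
        x = _insert(w, onsets, 1200, noise=0.1, seed=3)
        p = preprocess_trace(x, 20.0)
        train = detect_events(p, library, 20.0, cell_type=NEURON)
        assert len(train) == 3
        det = (train.times * 20.0).round().astype(int)
        assert all(abs(d - o) <= 2 for d, o in zip(det, onsets))

    def test_pure_noise_rarely_fires(self, library):
        hits = 0
        for s in range(40):
            x = np.random.default_rng(s).normal(0, 1, 800)
            train = detect_events(x, library, 20.0, r_threshold=0.8,
                                  cell_type=NEURON)
            hits += len(train) > 0
        assert hits <= 2  # >= 95% of runs event-free

    def test_translation_equivariance(self, library):
        w = library.templates[NEURON][0]
        x = _insert(w, [100, 500], 1200, noise=0.05, seed=9)
        k = 37
        shifted = np.r_[np.zeros(k), x[:-k]]
        t0 = detect_events(x, library, 20.0, cell_type=NEURON)
        t1 = detect_events(shifted, library, 20.0, cell_type=NEURON)
        assert len(t0) == len(t1) == 2
        assert np.allclose(t1.times - t0.times, k / 20.0, atol=1e-9)

    def test_recall_precision_on_synthetic_recordings(self):
        """Recall and precision >= 0.9 at SNR 10 with the default threshold."""
        pop = generate_population(25, 0, seed=31)
        lib = TemplateLibrary.default(20.0)
        ts = simulate_traces(pop, np.zeros((25, 25)), duration=200.0, seed=17,
                             noise_sigma=0.1)
        trains = detect_events_traceset(ts, lib)
        tp = fp = fn = 0
        tol = 3 / 20.0
        for truth, det in zip(ts.event_times, trains):
            # only isolated true events are resolvable by template matching
            truth = np.asarray(truth)
            matched = np.zeros(len(det.times), dtype=bool)
            for t in truth:
                d = np.abs(det.times - t)
                hit = np.flatnonzero(d <= max(tol, 0.35))
                if len(hit):
                    tp += 1
                    matched[hit[0]] = True
                else:
                    # events within one template of a neighbor may merge
                    if np.min(np.abs(truth[truth != t] - t), initial=np.inf) > 3.2:
                        fn += 1
            fp += int((~matched).sum())
        recall = tp / max(tp + fn, 1)
        precision = tp / max(tp + fp, 1)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_missing_templates_rejected(self):
        neuron_only = TemplateLibrary(
            templates={NEURON: [calcium_template(0.1, 0.6, 20.0)]},
            sampling_rate=20.0,
        )
        with pytest.raises(ValueError, match="no templates"):
            detect_events(np.zeros(100), neuron_only, 20.0, cell_type=ASTRO)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TemplateLibrary(templates={}, sampling_rate=20.0)

    def test_event_train_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            EventTrain("r", [1.0, 1.0], [0.9, 0.9])


class TestPruneAndRates:
    @pytest.fixture
    def two_timepoint_recordings(self, small_population):
        from nanet.synthetic import generate_coupling

        c = generate_coupling(small_population, 0.2, 0.2, seed=3)
        ts = [
            simulate_traces(
                small_population, c, duration=60.0, seed=s,
                condition=ConditionSpec(timepoint=tp),
            )
            for s, tp in ((1, "baseline"), (2, "post_injury"))
        ]
        lib = TemplateLibrary.default(20.0)
        trains = [detect_events_traceset(t, lib) for t in ts]
        return ts, trains

    def test_active_any_timepoint_retained_everywhere(
        self, two_timepoint_recordings
    ):
        ts, trains = two_timepoint_recordings
        pruned, ptrains, report = prune_inactive(ts, trains)
        kept = report.kept_roi_ids[ts[0].dish_id]
        active_any = {
            e.roi_id
            for tr in trains
            for e in tr
            if len(e) > 0
        }
        assert set(kept) == active_any
        assert pruned[0].roi_ids == pruned[1].roi_ids == kept

    def test_pruning_idempotent(self, two_timepoint_recordings):
        ts, trains = two_timepoint_recordings
        p1, t1, _ = prune_inactive(ts, trains)
        p2, t2, _ = prune_inactive(p1, t1)
        for a, b in zip(p1, p2):
            assert a.roi_ids == b.roi_ids
            assert np.array_equal(a.traces, b.traces)

    def test_all_silent_dish_flagged(self, small_population):
        ts = simulate_traces(
            small_population, np.zeros((len(small_population),) * 2),
            duration=30.0, seed=1, noise_sigma=0.0,
            base_rates={NEURON: 0.0, ASTRO: 0.0},
        )
        trains = [
            EventTrain(rid, np.empty(0), np.empty(0)) for rid in ts.roi_ids
        ]
        pruned, _, report = prune_inactive([ts], [trains])
        assert pruned[0].traces.shape[1] == 0
        assert report.astro_excluded[ts.dish_id]

    def test_single_active_segment_excluded_from_astro_analyses(
        self, small_population
    ):
        # one astro segment and three neurons active
        active = [r.roi_id for r in small_population.rois if r.cell_type == NEURON][:3]
        active.append(
            next(r.roi_id for r in small_population.rois if r.cell_type == ASTRO)
        )
        ts = simulate_traces(
            small_population, np.zeros((len(small_population),) * 2),
            duration=30.0, seed=2,
        )
        trains = [
            EventTrain(
                rid,
                np.array([1.0]) if rid in active else np.empty(0),
                np.array([0.9]) if rid in active else np.empty(0),
            )
            for rid in ts.roi_ids
        ]
        _, _, report = prune_inactive([ts], [trains])
        assert report.n_active_astro[ts.dish_id] == 1
        assert report.astro_excluded[ts.dish_id]
        assert ts.dish_id not in report.astro_dishes()

    def test_rate_summary_hand_values(self, small_population):
        ts = simulate_traces(
            small_population, np.zeros((len(small_population),) * 2),
            duration=100.0, seed=3,
        )
        neurons = [r.roi_id for r in small_population.rois
                   if r.cell_type == NEURON]
        trains = []
        for rid in ts.roi_ids:
            if rid == neurons[0]:
                times = np.linspace(1, 90, 5)  # 5 events in 100 s -> 0.05 Hz
            elif rid == neurons[1]:
                times = np.linspace(1, 90, 30)  # 0.30 Hz
            else:
                times = np.empty(0)
            trains.append(EventTrain(rid, times, np.full(len(times), 0.9)))
        pruned, ptrains, _ = prune_inactive([ts], [trains])
        summary = event_rate_summary(pruned, ptrains)
        row = summary.query("cell_type == 'neuron'").iloc[0]
        assert row.mean_rate_hz == pytest.approx((0.05 + 0.30) / 2)
        # no astrocyte row at all, rather than a zero
        assert summary.query("cell_type == 'astrocyte_segment'").empty
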
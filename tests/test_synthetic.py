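"""Synthetic study generator: placement, coupling, trace statistics, design."""

import numpy as np
import pytest

from nanet.synthetic import (
    DishDesign,
    EffectSpec,
    generate_coupling,
    generate_population,
    generate_study,
    parent_cell_coupling,
    simulate_traces,
)
from nanet.types import ASTRO, NEURON, ConditionSpec


class TestGeneratePopulation:
    def test_counts_and_parent_ids(self):
        pop = generate_population(40, 3, segments_per_astrocyte=5.0, seed=0)
        types = pop.cell_types
        assert (types == NEURON).sum() == 40
        n_seg = (types == ASTRO).sum()
        assert 5 <= n_seg <= 30  # ~15 expected
        parents = {r.parent_cell_id for r in pop.rois if r.cell_type == ASTRO}
        assert len(parents) == 3

    def test_segment_mean_matches_configured_value(self):
        counts = []
        for s in range(30):
            pop = generate_population(0, 4, segments_per_astrocyte=5.0, seed=s)
            counts.append((pop.cell_types == ASTRO).sum() / 4)
        assert np.mean(counts) == pytest.approx(5.0, abs=0.5)

    def test_neurons_only(self):
        pop = generate_population(10, 0, seed=1)
        assert all(r.parent_cell_id is None for r in pop.rois)
        assert set(pop.cell_types) == {NEURON}

    def test_deterministic(self):
        a = generate_population(20, 2, seed=42)
        b = generate_population(20, 2, seed=42)
        assert a.to_frame().equals(b.to_frame())

    def test_empty_dish_rejected(self):
        with pytest.raises(ValueError, match="empty dish"):
            generate_population(0, 0, seed=0)

    def test_centroids_inside_fov(self):
        pop = generate_population(50, 5, fov=(300.0, 200.0), seed=3)
        xy = pop.coords
        assert xy[:, 0].min() >= 0 and xy[:, 0].max() <= 300
        assert xy[:, 1].min() >= 0 and xy[:, 1].max() <= 200

    def test_segments_near_parent_center(self):
        pop = generate_population(0, 3, segments_per_astrocyte=6.0, seed=7,
                                  cell_radius=50.0)
        by_parent = {}
        for r in pop.rois:
            by_parent.setdefault(r.parent_cell_id, []).append((r.x, r.y))
        for coords in by_parent.values():
            xy = np.array(coords)
            spread = np.sqrt(((xy - xy.mean(0)) ** 2).sum(1)).max()
            assert spread <= 2 * 50.0


class TestGenerateCoupling:
    def test_realized_density_binomial(self):
        # ~10^4 pairs: 142 ROIs
        pop = generate_population(142, 0, seed=0)
        c = generate_coupling(pop, base_density=0.2, spatial_weight=0.0, seed=1)
        n_pairs = 142 * 141 / 2
        realized = np.count_nonzero(np.triu(c, 1)) / n_pairs
        se = np.sqrt(0.2 * 0.8 / n_pairs)
        assert abs(realized - 0.2) < 3 * se

    def test_no_spatial_dependence_when_knob_off(self):
        pop = generate_population(142, 0, seed=2)
        c = generate_coupling(pop, 0.3, spatial_weight=0.0, seed=3)
        from nanet.synthetic import spatial_proximity

        prox = spatial_proximity(pop)
        iu = np.triu_indices(len(pop), 1)
        near = prox[iu] > np.median(prox[iu])
        connected = c[iu] > 0
        # chi-square on distance-stratified connection counts
        from scipy.stats import chi2_contingency

        table = [
            [np.sum(connected & near), np.sum(~connected & near)],
            [np.sum(connected & ~near), np.sum(~connected & ~near)],
        ]
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_saturated_knob_probability_equals_proximity(self):
        from nanet.synthetic import spatial_proximity

        pop = generate_population(120, 0, seed=4)
        prox = spatial_proximity(pop)
        iu = np.triu_indices(len(pop), 1)
        hits = np.zeros(len(iu[0]))
        n_rep = 60
        for s in range(n_rep):
            c = generate_coupling(pop, 1.0, spatial_weight=1.0, seed=100 + s)
            hits += c[iu] > 0
        # empirical connection frequency tracks proximity weight
        resid = hits / n_rep - prox[iu]
        assert np.abs(resid.mean()) < 0.02
        assert np.corrcoef(hits / n_rep, prox[iu])[0, 1] > 0.9

    def test_symmetry_and_range(self, small_population):
        c = generate_coupling(small_population, 0.5, 0.5, seed=5, strength=0.7)
        assert np.allclose(c, c.T)
        assert set(np.unique(c)) <= {0.0, 0.7}

    def test_single_roi_rejected(self):
        pop = generate_population(1, 0, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            generate_coupling(pop, 0.2, 0.2, seed=0)

    def test_parent_cell_coupling_blocks(self, small_population):
        c = parent_cell_coupling(small_population, strength=1.0)
        rois = small_population.rois
        for i, ri in enumerate(rois):
            for j, rj in enumerate(rois):
                if i == j:
                    continue
                expected = (
                    ri.parent_cell_id is not None
                    and ri.parent_cell_id == rj.parent_cell_id
                )
                assert (c[i, j] == 1.0) == expected


class TestSimulateTraces:
    def test_uncoupled_traces_uncorrelated(self):
        # neuron-only population: the fast template keeps the traces'
        # autocorrelation short so the white-noise-style bound applies
        pop = generate_population(20, 0, seed=11)
        ts = simulate_traces(pop, np.zeros((20, 20)), duration=120.0, seed=9)
        R = np.corrcoef(ts.traces.T)
        off = R[~np.eye(len(R), dtype=bool)]
        assert np.abs(off).mean() < 3 / np.sqrt(ts.n_frames)

    def test_rate_knob_zero_silences_neurons(self, small_population):
        cond = ConditionSpec(timepoint="post_drug", neuron_rate_multiplier=0.0)
        c = np.zeros((len(small_population),) * 2)
        ts = simulate_traces(small_population, c, condition=cond, duration=60.0,
                             seed=2)
        for i, roi in enumerate(small_population.rois):
            if roi.cell_type == NEURON:
                assert len(ts.event_times[i]) == 0

    def test_fully_coupled_pair_beats_uncoupled_distribution(
        self, two_neuron_population
    ):
        uncoupled = []
        for s in range(100):
            ts = simulate_traces(
                two_neuron_population, np.zeros((2, 2)), duration=120.0, seed=s
            )
            uncoupled.append(np.corrcoef(ts.traces.T)[0, 1])
        q99 = np.quantile(uncoupled, 0.99)
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        ts = simulate_traces(two_neuron_population, C, duration=120.0, seed=1234)
        assert np.corrcoef(ts.traces.T)[0, 1] > q99

    def test_marginal_rate_recovery(self):
        """Empirical event rate within 3 SE of configured over >=100 recordings."""
        pop = generate_population(30, 3, 5.0, seed=21)
        rates = {NEURON: [], ASTRO: []}
        duration = 200.0
        for s in range(4):  # 4 x ~45 ROIs > 100 ROI-recordings
            c = generate_coupling(pop, 0.15, 0.2, seed=50 + s)
            ts = simulate_traces(pop, c, duration=duration, seed=500 + s)
            for i, t in enumerate(pop.cell_types):
                rates[t].append(len(ts.event_times[i]) / duration)
        for ct, target in ((NEURON, 0.08), (ASTRO, 0.02)):
            vals = np.array(rates[ct])
            se = np.sqrt(target / duration) / np.sqrt(len(vals))
            assert abs(vals.mean() - target) < 3 * se, ct

    def test_coupling_monotonicity(self, two_neuron_population):
        means = []
        for cval in (0.0, 0.25, 0.5, 1.0):
            C = np.array([[0.0, cval], [cval, 0.0]])
            rs = [
                np.corrcoef(
                    simulate_traces(
                        two_neuron_population, C, duration=300.0, seed=s
                    ).traces.T
                )[0, 1]
                for s in range(8)
            ]
            means.append(np.mean(rs))
        assert all(b > a - 0.02 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 0.3

    def test_shape_mismatch_rejected(self, small_population):
        with pytest.raises(ValueError, match="does not match"):
            simulate_traces(small_population, np.zeros((3, 3)), seed=0)

    def test_deterministic(self, small_population):
        c = generate_coupling(small_population, 0.2, 0.2, seed=1)
        a = simulate_traces(small_population, c, duration=30.0, seed=7)
        b = simulate_traces(small_population, c, duration=30.0, seed=7)
        assert np.array_equal(a.traces, b.traces)
        for ta, tb in zip(a.event_times, b.event_times):
            assert np.array_equal(ta, tb)


class TestGenerateStudy:
    def test_counting(self):
        design = [
            DishDesign(f"d{i}", drug, injury)
            for i, (drug, injury) in enumerate(
                [(d, j) for d in ("MEM", "MPEP") for j in ("Sham", "Injury")] * 2
            )
        ]
        study = generate_study(
            design, seed=0, n_neurons=5, n_astrocytes=1,
            segments_per_astrocyte=2.0, duration=20.0,
        )
        assert len(study.tracesets) == 8 * 3
        assert len(study.populations) == 8

    def test_population_reused_across_timepoints(self):
        design = [DishDesign("d0", "MEM", "Injury")]
        study = generate_study(design, seed=1, n_neurons=6, n_astrocytes=1,
                               segments_per_astrocyte=2.0, duration=20.0)
        pops = {ts.population.dish_id for ts in study.tracesets}
        assert pops == {"d0"}
        ids = [tuple(ts.roi_ids) for ts in study.tracesets]
        assert len(set(ids)) == 1

    def test_baseline_identical_distribution_across_groups(self):
        """Condition knobs must not act before their timepoint."""
        design = [DishDesign("sham", "MEM", "Sham"),
                  DishDesign("inj", "MEM", "Injury")]
        effects = EffectSpec(injury_coupling_multiplier=3.0,
                             injury_spatial_multiplier=3.0)
        study = generate_study(design, seed=3, effects=effects, n_neurons=10,
                               n_astrocytes=1, segments_per_astrocyte=2.0,
                               duration=20.0)
        for dish in ("sham", "inj"):
            base = study.traceset(dish, "baseline")
            assert base.condition.neuron_coupling_multiplier == 1.0
            assert base.condition.spatial_multiplier == 1.0
        # at post_injury the knob differs
        assert study.traceset("inj", "post_injury").condition.neuron_coupling_multiplier == 3.0
        assert study.traceset("sham", "post_injury").condition.neuron_coupling_multiplier == 1.0

    def test_distinct_dishes_reproducible(self):
        design = [DishDesign("a"), DishDesign("b")]
        s1 = generate_study(design, seed=5, n_neurons=5, n_astrocytes=1,
                            segments_per_astrocyte=2.0, duration=20.0)
        s2 = generate_study(design, seed=5, n_neurons=5, n_astrocytes=1,
                            segments_per_astrocyte=2.0, duration=20.0)
        ta1 = s1.traceset("a", "baseline").traces
        tb1 = s1.traceset("b", "baseline").traces
        assert not np.array_equal(ta1, tb1)
        assert np.array_equal(ta1, s2.traceset("a", "baseline").traces)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            generate_study([], seed=0)
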
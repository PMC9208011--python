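"""Synthetic study generator.

Emulates the statistical structure of mixed cortical culture calcium imaging:
dishes with tens of neurons and a handful of astrocytes, each astrocyte split
into several independently active segments; Poisson event trains rendered
through cell-type-specific transient templates with additive Gaussian noise;
pairwise coupling implemented as a shared-latent-train thinning model so that
one knob controls trace correlation; and a 2x2 drug-by-injury design across
three imaging timepoints with multiplicative effect knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    ASTRO,
    NEURON,
    TIMEPOINTS,
    ConditionSpec,
    Population,
    Roi,
    TraceSet,
    validate_coupling,
    as_seedseq,
)
from .waveforms import DEFAULT_KINETICS, calcium_template

#: Baseline event rates (Hz). The source study shows rates only graphically;
#: these sit in the range typical of spontaneous activity in dissociated
#: cortical culture, with astrocyte microdomains much sparser than neurons.
DEFAULT_BASE_RATES = {NEURON: 0.08, ASTRO: 0.02}

#: Fraction of the slower partner's rate routed through the shared latent
#: train when a pair is fully coupled.
DEFAULT_SHARE_SCALE = 0.8

DEFAULT_NOISE_SIGMA = 0.1  # in units of template peak


def generate_population(
    n_neurons: int,
    n_astrocytes: int,
    segments_per_astrocyte: float = 5.0,
    fov: tuple[float, float] = (1000.0, 1000.0),
    seed: int = 0,
    cell_radius: float = 50.0,
    dish_id: str = "dish",
) -> Population:
    """Place neurons uniformly in the FOV and astrocyte segments in clusters.

    ``segments_per_astrocyte`` is the mean of a (shifted, >= 1) Poisson count
    per astrocyte. Segments fall within ``cell_radius`` of their parent's
    center (clipped to the FOV).
    """
    if n_neurons < 0 or n_astrocytes < 0:
        raise ValueError("counts must be >= 0")
    fov_w, fov_h = fov
    rng = np.random.default_rng(seed)
    rois: list[Roi] = []
    for i in range(n_neurons):
        x, y = rng.uniform(0, fov_w), rng.uniform(0, fov_h)
        rois.append(Roi(f"{dish_id}_n{i:03d}", NEURON, x, y))
    for j in range(n_astrocytes):
        cx, cy = rng.uniform(0, fov_w), rng.uniform(0, fov_h)
        n_seg = 1 + rng.poisson(max(segments_per_astrocyte - 1.0, 0.0))
        parent = f"{dish_id}_a{j:02d}"
        for k in range(n_seg):
            # uniform in the disk of radius cell_radius around the center
            r = cell_radius * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            x = float(np.clip(cx + r * np.cos(th), 0, fov_w))
            y = float(np.clip(cy + r * np.sin(th), 0, fov_h))
            rois.append(Roi(f"{parent}s{k:02d}", ASTRO, x, y, parent_cell_id=parent))
    if not rois:
        raise ValueError("empty dish: no ROIs generated")
    return Population(rois=rois, fov_width=fov_w, fov_height=fov_h, dish_id=dish_id)


def spatial_proximity(population: Population) -> np.ndarray:
    """Pairwise 1 - d/d_max proximity weights (diagonal zeroed)."""
    xy = population.coords
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    w = 1.0 - d / population.fov_diagonal
    np.fill_diagonal(w, 0.0)
    return w


def generate_coupling(
    population: Population,
    base_density: float = 0.15,
    spatial_weight: float = 0.2,
    seed: int = 0,
    strength: float = 0.8,
    pair_multiplier: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Bernoulli ground-truth coupling with a tunable spatial component.

    Pair connection probability is
    ``(1 - spatial_weight) * base_density + spatial_weight * base_density * s_ij``
    where ``s_ij`` is the spatial proximity weight, optionally scaled by a
    per-pair ``pair_multiplier`` (clipped into [0, 1]; used by the study
    generator for condition effects). Connected pairs receive coupling
    ``strength``. The uniform variates are drawn before thresholding, so
    regenerating with the same seed but different probabilities yields
    nested edge sets.
    """
    if not 0 <= base_density <= 1 or not 0 <= spatial_weight <= 1:
        raise ValueError("base_density and spatial_weight must lie in [0, 1]")
    if not 0 <= strength <= 1:
        raise ValueError("strength must lie in [0, 1]")
    n = len(population)
    if n < 2:
        raise ValueError("need at least 2 ROIs to couple")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(n, n))
    u = np.triu(u, 1)
    u = u + u.T  # symmetric uniforms
    prox = spatial_proximity(population)
    p = (1 - spatial_weight) * base_density + spatial_weight * base_density * prox
    p = np.clip(p * pair_multiplier, 0.0, 1.0)
    np.fill_diagonal(p, 0.0)
    coupling = np.where(u < p, strength, 0.0)
    np.fill_diagonal(coupling, 0.0)
    return validate_coupling(coupling, n)


def parent_cell_coupling(population: Population, strength: float = 1.0) -> np.ndarray:
    """Coupling that ties segments of the same astrocyte together.

    Stand-in ground truth for within-cell synchrony: segments sharing a
    ``parent_cell_id`` are coupled at ``strength``; all other pairs are 0.
    """
    parents = np.array(
        [r.parent_cell_id if r.parent_cell_id is not None else f"__self__{i}"
         for i, r in enumerate(population.rois)]
    )
    same = parents[:, None] == parents[None, :]
    coupling = np.where(same, float(strength), 0.0)
    np.fill_diagonal(coupling, 0.0)
    return validate_coupling(coupling, len(population))




def simulate_traces(
    population: Population,
    coupling: np.ndarray,
    condition: ConditionSpec | None = None,
    duration: float = 120.0,
    sampling_rate: float = 20.0,
    seed: int = 0,
    base_rates: dict[str, float] | None = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    share_scale: float = DEFAULT_SHARE_SCALE,
    degree_norm: float | None = None,
) -> TraceSet:
    """Render fluorescence traces from coupled Poisson event trains.

    Event sharing follows a common-parent-train thinning model: each coupled
    pair (i, j) owns a latent Poisson train whose events are copied into
    *both* trains with probability ``c_ij``, so the shared rate (and hence
    the trace correlation) grows monotonically with the coupling strength.
    The latent rate is ``share_scale * min(r_i, r_j) / degree_norm``;
    ``degree_norm`` defaults to the mean coupled degree of the given
    coupling, splitting each node's shared budget across a typical partner
    count (the study generator passes the dish's *baseline* value so a
    condition that adds couplings does not dilute per-pair correlation).
    Nodes whose total shared demand exceeds their configured rate have their
    shared copies thinned, and an independent component tops every marginal
    rate back up, so per-ROI rates match the configured values in
    expectation.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    condition = condition or ConditionSpec()
    n = len(population)
    # the condition's coupling/spatial knobs act at coupling *generation*
    # (see generate_study); here the coupling matrix is taken as given
    coupling = validate_coupling(coupling, n)
    base_rates = dict(DEFAULT_BASE_RATES if base_rates is None else base_rates)

    rng = np.random.default_rng(seed)
    types = population.cell_types
    rates = np.array([base_rates[t] for t in types], dtype=float)
    rates[types == NEURON] *= condition.neuron_rate_multiplier

    degree = (coupling > 0).sum(axis=1)
    if degree_norm is None:
        coupled = degree[degree > 0]
        degree_norm = float(coupled.mean()) if coupled.size else 1.0
    degree_norm = max(degree_norm, 1.0)

    # shared component per coupled pair
    shared_events: list[list[np.ndarray]] = [[] for _ in range(n)]
    shared_rate = np.zeros(n)
    ii, jj = np.nonzero(np.triu(coupling, 1))
    for i, j in zip(ii, jj):
        lam = share_scale * min(rates[i], rates[j]) / degree_norm
        if lam <= 0:
            continue
        c = coupling[i, j]
        n_latent = rng.poisson(lam * duration)
        if n_latent:
            t_latent = rng.uniform(0, duration, size=n_latent)
            shared = t_latent[rng.uniform(size=n_latent) < c]
            shared_events[i].append(shared)
            shared_events[j].append(shared)
        shared_rate[i] += c * lam
        shared_rate[j] += c * lam

    # thin over-budget shared copies; top up with an independent component
    events: list[np.ndarray] = []
    for i in range(n):
        sh = (
            np.concatenate(shared_events[i]) if shared_events[i] else np.empty(0)
        )
        if shared_rate[i] > rates[i] > 0:
            sh = sh[rng.uniform(size=len(sh)) < rates[i] / shared_rate[i]]
        ind_rate = max(rates[i] - shared_rate[i], 0.0)
        k = rng.poisson(ind_rate * duration)
        ind = rng.uniform(0, duration, size=k) if k else np.empty(0)
        events.append(np.concatenate([sh, ind]))

    n_frames = int(round(duration * sampling_rate))
    templates = {
        ct: calcium_template(rt, dt, sampling_rate)
        for ct, (rt, dt) in DEFAULT_KINETICS.items()
    }
    traces = np.zeros((n_frames, n))
    event_times: list[np.ndarray] = []
    for i in range(n):
        t_i = np.sort(events[i])
        event_times.append(t_i)
        impulses = np.zeros(n_frames)
        onsets = np.minimum((t_i * sampling_rate).astype(int), n_frames - 1)
        np.add.at(impulses, onsets, 1.0)
        clean = np.convolve(impulses, templates[types[i]])[:n_frames]
        traces[:, i] = clean
    traces += rng.normal(0.0, noise_sigma, size=traces.shape)

    return TraceSet(
        traces=traces,
        sampling_rate=sampling_rate,
        population=population,
        condition=condition,
        event_times=event_times,
    )


@dataclass(frozen=True)
class EffectSpec:
    """Condition effect knobs of the study design.

    MPEP lowers neuronal event rate from the post-drug timepoint on; injury
    raises neuron-layer coupling and the spatial dependence of coupling at the
    post-injury timepoint; pre-treatment with MPEP attenuates both injury
    knobs back to identity.
    """

    mpep_rate_multiplier: float = 0.6
    injury_coupling_multiplier: float = 1.5
    injury_spatial_multiplier: float = 2.0
    mpep_injury_coupling_multiplier: float = 1.0
    mpep_injury_spatial_multiplier: float = 1.0

    def condition(self, drug: str, injury: str, timepoint: str) -> ConditionSpec:
        """Effective knobs for one (arm, timepoint) cell."""
        rate = 1.0
        coup = 1.0
        spat = 1.0
        if drug == "MPEP" and timepoint in ("post_drug", "post_injury"):
            rate = self.mpep_rate_multiplier
        if injury == "Injury" and timepoint == "post_injury":
            if drug == "MPEP":
                coup = self.mpep_injury_coupling_multiplier
                spat = self.mpep_injury_spatial_multiplier
            else:
                coup = self.injury_coupling_multiplier
                spat = self.injury_spatial_multiplier
        return ConditionSpec(
            drug=drug,
            injury=injury,
            timepoint=timepoint,
            neuron_rate_multiplier=rate,
            neuron_coupling_multiplier=coup,
            spatial_multiplier=spat,
        )


@dataclass(frozen=True)
class DishDesign:
    dish_id: str
    drug: str = "MEM"
    injury: str = "Sham"


@dataclass
class Study:
    """Everything generated for one synthetic study."""

    populations: dict[str, Population]
    couplings: dict[str, np.ndarray]  # baseline coupling per dish
    tracesets: list[TraceSet]
    design: list[DishDesign] = field(default_factory=list)

    def traceset(self, dish_id: str, timepoint: str) -> TraceSet:
        for ts in self.tracesets:
            if ts.dish_id == dish_id and ts.condition.timepoint == timepoint:
                return ts
        raise KeyError((dish_id, timepoint))

    def by_dish(self) -> dict[str, list[TraceSet]]:
        out: dict[str, list[TraceSet]] = {}
        for ts in self.tracesets:
            out.setdefault(ts.dish_id, []).append(ts)
        return out


def default_design(n_per_group: int = 9) -> list[DishDesign]:
    """2x2 balanced design, ``n_per_group`` dishes per arm."""
    design = []
    k = 0
    for drug in ("MEM", "MPEP"):
        for injury in ("Sham", "Injury"):
            for _ in range(n_per_group):
                design.append(DishDesign(f"d{k:02d}", drug, injury))
                k += 1
    return design


def generate_study(
    design: list[DishDesign],
    seed: int = 0,
    timepoints: tuple[str, ...] = TIMEPOINTS,
    effects: EffectSpec | None = None,
    n_neurons: int = 40,
    n_astrocytes: int = 3,
    segments_per_astrocyte: float = 5.0,
    fov: tuple[float, float] = (1000.0, 1000.0),
    base_density: float = 0.15,
    spatial_weight: float = 0.2,
    coupling_strength: float = 0.8,
    duration: float = 120.0,
    sampling_rate: float = 20.0,
    base_rates: dict[str, float] | None = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    share_scale: float = DEFAULT_SHARE_SCALE,
) -> Study:
    """Generate one TraceSet per dish per timepoint.

    Each dish's population is generated once and reused across its
    timepoints. The ground-truth coupling is regenerated per timepoint from
    the same per-dish seed, so the condition's spatial-dependence knob
    perturbs the same underlying uniform draws (nested edge sets); the
    neuron-layer coupling knob is applied inside ``simulate_traces``.
    """
    if not design:
        raise ValueError("design must be nonempty")
    unknown = [tp for tp in timepoints if tp not in TIMEPOINTS]
    if unknown:
        raise ValueError(f"unknown timepoints {unknown}")
    effects = effects or EffectSpec()
    master = as_seedseq(seed)
    dish_seeds = master.spawn(len(design))

    populations: dict[str, Population] = {}
    couplings: dict[str, np.ndarray] = {}
    tracesets: list[TraceSet] = []
    for dish, dish_ss in zip(design, dish_seeds):
        pop_seed, coup_seed, *tp_seeds = dish_ss.spawn(2 + len(timepoints))
        pop = generate_population(
            n_neurons,
            n_astrocytes,
            segments_per_astrocyte,
            fov=fov,
            seed=pop_seed,
            dish_id=dish.dish_id,
        )
        populations[dish.dish_id] = pop
        couplings[dish.dish_id] = generate_coupling(
            pop, base_density, spatial_weight, seed=coup_seed, strength=coupling_strength
        )
        base_deg = (couplings[dish.dish_id] > 0).sum(axis=1)
        base_deg = base_deg[base_deg > 0]
        dish_degree_norm = float(base_deg.mean()) if base_deg.size else 1.0
        is_neuron = pop.cell_types == NEURON
        nn_mask = np.outer(is_neuron, is_neuron)
        prox = spatial_proximity(pop)
        off = ~np.eye(len(pop), dtype=bool)
        mean_prox = float(prox[off].mean())
        for tp, tp_ss in zip(timepoints, tp_seeds):
            cond = effects.condition(dish.drug, dish.injury, tp)
            sw = float(np.clip(spatial_weight * cond.spatial_multiplier, 0.0, 1.0))
            # compensate the spatial knob so expected density is unchanged:
            # it shifts *where* couplings fall, not how many there are
            comp = (1 - spatial_weight + spatial_weight * mean_prox) / (
                1 - sw + sw * mean_prox
            )
            pair_mult = np.where(
                nn_mask, comp * cond.neuron_coupling_multiplier, comp
            )
            coupling_tp = generate_coupling(
                pop,
                base_density,
                sw,
                seed=coup_seed,
                strength=coupling_strength,
                pair_multiplier=pair_mult,
            )
            tracesets.append(
                simulate_traces(
                    pop,
                    coupling_tp,
                    condition=cond,
                    duration=duration,
                    sampling_rate=sampling_rate,
                    seed=tp_ss,
                    base_rates=base_rates,
                    noise_sigma=noise_sigma,
                    share_scale=share_scale,
                    degree_norm=dish_degree_norm,
                )
            )
    return Study(
        populations=populations,
        couplings=couplings,
        tracesets=tracesets,
        design=list(design),
    )
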
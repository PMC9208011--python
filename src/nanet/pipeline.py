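"""End-to-end study orchestration.

Chains the full analysis: simulate (or load) a study -> preprocess traces and
detect events -> prune inactive ROIs -> build functional and spatial
adjacency -> assemble multilayer networks -> topology metrics against
degree-preserving nulls -> spatial-functional analyses -> community detection
with resolution tuning and partition comparison -> GLMs and group tests.
Every stage is an importable function; :func:`run_full_pipeline` composes
them, optionally writing all artifacts plus a manifest to a run directory.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .community import (
    adjusted_rand_index,
    louvain_consensus,
    module_participation,
    morphological_partition,
    tune_gamma,
)
from .connectivity import build_functional_adjacency, build_spatial_adjacency
from .metrics import METRICS, metrics_vs_null_ensemble
from .multilayer import (
    MultilayerAdjacency,
    layer_strength_means,
    multilayer_from_matrix,
    subsample_neurons,
)
from .spatial import connection_probability_curve, corrected_corr2, edge_weight_regression
from .stats import (
    fit_topology_glm,
    injury_effect_tests,
    null_delta_ttest,
    one_way_anova,
    tukey_posthoc,
)
from .synthetic import EffectSpec, Study, default_design, generate_study
from .traces import detect_events_traceset, event_rate_summary, prune_inactive
from .types import ASTRO, NEURON, TIMEPOINTS, as_seedseq
from .waveforms import TemplateLibrary

DELTA_METRICS = ("C", "B", "E")
SCOPES = ("neuron", "astrocyte", "multilayer")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class StudyConfig:
    """Study-generation and analysis settings, YAML-serializable."""

    # design
    n_per_group: int = 9
    timepoints: tuple[str, ...] = TIMEPOINTS
    # population & simulation
    n_neurons: int = 40
    n_astrocytes: int = 3
    segments_per_astrocyte: float = 5.0
    fov: tuple[float, float] = (1000.0, 1000.0)
    duration: float = 120.0
    sampling_rate: float = 20.0
    base_density: float = 0.15
    spatial_weight: float = 0.2
    coupling_strength: float = 0.8
    noise_sigma: float = 0.1
    share_scale: float = 0.8
    base_rates: dict | None = None
    effects: EffectSpec = field(default_factory=EffectSpec)
    # event detection
    r_threshold: float = 0.8
    # connectivity
    n_surrogates: int = 100
    alpha: float = 0.05
    analysis_timepoint: str = "post_injury"
    # nulls
    n_null: int = 100
    rewire_iterations: int = 100
    astro_rewire_iterations: int = 10
    delta_metrics: tuple[str, ...] = DELTA_METRICS
    metric_scopes: tuple[str, ...] = SCOPES
    # communities
    community_runs: int = 50
    gamma_functional: float = 1.0
    gamma_grid: tuple[float, ...] = tuple(np.round(np.arange(0.5, 2.0001, 0.05), 10))
    # balance control
    subsample: bool = True
    subsample_repeats: int = 25
    # stage toggles
    do_nulls: bool = True
    do_spatial: bool = True
    do_communities: bool = True
    do_stats: bool = True

    def __post_init__(self) -> None:
        if self.analysis_timepoint not in self.timepoints:
            raise ValueError("analysis_timepoint must be one of timepoints")
        if isinstance(self.effects, dict):
            self.effects = EffectSpec(**self.effects)
        self.timepoints = tuple(self.timepoints)
        self.fov = tuple(self.fov)
        self.gamma_grid = tuple(self.gamma_grid)
        self.delta_metrics = tuple(self.delta_metrics)
        self.metric_scopes = tuple(self.metric_scopes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"] = dataclasses.asdict(self.effects)
        d["timepoints"] = list(self.timepoints)
        d["fov"] = list(self.fov)
        d["gamma_grid"] = [float(g) for g in self.gamma_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(nio.read_yaml(path))


def simulate_stage(config: StudyConfig, seed) -> Study:
    design = default_design(config.n_per_group)
    return generate_study(
        design,
        seed=seed,
        timepoints=config.timepoints,
        effects=config.effects,
        n_neurons=config.n_neurons,
        n_astrocytes=config.n_astrocytes,
        segments_per_astrocyte=config.segments_per_astrocyte,
        fov=config.fov,
        base_density=config.base_density,
        spatial_weight=config.spatial_weight,
        coupling_strength=config.coupling_strength,
        duration=config.duration,
        sampling_rate=config.sampling_rate,
        base_rates=config.base_rates,
        noise_sigma=config.noise_sigma,
        share_scale=config.share_scale,
    )


def events_stage(study: Study, config: StudyConfig):
    """Detect events on every recording, prune, and summarize rates."""
    library = TemplateLibrary.default(config.sampling_rate)
    trains = [
        detect_events_traceset(ts, library, r_threshold=config.r_threshold)
        for ts in study.tracesets
    ]
    pruned_ts, pruned_trains, report = prune_inactive(study.tracesets, trains)
    rates = event_rate_summary(pruned_ts, pruned_trains)
    return pruned_ts, pruned_trains, report, rates


def connectivity_stage(pruned_ts, config: StudyConfig, seed):
    """Functional + spatial adjacency at the analysis timepoint, per dish.

    Returns ``{dish_id: (MultilayerAdjacency functional, MultilayerAdjacency
    spatial)}`` in neuron-first node order.
    """
    ss = as_seedseq(seed)
    nets: dict[str, tuple[MultilayerAdjacency, MultilayerAdjacency]] = {}
    analysis_ts = [
        ts for ts in pruned_ts if ts.condition.timepoint == config.analysis_timepoint
    ]
    seeds = ss.spawn(len(analysis_ts))
    for ts, s in zip(analysis_ts, seeds):
        if len(ts.population) < 2:
            continue
        fa = build_functional_adjacency(
            ts, n_surrogates=config.n_surrogates, alpha=config.alpha, seed=s
        )
        sa = build_spatial_adjacency(ts.population)
        nets[ts.dish_id] = (
            multilayer_from_matrix(fa.weights, ts.population),
            multilayer_from_matrix(sa.weights, ts.population),
        )
    return nets


def _scope_matrix(M: MultilayerAdjacency, scope: str) -> np.ndarray | None:
    if scope == "neuron":
        block = M.neuron_block
    elif scope == "astrocyte":
        block = M.astro_block
    else:
        block = M.weights
    return block if block.shape[0] >= 2 else None


def metrics_stage(nets, study: Study, config: StudyConfig, report, seed):
    """Tidy per-dish metric table with null-model means and deltas."""
    ss = as_seedseq(seed)
    rows = []
    dish_group = {d.dish_id: (d.drug, d.injury) for d in study.design}
    dish_seeds = dict(zip(sorted(nets), ss.spawn(len(nets))))
    for dish_id in sorted(nets):
        func, _ = nets[dish_id]
        drug, injury = dish_group[dish_id]
        scope_seeds = dish_seeds[dish_id].spawn(len(SCOPES) + 1)
        for scope, scope_seed in zip(SCOPES, scope_seeds):
            if scope not in config.metric_scopes:
                continue
            if scope == "astrocyte" and report.astro_excluded.get(dish_id, True):
                continue
            A = _scope_matrix(func, scope)
            if A is None:
                continue
            iters = (
                config.astro_rewire_iterations
                if scope == "astrocyte"
                else config.rewire_iterations
            )
            null_stats = (
                metrics_vs_null_ensemble(
                    A,
                    metrics=config.delta_metrics,
                    n_null=config.n_null,
                    seed=scope_seed,
                    iterations=iters,
                )
                if config.do_nulls
                else {}
            )
            for metric, fn in METRICS.items():
                value = fn(A)
                null_mean = np.nan
                delta = np.nan
                if metric in null_stats:
                    _, null_mean, delta = null_stats[metric]
                rows.append(
                    {
                        "dish_id": dish_id,
                        "drug": drug,
                        "injury": injury,
                        "group": f"{drug}-{injury}",
                        "timepoint": config.analysis_timepoint,
                        "scope": scope,
                        "metric": metric,
                        "value": value,
                        "null_mean": null_mean,
                        "delta": delta,
                    }
                )
        # interlayer strength/density summaries
        means = layer_strength_means(func)
        inter = func.interlayer_block
        if inter.size:
            rows.append(
                {
                    "dish_id": dish_id,
                    "drug": drug,
                    "injury": injury,
                    "group": f"{drug}-{injury}",
                    "timepoint": config.analysis_timepoint,
                    "scope": "interlayer",
                    "metric": "S",
                    "value": means["interlayer"],
                    "null_mean": np.nan,
                    "delta": np.nan,
                }
            )
            rows.append(
                {
                    "dish_id": dish_id,
                    "drug": drug,
                    "injury": injury,
                    "group": f"{drug}-{injury}",
                    "timepoint": config.analysis_timepoint,
                    "scope": "interlayer",
                    "metric": "kappa",
                    "value": float(np.count_nonzero(inter) / inter.size),
                    "null_mean": np.nan,
                    "delta": np.nan,
                }
            )
        if config.subsample and func.n_neurons >= func.n_astro >= 2:
            sub_vals = {m: [] for m in ("S", "C", "E")}
            sub_seeds = scope_seeds[-1].spawn(config.subsample_repeats)
            for s in sub_seeds:
                sub = subsample_neurons(func, seed=s)
                for m in sub_vals:
                    sub_vals[m].append(METRICS[m](sub.weights))
            for m, vals in sub_vals.items():
                rows.append(
                    {
                        "dish_id": dish_id,
                        "drug": drug,
                        "injury": injury,
                        "group": f"{drug}-{injury}",
                        "timepoint": config.analysis_timepoint,
                        "scope": "multilayer_subsampled",
                        "metric": m,
                        "value": float(np.mean(vals)),
                        "null_mean": np.nan,
                        "delta": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def null_tests_stage(metrics_df: pd.DataFrame):
    """One-sample t tests of per-dish metric deltas against zero."""
    reports = []
    for scope in SCOPES:
        for metric in DELTA_METRICS:
            d = metrics_df.query("scope == @scope and metric == @metric")["delta"]
            d = d.dropna()
            if len(d) >= 3 and np.ptp(d) > 0:
                reports.append(
                    null_delta_ttest(d, name=f"{scope}:{metric}_delta_vs_null")
                )
    return reports


def spatial_stage(nets, study: Study, config: StudyConfig, seed):
    """Probability curves, weight regressions, and corrected corr2 per class."""
    ss = as_seedseq(seed)
    dish_group = {d.dish_id: f"{d.drug}-{d.injury}" for d in study.design}
    out = {"curves": [], "weight_regressions": [], "corrected_corr2": []}
    classes = ("NN", "AA", "NA")
    by_group: dict[str, list[str]] = {}
    for dish_id in sorted(nets):
        by_group.setdefault(dish_group[dish_id], []).append(dish_id)
    for group, dishes in sorted(by_group.items()):
        funcs = [nets[d][0].weights for d in dishes]
        spats = [nets[d][1].weights for d in dishes]
        layers = [nets[d][0].layers for d in dishes]
        for cls in classes:
            try:
                curve = connection_probability_curve(
                    funcs, spats, layers, pair_class=cls, n_bins=30
                )
                reg = edge_weight_regression(funcs, spats, layers, pair_class=cls)
            except ValueError:
                continue
            out["curves"].append(
                {
                    "group": group,
                    "pair_class": cls,
                    "slope": curve.regression.slope,
                    "ci_low": curve.regression.ci_low,
                    "ci_high": curve.regression.ci_high,
                    "r_squared": curve.regression.r_squared,
                    "p": curve.regression.p_value,
                    "n_bins": len(curve.table),
                    "n_pairs": curve.total_pairs,
                }
            )
            out["weight_regressions"].append(
                {
                    "group": group,
                    "pair_class": cls,
                    "slope": reg.slope,
                    "ci_low": reg.ci_low,
                    "ci_high": reg.ci_high,
                    "r_squared": reg.r_squared,
                    "p": reg.p_value,
                    "n_pairs": reg.n,
                }
            )
    # per-dish corrected 2-D correlation by class (block-restricted)
    seeds = ss.spawn(len(nets))
    for dish_id, s in zip(sorted(nets), seeds):
        func, spat = nets[dish_id]
        blocks = {
            "NN": (func.neuron_block, spat.neuron_block),
            "AA": (func.astro_block, spat.astro_block),
            "NA": (func.interlayer_block, spat.interlayer_block),
        }
        cls_seeds = s.spawn(len(blocks))
        for (cls, (F, S)), cs in zip(blocks.items(), cls_seeds):
            if F.size < 4:
                continue
            try:
                value = corrected_corr2(F, S, seed=cs)
            except ValueError:  # constant block (e.g., no edges)
                continue
            out["corrected_corr2"].append(
                {
                    "dish_id": dish_id,
                    "group": dish_group[dish_id],
                    "pair_class": cls,
                    "corrected_corr2": value,
                }
            )
    return {k: pd.DataFrame(v) for k, v in out.items()}


def community_stage(nets, study: Study, config: StudyConfig, report, seed):
    """Functional/spatial/morphological partitions, ARIs, participation."""
    ss = as_seedseq(seed)
    rows = []
    partitions = {}
    seeds = dict(zip(sorted(nets), ss.spawn(len(nets))))
    for dish_id in sorted(nets):
        func, spat = nets[dish_id]
        if np.abs(func.weights).sum() == 0:
            continue
        s_func, s_tune, s_spat, s_astro = seeds[dish_id].spawn(4)
        res_f = louvain_consensus(
            func.weights, gamma=config.gamma_functional,
            n_runs=config.community_runs, seed=s_func,
        )
        tuned = tune_gamma(
            func.weights, spat.weights, gammas=config.gamma_grid, seed=s_tune,
            gamma_ref=config.gamma_functional, n_runs=config.community_runs,
        )
        res_s = louvain_consensus(
            spat.weights, gamma=tuned.gamma_star,
            n_runs=config.community_runs, seed=s_spat,
        )
        partitions[dish_id] = {"functional": res_f, "spatial": res_s}
        part_f = module_participation(res_f.partition, func.layers)
        part_s = module_participation(res_s.partition, spat.layers)
        row = {
            "dish_id": dish_id,
            "ari_functional_spatial": adjusted_rand_index(
                res_f.partition, res_s.partition
            ),
            "gamma_spatial": tuned.gamma_star,
            "n_comm_functional": res_f.n_communities,
            "n_comm_spatial": res_s.n_communities,
            "mean_size_functional": len(res_f.partition) / res_f.n_communities,
            "mean_size_spatial": len(res_s.partition) / res_s.n_communities,
            "participation_functional_neuron": part_f.get(NEURON, np.nan),
            "participation_functional_astro": part_f.get(ASTRO, np.nan),
            "participation_spatial_neuron": part_s.get(NEURON, np.nan),
            "participation_spatial_astro": part_s.get(ASTRO, np.nan),
        }
        # astrocyte-layer three-way comparison where the dish qualifies
        if not report.astro_excluded.get(dish_id, True):
            pop = study.populations[dish_id].subset(
                report.kept_roi_ids[dish_id]
            )
            morph, seg_ids = morphological_partition(pop)
            astro_mask = func.layers == ASTRO
            order = [func.roi_ids[i] for i in np.flatnonzero(astro_mask)]
            morph_by_id = dict(zip(seg_ids, morph))
            morph_aligned = np.array([morph_by_id[r] for r in order])
            A_astro = func.astro_block
            if np.abs(A_astro).sum() > 0 and A_astro.shape[0] >= 2:
                res_af = louvain_consensus(
                    A_astro, gamma=config.gamma_functional,
                    n_runs=config.community_runs, seed=s_astro,
                )
                f_astro = res_af.partition
                s_astro_part = res_s.partition[astro_mask]
                row.update(
                    {
                        "ari_morph_functional_astro": adjusted_rand_index(
                            morph_aligned, f_astro
                        ),
                        "ari_morph_spatial_astro": adjusted_rand_index(
                            morph_aligned, s_astro_part
                        ),
                        "ari_functional_spatial_astro": adjusted_rand_index(
                            f_astro, s_astro_part
                        ),
                        "ari_morph_multilayer_astro": adjusted_rand_index(
                            morph_aligned, res_f.partition[astro_mask]
                        ),
                    }
                )
        rows.append(row)
    return pd.DataFrame(rows), partitions


def stats_stage(metrics_df: pd.DataFrame, rates: pd.DataFrame, config: StudyConfig):
    """GLMs per scope/outcome plus event-rate group comparisons."""
    out = {"glm": [], "injury_contrasts": [], "anova": [], "tukey": []}
    rate_cov = (
        rates.query("timepoint == @config.analysis_timepoint")
        .pivot_table(index="dish_id", columns="cell_type", values="mean_rate_hz")
        .rename(columns={NEURON: "neuron_rate", ASTRO: "astro_rate"})
    )
    for scope in SCOPES:
        wide = (
            metrics_df.query("scope == @scope")
            .pivot_table(
                index=["dish_id", "drug", "injury"], columns="metric", values="value"
            )
            .reset_index()
        )
        if len(wide) < 8:
            continue
        wide = wide.merge(rate_cov, on="dish_id", how="left")
        rate_col = "astro_rate" if scope == "astrocyte" else "neuron_rate"
        for outcome in ("C", "B", "E"):
            if outcome not in wide:
                continue
            try:
                g = fit_topology_glm(wide, outcome, covariate="S")
            except ValueError:
                continue
            rec = g.table.assign(scope=scope, outcome=outcome, n=g.n)
            out["glm"].append(rec)
            eff = injury_effect_tests(wide, outcome, covariate="S")
            out["injury_contrasts"].append(
                {
                    "scope": scope,
                    "outcome": outcome,
                    "mem_injury_effect": eff.mem_effect,
                    "mem_injury_p": eff.mem_p,
                    "mpep_injury_effect": eff.mpep_effect,
                    "mpep_injury_p": eff.mpep_p,
                }
            )
        if "S" in wide and rate_col in wide and wide[rate_col].notna().sum() >= 8:
            try:
                g = fit_topology_glm(wide.dropna(subset=[rate_col]), "S",
                                     covariate=rate_col)
                out["glm"].append(g.table.assign(scope=scope, outcome="S", n=g.n))
            except ValueError:
                pass
    # event-rate ANOVA + Tukey at the analysis timepoint, per cell type
    for ct in (NEURON, ASTRO):
        sub = rates.query("timepoint == @config.analysis_timepoint and cell_type == @ct")
        if sub["group"].nunique() >= 2 and (sub.groupby("group").size() >= 2).all():
            out["anova"].append(
                dataclasses.asdict(
                    one_way_anova(sub, "mean_rate_hz", "group", name=f"rate[{ct}]")
                )
            )
            out["tukey"].extend(
                dataclasses.asdict(t)
                for t in tukey_posthoc(sub, "mean_rate_hz", "group")
            )
    glm_df = (
        pd.concat(out["glm"], ignore_index=True) if out["glm"] else pd.DataFrame()
    )
    return {
        "glm": glm_df,
        "injury_contrasts": pd.DataFrame(out["injury_contrasts"]),
        "anova": out["anova"],
        "tukey": out["tukey"],
    }


def run_full_pipeline(config: StudyConfig, seed, out_dir=None) -> dict:
    """Execute every stage; return the results bundle.

    With ``out_dir`` set, all tables and a manifest (config, seed, stage
    timings, artifact list) are written there; partial outputs are retained
    if a stage fails.
    """
    bundle: dict = {"config": config, "seed": seed}
    timings: dict[str, float] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    ss = as_seedseq(seed)
    s_sim, s_conn, s_metrics, s_spatial, s_comm = ss.spawn(5)

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as e:  # noqa: BLE001 - stage-named abort by contract
            if out_path is not None:
                _write_outputs(bundle, timings, out_path)
            raise StageError(name, e) from e
        timings[name] = time.perf_counter() - t0
        return result

    study = stage("simulate", simulate_stage, config, s_sim)
    bundle["study"] = study
    pruned_ts, trains, report, rates = stage("events", events_stage, study, config)
    bundle.update(
        {"pruned_tracesets": pruned_ts, "trains": trains, "prune_report": report,
         "rates": rates}
    )
    nets = stage("connectivity", connectivity_stage, pruned_ts, config, s_conn)
    bundle["networks"] = nets
    metrics_df = stage(
        "metrics", metrics_stage, nets, study, config, report, s_metrics
    )
    bundle["metrics"] = metrics_df
    bundle["null_tests"] = stage("null_tests", null_tests_stage, metrics_df)
    if config.do_spatial:
        bundle["spatial_functional"] = stage(
            "spatial_functional", spatial_stage, nets, study, config, s_spatial
        )
    if config.do_communities:
        comm_df, partitions = stage(
            "communities", community_stage, nets, study, config, report, s_comm
        )
        bundle["communities"] = comm_df
        bundle["partitions"] = partitions
    if config.do_stats:
        bundle["stats"] = stage("stats", stats_stage, metrics_df, rates, config)
    if out_path is not None:
        _write_outputs(bundle, timings, out_path)
    return bundle


def _write_outputs(bundle: dict, timings: dict, out: Path) -> None:
    artifacts: list[str] = []

    def save(name, writer):
        writer(out / name)
        artifacts.append(name)

    if "study" in bundle:
        study: Study = bundle["study"]
        save("rois.csv",
             lambda p: nio.write_roi_table(study.populations.values(), p))
        save("traces.h5", lambda p: nio.write_traces_h5(study.tracesets, p))
    if "rates" in bundle:
        save("event_rates.csv", lambda p: bundle["rates"].to_csv(p, index=False))
    if "trains" in bundle:
        save(
            "events.csv",
            lambda p: nio.write_events_csv(
                bundle["trains"], bundle["pruned_tracesets"], p
            ),
        )
    if "networks" in bundle:
        adj_dir = out / "adjacency"
        adj_dir.mkdir(exist_ok=True)
        for dish_id, (func, spat) in bundle["networks"].items():
            nio.write_adjacency(func.weights, func.roi_ids,
                                adj_dir / f"{dish_id}_functional")
            nio.write_adjacency(spat.weights, spat.roi_ids,
                                adj_dir / f"{dish_id}_spatial")
        artifacts.append("adjacency/")
    if "metrics" in bundle:
        save("metrics.csv", lambda p: bundle["metrics"].to_csv(p, index=False))
    if "null_tests" in bundle:
        save(
            "null_tests.json",
            lambda p: nio.write_json(
                [dataclasses.asdict(t) for t in bundle["null_tests"]], p
            ),
        )
    if "spatial_functional" in bundle:
        for key, df in bundle["spatial_functional"].items():
            save(f"spatial_{key}.csv", lambda p, d=df: d.to_csv(p, index=False))
    if "communities" in bundle:
        save("communities.csv",
             lambda p: bundle["communities"].to_csv(p, index=False))
    if "stats" in bundle:
        st = bundle["stats"]
        save("glm.csv", lambda p: st["glm"].to_csv(p, index=False))
        save(
            "injury_contrasts.csv",
            lambda p: st["injury_contrasts"].to_csv(p, index=False),
        )
        save(
            "group_tests.json",
            lambda p: nio.write_json(
                {"anova": st["anova"], "tukey": st["tukey"]}, p
            ),
        )
    config: StudyConfig = bundle["config"]
    nio.write_json(
        {
            "seed": int(bundle["seed"]) if np.isscalar(bundle["seed"]) else None,
            "config": config.to_dict(),
            "timings_s": timings,
            "artifacts": artifacts,
        },
        out / "manifest.json",
    )
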
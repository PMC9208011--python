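"""Pre-configured study-level experiments.

The effect-recovery experiment plants the study's headline injury effect in
the generator (injury raises neuron-layer coupling density and the spatial
dependence of coupling; pre-treatment with the mGluR5 blocker attenuates
both) and asks whether the analysis pipeline recovers the qualitative
pattern. Because each dish's baseline shares the ground-truth coupling
draws with its post-injury recording, the injury response is estimated as a
within-dish change from baseline — the paired design the timepoints exist
for — which cancels dish-level structural variation in the topology
metrics.

Per replicate study (one master seed) the pattern is scored on the
neuronal-layer change scores dC and dE (post-injury minus baseline):

1. the combined topology response dC + dE is larger in the untreated
   injured arm than in untreated sham,
2. the efficiency response dE alone is larger as well, and
3. the combined response in the MPEP arm is smaller than in the MEM arm
   (attenuation).

The per-metric C and E directions are reported alongside. A matched
no-effect (null) study calibrates the treatment-GLM z statistics.

Study sizes are scaled for desk-scale reproduction: 9 dishes per arm (the
emulated design), 25 neurons and 2 astrocytes x ~4 segments per dish,
120 s recordings at 20 Hz, baseline + post-injury timepoints.
"""

from __future__ import annotations

import pandas as pd

from .pipeline import (
    StudyConfig,
    connectivity_stage,
    events_stage,
    metrics_stage,
    simulate_stage,
)
from .stats import fit_topology_glm
from .synthetic import EffectSpec
from .types import as_seedseq

NULL_EFFECTS = EffectSpec(
    mpep_rate_multiplier=1.0,
    injury_coupling_multiplier=1.0,
    injury_spatial_multiplier=1.0,
)


def effect_recovery_config(null_study: bool = False) -> StudyConfig:
    """Scaled study configuration for the effect-recovery experiment."""
    return StudyConfig(
        n_per_group=9,
        n_neurons=25,
        n_astrocytes=2,
        segments_per_astrocyte=4.0,
        duration=120.0,
        timepoints=("baseline", "post_injury"),
        n_surrogates=100,
        effects=NULL_EFFECTS if null_study else EffectSpec(),
        metric_scopes=("neuron",),
        do_nulls=False,
        do_spatial=False,
        do_communities=False,
        subsample=False,
        do_stats=False,
    )


def _metric_wide(nets, study, config, report, seed) -> pd.DataFrame:
    m = metrics_stage(nets, study, config, report, seed)
    return (
        m.query("scope == 'neuron'")
        .pivot_table(index=["dish_id", "drug", "injury"], columns="metric",
                     values="value")
        .reset_index()
    )


def _one_seed(config: StudyConfig, seed, null_study: bool) -> dict:
    ss = as_seedseq(seed)
    s_sim, s_conn, s_met, *_ = ss.spawn(5)
    study = simulate_stage(config, s_sim)
    pruned, _, report, _ = events_stage(study, config)

    from dataclasses import replace

    post_cfg = config
    post = _metric_wide(
        connectivity_stage(pruned, post_cfg, s_conn), study, post_cfg,
        report, s_met,
    )
    row: dict = {}
    g = fit_topology_glm(post, "C", covariate="S")
    row["sham_z_C"] = g.z("Sham")
    if null_study:
        return row

    base_cfg = replace(config, analysis_timepoint="baseline")
    base = _metric_wide(
        connectivity_stage(pruned, base_cfg, s_conn), study, base_cfg,
        report, s_met,
    )
    merged = post.merge(base, on=["dish_id", "drug", "injury"],
                        suffixes=("_post", "_base"))
    merged["dC"] = merged["C_post"] - merged["C_base"]
    merged["dE"] = merged["E_post"] - merged["E_base"]
    means = merged.groupby(["drug", "injury"])[["dC", "dE"]].mean()

    def contrast(drug, col):
        return float(means.loc[(drug, "Injury"), col]
                     - means.loc[(drug, "Sham"), col])

    row.update(
        c_mem=contrast("MEM", "dC"),
        e_mem=contrast("MEM", "dE"),
        c_mpep=contrast("MPEP", "dC"),
        e_mpep=contrast("MPEP", "dE"),
    )
    combined_mem = row["c_mem"] + row["e_mem"]
    combined_mpep = row["c_mpep"] + row["e_mpep"]
    row["pattern_recovered"] = bool(
        combined_mem > 0 and row["e_mem"] > 0 and combined_mpep < combined_mem
    )
    return row


def run_effect_recovery(
    master_seed: int = 0,
    n_seeds: int = 20,
    null_study: bool = False,
) -> pd.DataFrame:
    """Run the experiment over ``n_seeds`` master seeds -> tidy outcome table."""
    cfg = effect_recovery_config(null_study=null_study)
    seeds = as_seedseq(master_seed).spawn(n_seeds)
    rows = []
    for k, s in enumerate(seeds):
        row = _one_seed(cfg, s, null_study)
        row["replicate"] = k
        rows.append(row)
    return pd.DataFrame(rows)
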